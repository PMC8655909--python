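"""Coarse-grained model: topology parsing, eRMSD metric, energies."""

import numpy as np
import pytest

from rnadsorb import constants
from rnadsorb.cg_model import (
    AFormTemplate,
    Conformation,
    ForceFieldParams,
    build_topology,
    ermsd,
    ermsd_between,
    intra_energy,
    restraint_energy,
)
from rnadsorb.fragments import FRAGMENT_DOTBRACKETS
from rnadsorb.geometry import rotation_matrix, straight_chain


# ---------------------------------------------------------------------------
# independent straight-line eRMSD oracle (vectorised, separate code path)
# ---------------------------------------------------------------------------

def ermsd_oracle(bases_a, bases_b):
    def gmat(bases):
        m = len(bases)
        cen = bases.mean(axis=1)
        g = np.zeros((m, m, 4))
        frames = []
        for i in range(m):
            x = bases[i, 0] - cen[i]
            x = x / np.linalg.norm(x)
            z = np.cross(x, bases[i, 1] - cen[i])
            z = z / np.linalg.norm(z)
            frames.append((x, np.cross(z, x), z))
        gamma = np.pi / constants.ERMSD_CUTOFF
        for i in range(m):
            for j in range(m):
                if i == j:
                    continue
                d = cen[j] - cen[i]
                r = np.array([
                    np.dot(frames[i][0], d) / constants.ERMSD_SCALE_XY,
                    np.dot(frames[i][1], d) / constants.ERMSD_SCALE_XY,
                    np.dot(frames[i][2], d) / constants.ERMSD_SCALE_Z,
                ])
                rn = np.linalg.norm(r)
                if rn < constants.ERMSD_CUTOFF:
                    g[i, j, :3] = np.sin(gamma * rn) * r / (rn * gamma)
                    g[i, j, 3] = (1 + np.cos(gamma * rn)) / gamma
        return g

    ga, gb = gmat(np.asarray(bases_a)), gmat(np.asarray(bases_b))
    return np.sqrt(((ga - gb) ** 2).sum() / len(bases_a))


# ---------------------------------------------------------------------------
# topology parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("db,expected_pairs", [
    ("((....))", {(0, 7), (1, 6)}),
    ("(....)", {(0, 5)}),
    ("..(((...)))..", {(2, 10), (3, 9), (4, 8)}),
])
def test_build_topology_pairs(db, expected_pairs):
    topo = build_topology(db)
    assert set(topo.base_pairs) == expected_pairs
    assert topo.structured


@pytest.mark.parametrize("db", ["((....)", "(..))", "((..x..))", "(..)", ""])
def test_build_topology_rejects_invalid(db):
    with pytest.raises(ValueError):
        build_topology(db)


def test_s1_standin_counts():
    topo = build_topology(FRAGMENT_DOTBRACKETS["S1"])
    assert topo.n_nucleotides == 22
    assert len(topo.base_pairs) == 7
    assert topo.paired_fraction == pytest.approx(14 / 22)


def test_stems_are_maximal_stacked_runs():
    topo = build_topology(FRAGMENT_DOTBRACKETS["S1"])
    # a 4-pair outer stem and a 3-pair inner stem separated by a bulge
    assert sorted(len(s) for s in topo.stems) == [3, 4]
    flat = [p for s in topo.stems for p in s]
    assert sorted(flat) == sorted(topo.base_pairs)


def test_sequence_validation():
    build_topology("((....))", sequence="GGAAAACC")
    with pytest.raises(ValueError):
        build_topology("((....))", sequence="GGAAAAC")   # wrong length
    with pytest.raises(ValueError):
        build_topology("((....))", sequence="GGAAAATC")  # T is not RNA


def test_unstructured_variant_drops_pairs():
    topo = build_topology(FRAGMENT_DOTBRACKETS["S1"]).unstructured()
    assert topo.base_pairs == ()
    assert not topo.structured
    assert topo.n_nucleotides == 22


# ---------------------------------------------------------------------------
# eRMSD
# ---------------------------------------------------------------------------

def _template_bases(label="S1", stem=0):
    topo = build_topology(FRAGMENT_DOTBRACKETS[label])
    tmpl = AFormTemplate(topo)
    return tmpl, tmpl.stem_bases[stem].copy(), tmpl.stem_residues[stem]


def test_ermsd_zero_on_identical():
    _, bases, _ = _template_bases()
    assert ermsd_between(bases, bases) == pytest.approx(0.0, abs=1e-12)


def test_ermsd_rigid_motion_invariance(rng):
    _, bases, _ = _template_bases()
    R = rotation_matrix(rng.standard_normal(3), 1.234)
    moved = bases @ R.T + np.array([3.0, -2.0, 7.0])
    assert ermsd_between(bases, moved) < 1e-10


def test_ermsd_matches_bruteforce_oracle(rng):
    _, bases, _ = _template_bases()
    pert = bases + 0.08 * rng.standard_normal(bases.shape)
    ours = ermsd_between(bases, pert)
    ref = ermsd_oracle(bases, pert)
    assert ours == pytest.approx(ref, abs=1e-10)
    assert ours > 0.01


def test_ermsd_symmetry_and_nonnegativity(rng):
    _, bases, _ = _template_bases()
    pert = bases + 0.05 * rng.standard_normal(bases.shape)
    assert ermsd_between(bases, pert) == pytest.approx(
        ermsd_between(pert, bases), abs=1e-12)
    assert ermsd_between(bases, pert) >= 0


def test_ermsd_conformation_api(s1_wiss):
    res = s1_wiss.template.stem_residues[0]
    assert ermsd(s1_wiss.conformation, s1_wiss.template, res) < 1e-9
    with pytest.raises(IndexError):
        ermsd(s1_wiss.conformation, s1_wiss.template, [99])
    with pytest.raises(ValueError):
        ermsd(s1_wiss.conformation, s1_wiss.template, [])


# ---------------------------------------------------------------------------
# restraint energy
# ---------------------------------------------------------------------------

def test_restraint_zero_for_noss(s1_noss):
    assert restraint_energy(s1_noss.conformation, s1_noss.topology, None) == 0.0


def test_restraint_zero_at_template(s1_wiss):
    e = restraint_energy(s1_wiss.conformation, s1_wiss.topology, s1_wiss.template)
    assert e == pytest.approx(0.0, abs=1e-12)


def test_restraint_equals_kss_ermsd_sq(s1_wiss, rng):
    conf = s1_wiss.conformation.copy()
    conf.pos[:, 2:, :] += 0.05 * rng.standard_normal(conf.pos[:, 2:, :].shape)
    expected = sum(
        constants.K_SS * ermsd_oracle(conf.bases[res],
                                      s1_wiss.template.stem_bases[k]) ** 2
        for k, res in enumerate(s1_wiss.template.stem_residues))
    got = restraint_energy(conf, s1_wiss.topology, s1_wiss.template)
    assert got == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# intramolecular energy
# ---------------------------------------------------------------------------

def test_straight_relaxed_chain_has_zero_energy():
    conf = Conformation(straight_chain(10) + np.array([0, 0, 2.0]))
    topo = build_topology("." * 10)
    assert intra_energy(conf, topo) == pytest.approx(0.0, abs=1e-18)


def test_hardcore_overlap_is_infinite():
    pos = straight_chain(4) + np.array([0, 0, 2.0])
    pos[3] = pos[0] + np.array([0.1, 0.0, 0.0])  # phosphates overlap
    conf = Conformation(pos)
    topo = build_topology("....")
    assert intra_energy(conf, topo) == np.inf


def test_site_below_wall_is_rejected():
    pos = straight_chain(4)
    pos[..., 2] += 2.0
    pos[1, 0, 2] = -0.01
    assert intra_energy(Conformation(pos), build_topology("....")) == np.inf


def test_intra_energy_matches_bruteforce(rng, s1_noss):
    """Term-by-term numpy re-computation on a bent but valid chain."""
    conf = s1_noss.conformation
    topo = s1_noss.topology
    p = ForceFieldParams()
    pos = conf.pos
    P = pos[:, 0]
    e = 0.0
    d = np.linalg.norm(np.diff(P, axis=0), axis=1)
    e += 0.5 * p.k_bond_pp * ((d - p.bond_pp) ** 2).sum()
    S = pos[:, 1]
    Bc = pos[:, 2:].mean(axis=1)
    e += 0.5 * p.k_bond_ps * ((np.linalg.norm(P - S, axis=1) - p.bond_ps) ** 2).sum()
    e += 0.5 * p.k_bond_sb * ((np.linalg.norm(S - Bc, axis=1) - p.bond_sb) ** 2).sum()
    for i in range(1, len(P) - 1):
        a = P[i - 1] - P[i]
        b = P[i + 1] - P[i]
        th = np.arccos(np.clip(a @ b / np.linalg.norm(a) / np.linalg.norm(b), -1, 1))
        e += 0.5 * p.k_angle * (th - p.angle0) ** 2
    assert intra_energy(conf, topo, p) == pytest.approx(e, rel=1e-10)


def test_intra_energy_invariant_under_inplane_rigid_motion(s1_wiss):
    conf = s1_wiss.conformation
    e0 = intra_energy(conf, s1_wiss.topology, template=s1_wiss.template)
    R = rotation_matrix([0, 0, 1.0], 0.8)
    com = conf.com()
    moved = Conformation((conf.pos - com) @ R.T + com + np.array([5.0, -3.0, 0.0]))
    e1 = intra_energy(moved, s1_wiss.topology, template=s1_wiss.template)
    assert e1 == pytest.approx(e0, abs=1e-9)


def test_forcefield_params_validation():
    with pytest.raises(ValueError):
        ForceFieldParams(k_bond_pp=-1.0)
    with pytest.raises(ValueError):
        ForceFieldParams(radii=(0.2, 0.0, 0.16, 0.16, 0.16))  # P radius fixed


def test_base_triangle_rigid_under_moves(s1_wiss):
    """Base-triangle edge lengths equal the template edge to 1e-9."""
    tri = s1_wiss.conformation.pos[:, 2:, :]
    e01 = np.linalg.norm(tri[:, 0] - tri[:, 1], axis=1)
    e12 = np.linalg.norm(tri[:, 1] - tri[:, 2], axis=1)
    e20 = np.linalg.norm(tri[:, 2] - tri[:, 0], axis=1)
    for e in (e01, e12, e20):
        assert np.allclose(e, constants.BASE_EDGE, atol=1e-9)


def test_nucleotide_frame_right_handed_orthonormal(s1_wiss):
    from rnadsorb.cg_model import NucleotideGeometry
    for i in range(s1_wiss.conformation.n_nucleotides):
        R = NucleotideGeometry(s1_wiss.conformation.pos[i]).nucleotide_frame
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


def test_pdb_roundtrip(tmp_path, s1_wiss):
    path = tmp_path / "s1.pdb"
    s1_wiss.conformation.to_pdb(path)
    back = Conformation.from_pdb(path)
    # PDB stores two decimals in Angstrom -> 1e-3 nm roundoff
    assert np.allclose(back.pos, s1_wiss.conformation.pos, atol=2e-3)
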