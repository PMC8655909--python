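"""Monte Carlo sampler: CV, determinism, exact stationary distributions.

Each move type is checked against an exactly solvable toy: the whole-chain
z-translation and single-nucleotide translation reduce to 1D Boltzmann
sampling (oracle: numerical quadrature of exp(-E(z))), single-nucleotide
rotation to a 1D distribution over the phosphate tilt (quadrature over
cos(theta)), and the crankshaft to a uniform dihedral.  Reversibility is
additionally checked through the symmetry of binned transition counts.
"""

import numpy as np
import pytest

from rnadsorb import constants
from rnadsorb.cg_model import Conformation, build_topology
from rnadsorb.fragments import make_toy_chain
from rnadsorb.geometry import straight_chain
from rnadsorb.sampler import (
    DEFAULT_MOVE_PROBS,
    UmbrellaWindow,
    collective_variable,
    run_unbiased,
    run_window,
    run_window_scan,
)
from rnadsorb.surface import DebyeHuckelWall, SquareWellWall
from rnadsorb.wham_pmf import blocking_analysis
from rnadsorb import _kernels
from rnadsorb.cg_model import ForceFieldParams, empty_stem_arrays


def _single_nucleotide_at(z):
    pos = straight_chain(1)
    pos[..., 2] += z - pos[..., 2].mean()
    return pos


def _run_kernel(pos, wall, ku, d0, n_sweeps, seed, move_probs, amps=None):
    """Directly drive the MC kernel with a custom move mix."""
    params = ForceFieldParams()
    stem = empty_stem_arrays()
    wtype, wp = wall.kernel_params() if wall is not None else (0, np.zeros(4))
    amps = np.array(amps if amps is not None else [0.3, 0.8, 0.8, 0.3, 0.8])
    cv, snaps, acc, att, _, _ = _kernels.run_mc(
        pos, params.vector(), params.radii_array(), *stem,
        wtype, wp, ku, d0, 200, n_sweeps, 1, seed, amps,
        np.asarray(move_probs, dtype=float), False, False)
    return cv, snaps


# ---------------------------------------------------------------------------
# collective variable
# ---------------------------------------------------------------------------

def test_cv_is_mean_site_height():
    pos = straight_chain(4)
    pos[..., 2] = 2.0
    assert collective_variable(Conformation(pos)) == pytest.approx(2.0)
    pos[:2, :, 2] = 1.0
    pos[2:, :, 2] = 3.0
    assert collective_variable(Conformation(pos)) == pytest.approx(2.0)


def test_cv_bruteforce(rng):
    pos = straight_chain(7)
    pos[..., 2] += rng.random((7, 5)) + 1.0
    conf = Conformation(pos)
    assert collective_variable(conf) == pytest.approx(pos[..., 2].mean())


# ---------------------------------------------------------------------------
# exact stationary laws per move type
# ---------------------------------------------------------------------------

def test_bias_only_gaussian_variance():
    """A free nucleotide under a pure harmonic CV bias samples a Gaussian
    with variance kBT/k_u."""
    ku, d0 = 50.0, 4.0
    pos = _single_nucleotide_at(d0)
    cv, _ = _run_kernel(pos, None, ku, d0, 100_000, seed=3,
                        move_probs=[0.5, 0.0, 0.0, 0.5, 0.0])
    tau = blocking_analysis(cv).tau
    n_eff = len(cv) / (2 * tau + 1)
    var = cv.var()
    se = var * np.sqrt(2.0 / n_eff)
    assert abs(var - 1.0 / ku) < 3 * se + 1e-9
    assert abs(cv.mean() - d0) < 3 * np.sqrt(var / n_eff)


def _boltzmann_ratio_1d(energy, lo, hi, split):
    z = np.linspace(lo, hi, 200_001)
    w = np.exp(-energy(z))
    below = np.trapezoid(w[z < split], z[z < split])
    above = np.trapezoid(w[z >= split], z[z >= split])
    return below / above


@pytest.mark.parametrize("move_probs", [
    [1.0, 0.0, 0.0, 0.0, 0.0],   # single-nucleotide translation
    [0.0, 0.0, 0.0, 1.0, 0.0],   # whole-chain z-translation
])
def test_translation_moves_sample_boltzmann(move_probs):
    """One nucleotide in a square well + soft bias: the z-occupancy ratio of
    two bins must match the quadrature oracle, and the binned transition
    counts must be symmetric (reversibility)."""
    wall = SquareWellWall(depth=1.0, width=0.5)
    ku, d0 = 2.0, 0.6
    pos = _single_nucleotide_at(0.6)
    zoff = pos[0, 0, 2] - pos.mean(axis=(0, 1))[2]  # P height minus COM
    # lowest site offset below the COM bounds the accessible z range (all
    # sites must stay above the wall plane)
    min_off = (pos[..., 2] - pos[..., 2].mean()).min()

    cv, _ = _run_kernel(pos, wall, ku, d0, 150_000, seed=11,
                        move_probs=move_probs)
    zp = cv + zoff  # phosphate height series
    split = 0.5

    def energy(z_p):
        u = np.where(z_p < 0.5, -1.0, 0.0)
        com = z_p - zoff
        return u + 0.5 * ku * (com - d0) ** 2

    expected = _boltzmann_ratio_1d(energy, zoff - min_off + 1e-6, 6.0, split)
    below = np.mean(zp < split)
    ratio = below / (1 - below)
    tau = blocking_analysis((zp < split).astype(float)).tau
    n_eff = len(zp) / (2 * tau + 1)
    se_p = np.sqrt(below * (1 - below) / n_eff)
    lo_p, hi_p = below - 3 * se_p, below + 3 * se_p
    assert lo_p / (1 - lo_p) < expected < hi_p / (1 - hi_p)

    # reversibility: binned transition flows are symmetric
    a = zp[:-1] < split
    b = zp[1:] < split
    up = np.sum(a & ~b)
    down = np.sum(~a & b)
    assert abs(up - down) < 3 * np.sqrt(up + down + 1)


def test_rotation_move_samples_boltzmann_orientation():
    """A nucleotide rotating about its centroid near a square-well wall:
    the phosphate height follows exp(-U) restricted to the sphere around
    the (fixed) centroid."""
    wall = SquareWellWall(depth=1.5, width=0.5)
    pos = _single_nucleotide_at(0.8)
    centroid = pos.mean(axis=(0, 1))
    r = np.linalg.norm(pos[0, 0] - centroid)
    zc = centroid[2]
    cv, snaps = _run_kernel(pos, wall, 0.0, 1.0, 120_000, seed=13,
                            move_probs=[0.0, 1.0, 0.0, 0.0, 0.0])
    zp = snaps[:, 0, 0, 2]
    # P height z = zc + r*u with u uniform on [-1, 1] a priori
    split = 0.5
    u = np.linspace(-1, 1, 200_001)
    w = np.exp(-np.where(zc + r * u < 0.5, -1.5, 0.0))
    expected_below = np.trapezoid(w[zc + r * u < split], u[zc + r * u < split]) \
        / np.trapezoid(w, u)
    below = np.mean(zp < split)
    se = np.sqrt(expected_below * (1 - expected_below) / (len(zp) / 20))
    assert abs(below - expected_below) < 4 * se + 0.01


def test_crankshaft_dihedral_is_uniform():
    """Crankshaft on a 3-mer with no wall: the middle nucleotide's rotation
    angle about the end-to-end axis is energy-neutral, hence uniform."""
    pos = straight_chain(3)
    pos[..., 2] += 3.0
    cv, snaps = _run_kernel(pos, None, 5.0, 3.0, 60_000, seed=17,
                            move_probs=[0.0, 0.0, 1.0, 0.0, 0.0])
    # angle of the middle phosphate-sugar vector around the x-axis
    v = snaps[:, 1, 1, :] - snaps[:, 1, 0, :]
    ang = np.arctan2(v[:, 2], v[:, 1])
    counts, _ = np.histogram(ang, bins=8, range=(-np.pi, np.pi))
    n_eff = len(ang) / (2 * blocking_analysis(ang).tau + 1)
    # each bin should hold 1/8 of the mass
    frac = counts / counts.sum()
    se = np.sqrt((1 / 8) * (7 / 8) / n_eff)
    assert np.all(np.abs(frac - 1 / 8) < 5 * se + 0.01)


def test_relaxation_dissipates_strain():
    """Metropolis dynamics rapidly relaxes a strongly strained bond down to
    thermal-equipartition energies."""
    from rnadsorb.cg_model import intra_energy
    from rnadsorb.sampler import mc_sweep
    topo = build_topology("..")
    pos = straight_chain(2)
    pos[..., 2] += 3.0
    pos[1, :, 0] += 1.0  # stretch the backbone bond by 1 nm (100 kBT)
    conf = Conformation(pos)
    e0 = intra_energy(conf, topo)
    assert e0 > 80.0
    relaxed = mc_sweep(conf, topo, None, None, None, seed=1, n_sweeps=200)
    e1 = intra_energy(relaxed, topo)
    assert np.isfinite(e1)
    assert e1 < 10.0


def test_toy_chain_starts_near_rest_energy(s1_noss):
    """A freshly grown self-avoiding walk carries < 1 kBT per nucleotide."""
    from rnadsorb.cg_model import intra_energy
    conf = make_toy_chain(22, seed=9)
    assert intra_energy(conf, s1_noss.topology) < 22.0


# ---------------------------------------------------------------------------
# run_window behaviour
# ---------------------------------------------------------------------------

def test_run_window_deterministic(s1_noss):
    wall = DebyeHuckelWall(0.89)
    win = UmbrellaWindow(center=1.5, n_equil=100, n_prod=300, seed=12345)
    a = run_window(s1_noss.topology, None, wall, win, s1_noss.conformation)
    b = run_window(s1_noss.topology, None, wall, win, s1_noss.conformation)
    assert np.array_equal(a.cv_series, b.cv_series)
    assert np.array_equal(a.conformations, b.conformations)


def test_wiss_restraint_preserved_during_sampling(s1_wiss):
    wall = DebyeHuckelWall(1.78)
    win = UmbrellaWindow(center=1.2, n_equil=300, n_prod=1000, seed=5)
    ws = run_window(s1_wiss.topology, None, wall, win, s1_wiss.conformation,
                    s1_wiss.template)
    assert ws.ermsd_trace is not None
    assert ws.ermsd_trace.max() < constants.ERMSD_RESTRAINT_MAX


def test_far_window_mean_matches_center(s1_noss):
    """With no wall attraction the bias dominates: mean CV ~ window center."""
    win = UmbrellaWindow(center=3.5, n_equil=300, n_prod=2000, seed=8)
    ws = run_window(s1_noss.topology, None, DebyeHuckelWall(0.0), win,
                    s1_noss.conformation)
    tau = blocking_analysis(ws.cv_series).tau
    se = ws.cv_series.std() / np.sqrt(len(ws.cv_series) / (2 * tau + 1))
    assert abs(ws.cv_series.mean() - 3.5) < max(3 * se, 0.05)


def test_all_cv_positive(s1_noss):
    wall = DebyeHuckelWall(1.78)
    win = UmbrellaWindow(center=0.5, n_equil=200, n_prod=500, seed=3)
    ws = run_window(s1_noss.topology, None, wall, win, s1_noss.conformation)
    assert np.all(ws.cv_series > 0)


def test_window_validation():
    with pytest.raises(ValueError):
        UmbrellaWindow(center=1.0, spring=-5.0)
    with pytest.raises(ValueError):
        UmbrellaWindow(center=1.0, n_prod=0)
    with pytest.raises(ValueError):
        UmbrellaWindow(center=-1.0)


def test_window_scan_returns_original_order(s1_noss):
    wall = DebyeHuckelWall(0.89)
    wins = [UmbrellaWindow(center=c, n_equil=50, n_prod=100, seed=k)
            for k, c in enumerate([1.0, 2.0, 3.0])]
    out = run_window_scan(s1_noss.topology, None, wall, wins,
                          s1_noss.conformation)
    assert [ws.window.center for ws in out] == [1.0, 2.0, 3.0]


def test_unbiased_run_returns_samples(s1_noss):
    wall = DebyeHuckelWall(1.78)
    init = s1_noss.conformation.at_height(0.8)
    ws = run_unbiased(s1_noss.topology, None, wall, init, n_equil=100,
                      n_prod=400, seed=21)
    assert len(ws.cv_series) == 400
    assert ws.conformations.shape[0] == 40
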