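"""Synthetic RNA fragments and initial 3D coordinates.

Three stand-in fragments mirror the archetypal secondary-structure motifs
of short viral-genome segments probed by chemical mapping:

* ``S1`` -- a 22-nt hairpin with 7 base pairs and a small internal bulge
  (paired fraction 63%),
* ``S2`` -- a 50-nt hairpin with 15 base pairs distributed over several
  bulged stems (60%),
* ``S3`` -- a 36-nt two-hairpin multibranch joined by a single unpaired
  hinge nucleotide, 11 base pairs (61%).

Each fragment exists in a structured ("wiss", stems restrained to A-form)
and an unstructured ("noss", same chain with no base pairs) version.  The
exact dot-brackets are synthetic stand-ins chosen to match the reference
lengths, pair counts and motif descriptions; no real genomic coordinates
are used.

Structured initial coordinates are built analytically: nested stems are
stacked coaxially with ideal A-form geometry, bulges and terminal loops are
laid on outward arcs, and multibranch arms are placed side by side.  The
builder guarantees a clash-free conformation with stems exactly on their
restraint template; residual bond strain at junctions relaxes during
Monte Carlo equilibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants, geometry
from .cg_model import (
    AFormTemplate,
    Conformation,
    FragmentTopology,
    build_topology,
    intra_energy,
)

__all__ = ["FragmentSpec", "Fragment", "FRAGMENT_DOTBRACKETS",
           "make_fragment", "make_toy_chain"]

FRAGMENT_DOTBRACKETS = {
    "S1": "((((.(((....))).))))..",
    "S2": (
        ".." + "(((((" + "." + "((((" + ".." + "(((" + "." + "((("
        + "...." + ")))" + "." + ")))" + "." + "))))" + ".." + ")))))"
        + "......"
    ),
    "S3": "((((((....))))))." + "(((((....)))))" + ".....",
    "toy": "((((....))))",
}

_RISE = constants.AFORM_RISE
_TWIST = constants.AFORM_TWIST


@dataclass(frozen=True)
class FragmentSpec:
    """Descriptive summary of a fragment fixture."""

    label: str
    n_nucleotides: int
    dotbracket: str
    structured: bool
    paired_fraction: float


@dataclass(frozen=True)
class Fragment:
    """A fragment bundle: spec, topology, restraint template, coordinates."""

    spec: FragmentSpec
    topology: FragmentTopology
    template: AFormTemplate | None
    conformation: Conformation


class BuildError(RuntimeError):
    pass


def make_fragment(label: str, structured: bool = True, seed: int = 0) -> Fragment:
    """Construct a fragment fixture with valid initial 3D coordinates.

    Structured fragments start on their A-form template; unstructured ones
    start from a seeded self-avoiding walk.  The returned conformation is
    clash-free with every site above the wall.
    """
    if label not in FRAGMENT_DOTBRACKETS:
        raise KeyError(f"unknown fragment label {label!r}; "
                       f"known: {sorted(FRAGMENT_DOTBRACKETS)}")
    db = FRAGMENT_DOTBRACKETS[label]
    topo = build_topology(db)
    if not structured:
        topo = topo.unstructured()
        template = None
        conf = make_toy_chain(topo.n_nucleotides, seed=seed)
    else:
        template = AFormTemplate(topo)
        conf = _build_structured(topo, template)
    spec = FragmentSpec(
        label=label,
        n_nucleotides=topo.n_nucleotides,
        dotbracket=topo.dotbracket,
        structured=structured,
        paired_fraction=topo.paired_fraction,
    )
    e = intra_energy(conf, topo, template=template)
    if not np.isfinite(e):
        raise BuildError(f"initial conformation of {label} has hard overlaps")
    return Fragment(spec=spec, topology=topo, template=template, conformation=conf)


def make_toy_chain(n: int, seed: int = 0, max_restarts: int = 40) -> Conformation:
    """Self-avoiding random walk of ``n`` rigid nucleotides.

    Bond lengths are exactly at rest (0.6 nm phosphate spacing); chain
    directions wander with a persistence comparable to the bending
    stiffness.  Deterministic for a given seed.
    """
    if n < 2:
        raise ValueError("need at least 2 nucleotides")
    radii = constants.SITE_RADII
    for restart in range(max_restarts):
        rng = np.random.default_rng((seed, restart))
        pos = np.empty((n, 5, 3))
        d = np.array([1.0, 0.0, 0.0])
        pos[0] = _oriented_nucleotide(np.zeros(3), d)
        ok = True
        for i in range(1, n):
            placed = False
            for _ in range(60):
                if i == 1:
                    cand = d
                else:
                    cand = geometry.normalize(d + 0.45 * rng.standard_normal(3))
                p_new = pos[i - 1, 0] + constants.BOND_PP * cand
                # keep the walk inside the simulation slab (z-extent < z_top)
                zs = pos[:i, 0, 2]
                if max(zs.max(), p_new[2]) - min(zs.min(), p_new[2]) > 6.0:
                    continue
                nt = _oriented_nucleotide(p_new, cand)
                if _clashes(pos[:i], nt, i, radii):
                    continue
                pos[i] = nt
                d = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            pos[..., 2] -= pos[..., 2].min() - 0.4
            return Conformation(pos)
    raise BuildError(f"self-avoiding walk placement failed for n={n}")


def _oriented_nucleotide(p, direction):
    """Canonical nucleotide translated to phosphate ``p``, chain axis along
    ``direction``."""
    unit = geometry.canonical_nucleotide()
    d = geometry.normalize(direction)
    up = np.array([0.0, 0.0, 1.0])
    e2 = up - np.dot(up, d) * d
    if np.linalg.norm(e2) < 1e-6:
        probe = np.array([0.0, 1.0, 0.0])
        e2 = probe - np.dot(probe, d) * d
    e2 = geometry.normalize(e2)
    e3 = np.cross(d, e2)
    R = np.column_stack([d, e2, e3])
    return p + unit @ R.T


def _clashes(prev, nt, i, radii) -> bool:
    """Hard-sphere check of candidate nucleotide i against nucleotides < i-1."""
    if i < 2:
        return False
    for j in range(i - 1):
        dvec = prev[j][:, None, :] - nt[None, :, :]
        dist = np.sqrt((dvec ** 2).sum(-1))
        lim = radii[:, None] + radii[None, :]
        if (dist < lim).any():
            return True
    return False


# ---------------------------------------------------------------------------
# structured builder
# ---------------------------------------------------------------------------

def _build_structured(topo: FragmentTopology, template: AFormTemplate) -> Conformation:
    n = topo.n_nucleotides
    pos = np.full((n, 5, 3), np.nan)

    arms = _toplevel_arms(topo)
    spacing = 3.2
    arm_anchors = []
    arm_axes = []
    for k, arm in enumerate(arms):
        arm_pos = _build_arm(topo, arm)
        outer = arm[0][0]  # outermost pair of first stem in the arm
        # orient the arm about its own axis: the anchor that connects to a
        # neighbouring arm should face that neighbour
        if len(arms) > 1:
            if k == 0:
                ref, target = outer[1], 0.0          # exit faces +x
            else:
                ref, target = outer[0], np.pi        # entry faces -x
            phi = np.arctan2(arm_pos[ref][0, 1], arm_pos[ref][0, 0])
            rot = geometry.rotation_matrix([0.0, 0.0, 1.0], target - phi)
            arm_pos = {r: c @ rot.T for r, c in arm_pos.items()}
        shift = np.array([k * spacing, 0.0, 0.0])
        for r, coords in arm_pos.items():
            pos[r] = coords + shift
        arm_anchors.append((outer[0], outer[1]))
        arm_axes.append(shift)

    # hinges between consecutive arms, and 5'/3' tails radiating away from
    # the axis of their own arm
    first_i = arm_anchors[0][0]
    last_j = arm_anchors[-1][1]
    _place_tail(pos, range(first_i - 1, -1, -1), anchor=pos[first_i, 0],
                direction=_radial_dir(pos[first_i, 0],
                                      center=arm_axes[0] + pos[first_i, 0] * [0, 0, 1]))
    _place_tail(pos, range(last_j + 1, n), anchor=pos[last_j, 0],
                direction=_radial_dir(pos[last_j, 0],
                                      center=arm_axes[-1] + pos[last_j, 0] * [0, 0, 1]))
    for k in range(1, len(arms)):
        ja = arm_anchors[k - 1][1]  # last residue of previous arm
        ib = arm_anchors[k][0]      # first residue of this arm
        _place_linker(pos, range(ja + 1, ib), pos[ja, 0], pos[ib, 0])

    if np.isnan(pos).any():
        missing = sorted(set(np.where(np.isnan(pos[:, 0, 0]))[0]))
        raise BuildError(f"builder left residues unplaced: {missing}")

    pos[..., 2] -= pos[..., 2].min() - 0.4
    return Conformation(pos)


def _toplevel_arms(topo: FragmentTopology):
    """Group stems into top-level coaxial arms (nested stem chains)."""
    stems = list(topo.stems)
    arms = []
    used = [False] * len(stems)
    # top-level stems: outermost pair not contained in any other stem's span
    spans = [(s[0][0], s[0][1]) for s in stems]
    for k, (i0, j0) in enumerate(spans):
        if used[k]:
            continue
        if any(oi < i0 and j0 < oj for oi, oj in spans if (oi, oj) != (i0, j0)):
            continue
        # collect the chain of stems nested under stem k
        arm = [stems[k]]
        used[k] = True
        cur = spans[k]
        while True:
            child = None
            for m, (ci, cj) in enumerate(spans):
                if not used[m] and cur[0] < ci and cj < cur[1]:
                    child = m
                    break
            if child is None:
                break
            arm.append(stems[child])
            used[child] = True
            cur = spans[child]
        arms.append(arm)
    arms.sort(key=lambda a: a[0][0][0])
    return arms


def _build_arm(topo: FragmentTopology, arm) -> dict[int, np.ndarray]:
    """Coaxially stacked helices with bulge arcs and a terminal loop, built
    in a local frame with the helix axis along z."""
    coords: dict[int, np.ndarray] = {}
    heights = []
    phases = []
    h, phi = 0.0, 0.0
    for k, stem in enumerate(arm):
        heights.append(h)
        phases.append(phi)
        m = len(stem)
        if k + 1 < len(arm):
            nxt = arm[k + 1]
            la = nxt[0][0] - stem[-1][0] - 1
            lb = stem[-1][1] - nxt[0][1] - 1
            gap = _RISE + 0.28 * max(la, lb)
            # advance the helical phase through the bulge as if it were
            # stacked, which keeps the next stem clear of the junction
            phi += (m + max(la, lb)) * _TWIST
            h += (m - 1) * _RISE + gap
        # place stem residues
        for t, (i, j) in enumerate(stem):
            coords[i] = geometry.helix_residue(t, "A", phases[k], heights[k])
            coords[j] = geometry.helix_residue(t, "B", phases[k], heights[k])

    # bulges between consecutive stems
    for k in range(len(arm) - 1):
        s0, s1 = arm[k], arm[k + 1]
        ie, je = s0[-1]
        isd, jsd = s1[0]
        _place_bulge(coords, range(ie + 1, isd), coords[ie][0], coords[isd][0])
        _place_bulge(coords, range(jsd + 1, je), coords[jsd][0], coords[je][0])

    # terminal loop on the innermost stem
    ie, je = arm[-1][-1]
    _place_terminal_loop(coords, range(ie + 1, je), coords[ie][0], coords[je][0],
                         phases[-1] + (len(arm[-1]) - 1) * _TWIST,
                         heights[-1] + (len(arm[-1]) - 1) * _RISE)
    return coords


def _radial_dir(point, center):
    v = np.asarray(point, dtype=float) - np.asarray(center, dtype=float)
    v[2] = 0.0
    if np.linalg.norm(v) < 1e-9:
        return np.array([1.0, 0.0, 0.0])
    return geometry.normalize(v)


def _unpaired_nucleotide(p, outward):
    """Loop/bulge/tail nucleotide: base points outward, sugar in between."""
    bc = np.asarray(p) + 0.45 * np.asarray(outward)
    tri = geometry.base_triangle(bc, normal=[0.0, 0.0, 1.0], toward=outward)
    s = geometry.place_sugar(p, bc, prefer=np.array([0.0, 0.0, 1.0]))
    return np.vstack([np.asarray(p)[None], s[None], tri])


def _place_bulge(coords, residues, pa, pb):
    residues = list(residues)
    L = len(residues)
    if L == 0:
        return
    push = 0.45 + 0.15 * min(L, 3)
    for l, r in enumerate(residues, start=1):
        s = l / (L + 1)
        base_pt = (1 - s) * pa + s * pb
        outward = _radial_dir(base_pt, center=base_pt * [0, 0, 1])
        p = base_pt + push * np.sin(np.pi * s) * outward
        coords[r] = _unpaired_nucleotide(p, outward)


def _place_terminal_loop(coords, residues, pa, pb, top_phase, top_height):
    residues = list(residues)
    L = len(residues)
    phi_a = np.arctan2(pa[1], pa[0])
    phi_b = np.arctan2(pb[1], pb[0])
    dphi = np.arctan2(np.sin(phi_b - phi_a), np.cos(phi_b - phi_a))
    for l, r in enumerate(residues, start=1):
        s = l / (L + 1)
        phi = phi_a + s * dphi
        z = top_height + 0.35 + 0.45 * np.sin(np.pi * s)
        p = np.array([constants.AFORM_R_P * np.cos(phi),
                      constants.AFORM_R_P * np.sin(phi), z])
        outward = np.array([np.cos(phi), np.sin(phi), 0.0])
        coords[r] = _unpaired_nucleotide(p, outward)


def _place_tail(pos, residues, anchor, direction):
    """Unpaired tail extending outward from an anchor phosphate; bases point
    sideways so they stay clear of the following backbone beads."""
    residues = list(residues)
    d = geometry.normalize(np.asarray(direction, dtype=float))
    side = np.cross(d, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(side) < 1e-6:
        side = np.array([1.0, 0.0, 0.0])
    side = geometry.normalize(side)
    for l, r in enumerate(residues, start=1):
        p = np.asarray(anchor) + l * 0.55 * d + l * np.array([0.0, 0.0, -0.05])
        pos[r] = _unpaired_nucleotide(p, side)


def _place_linker(pos, residues, pa, pb):
    """Hinge nucleotides on the straight path between two arm anchors,
    displaced sideways to clear both helices."""
    residues = list(residues)
    L = len(residues)
    if L == 0:
        return
    side = np.array([0.0, 1.0, 0.0])
    for l, r in enumerate(residues, start=1):
        s = l / (L + 1)
        p = (1 - s) * pa + s * pb + 0.9 * np.sin(np.pi * s) * side
        pos[r] = _unpaired_nucleotide(p, side)
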