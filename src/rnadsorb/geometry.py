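"""Analytic construction helpers: rigid-body math, base triangles, A-form helix.

The ideal A-form double helix built here serves two purposes: it provides
the reference base-site coordinates against which stem eRMSD restraints are
measured, and it seeds the initial 3D coordinates of structured fragments.
Only the base sites enter the restraint; phosphates and sugars are attached
with intra-nucleotide bond lengths exactly at their rest values so that a
freshly built helix carries no spurious bond strain.
"""

from __future__ import annotations

import numpy as np

from .constants import (
    AFORM_P_DROP,
    AFORM_P_PHASE,
    AFORM_PAIR_PHASE,
    AFORM_PAIR_RISE,
    AFORM_R_B,
    AFORM_R_P,
    AFORM_RISE,
    AFORM_TWIST,
    BASE_CIRCUMRADIUS,
    BOND_PP,
    BOND_PS,
    BOND_SB,
)


def normalize(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize zero vector")
    return v / n


def rotation_matrix(axis, angle: float) -> np.ndarray:
    """Right-handed rotation about ``axis`` by ``angle`` (Rodrigues form)."""
    a = normalize(axis)
    c, s = np.cos(angle), np.sin(angle)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(a, a)


def base_triangle(center, normal, toward) -> np.ndarray:
    """Equilateral base triangle (3, 3) with the first vertex pointing
    ``toward`` (projected into the base plane)."""
    n = normalize(normal)
    t = np.asarray(toward, dtype=float)
    e1 = t - np.dot(t, n) * n
    if np.linalg.norm(e1) < 1e-9:
        # toward parallel to normal; pick any in-plane direction
        probe = np.array([1.0, 0.0, 0.0])
        e1 = probe - np.dot(probe, n) * n
    e1 = normalize(e1)
    e2 = np.cross(n, e1)
    ang = 2.0 * np.pi / 3.0
    verts = [
        np.asarray(center) + BASE_CIRCUMRADIUS * (np.cos(k * ang) * e1 + np.sin(k * ang) * e2)
        for k in range(3)
    ]
    return np.array(verts)


def place_sugar(p, bc, prefer) -> np.ndarray:
    """Sugar position with |S-P| = BOND_PS and |S-Bc| = BOND_SB exactly.

    The two-sphere intersection circle is resolved by choosing the point
    closest to the ``prefer`` direction.  If the spheres do not intersect
    (anchors too far/too close) the sugar falls back onto the P-Bc segment,
    leaving a small bond strain that relaxes during equilibration.
    """
    p = np.asarray(p, dtype=float)
    bc = np.asarray(bc, dtype=float)
    d = bc - p
    L = np.linalg.norm(d)
    r1, r2 = BOND_PS, BOND_SB
    if L >= (r1 + r2) * 0.999 or L <= abs(r1 - r2) * 1.001 or L < 1e-9:
        if L < 1e-9:
            return p + np.array([0.0, 0.0, r1])
        return p + d * (r1 / (r1 + r2))
    dhat = d / L
    a = (L * L + r1 * r1 - r2 * r2) / (2.0 * L)
    h = np.sqrt(max(r1 * r1 - a * a, 0.0))
    center = p + a * dhat
    w = np.asarray(prefer, dtype=float)
    w = w - np.dot(w, dhat) * dhat
    if np.linalg.norm(w) < 1e-9:
        probe = np.array([0.0, 0.0, 1.0])
        w = probe - np.dot(probe, dhat) * dhat
        if np.linalg.norm(w) < 1e-9:
            w = np.array([1.0, 0.0, 0.0])
    w = normalize(w)
    return center + h * w


def canonical_nucleotide() -> np.ndarray:
    """One nucleotide (5, 3) with P at the origin and the chain along +x.

    P-S and S-base bonds are at their rest lengths; the base triangle lies
    in the plane normal to the chain axis, pointing away from the backbone.
    """
    p = np.zeros(3)
    s = np.array([0.5 * BOND_PS, np.sqrt(3.0) / 2.0 * BOND_PS, 0.0])
    bc = s + np.array([0.0, BOND_SB, 0.0])
    tri = base_triangle(bc, normal=[1.0, 0.0, 0.0], toward=[0.0, 1.0, 0.0])
    return np.vstack([p[None], s[None], tri])


def straight_chain(n: int, spacing: float = BOND_PP) -> np.ndarray:
    """Straight relaxed chain (n, 5, 3): bonds and angles at rest, no overlap."""
    unit = canonical_nucleotide()
    pos = np.empty((n, 5, 3))
    for i in range(n):
        pos[i] = unit + np.array([i * spacing, 0.0, 0.0])
    return pos


def helix_residue(step: int, strand: str, start_phase: float = 0.0,
                  start_height: float = 0.0) -> np.ndarray:
    """Five-site coordinates of one A-form residue.

    ``step`` indexes base pairs from the helix bottom; ``strand`` is "A"
    (5'->3' running up) or "B" (the antiparallel partner strand).
    """
    phi = start_phase + step * AFORM_TWIST
    h = start_height + step * AFORM_RISE
    if strand == "A":
        phib, hb, sgn = phi, h, 1.0
    else:
        phib = phi + AFORM_PAIR_PHASE
        hb = h + AFORM_PAIR_RISE
        sgn = -1.0
    bc = np.array([AFORM_R_B * np.cos(phib), AFORM_R_B * np.sin(phib), hb])
    pphi = phib + sgn * AFORM_P_PHASE
    p = np.array([
        AFORM_R_P * np.cos(pphi),
        AFORM_R_P * np.sin(pphi),
        hb - sgn * AFORM_P_DROP,
    ])
    normal = np.array([0.0, 0.0, sgn])
    toward = -np.array([np.cos(phib), np.sin(phib), 0.0])  # radially inward
    tri = base_triangle(bc, normal=normal, toward=toward)
    s = place_sugar(p, bc, prefer=np.array([np.cos(phib), np.sin(phib), 0.5 * sgn]))
    return np.vstack([p[None], s[None], tri])


def aform_duplex(n_bp: int, start_phase: float = 0.0,
                 start_height: float = 0.0):
    """Ideal A-form duplex: two (n_bp, 5, 3) arrays for strands A and B.

    Index t on strand B is the partner of index t on strand A (so strand B
    in chain order runs from high t to low t).
    """
    a = np.empty((n_bp, 5, 3))
    b = np.empty((n_bp, 5, 3))
    for t in range(n_bp):
        a[t] = helix_residue(t, "A", start_phase, start_height)
        b[t] = helix_residue(t, "B", start_phase, start_height)
    return a, b


def min_site_distance(pos: np.ndarray, skip_adjacent: bool = True) -> float:
    """Smallest inter-site distance between nucleotides |i-j| >= 2 (or >= 1)."""
    n = pos.shape[0]
    flat = pos.reshape(n * 5, 3)
    best = np.inf
    gap = 2 if skip_adjacent else 1
    for i in range(n):
        for j in range(i + gap, n):
            d = flat[i * 5:(i + 1) * 5, None, :] - flat[j * 5:(j + 1) * 5][None, :, :]
            m = np.sqrt((d ** 2).sum(-1)).min()
            if m < best:
                best = m
    return float(best)
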