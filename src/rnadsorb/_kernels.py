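"""Numba-compiled numerical kernels for energies and Monte Carlo sampling.

The kernels operate on plain arrays:

* ``pos`` -- conformation coordinates, shape ``(n_nt, 5, 3)`` with site
  order P, S, B1, B2, B3 (nm).
* ``p`` -- force-field parameter vector, see :data:`PARAM_LAYOUT`.
* stems are encoded as ``stem_res`` (concatenated residue indices) with
  ``stem_off`` offsets, plus the flattened template G-vector tensors
  ``gt_flat`` / ``gt_off`` used by the eRMSD restraint.
* walls are encoded as an integer type tag plus a 4-vector of parameters
  (see :mod:`rnadsorb.surface`).

Everything here is deterministic given the RNG seed passed to ``run_mc``.
"""

import numpy as np
from numba import njit

from .constants import (
    ERMSD_CUTOFF,
    ERMSD_GAMMA,
    ERMSD_SCALE_XY,
    ERMSD_SCALE_Z,
)

# p-vector layout: [k_pp, r_pp, k_ps, r_ps, k_sb, r_sb, k_ang, theta0, k_ss, z_top]
PARAM_LAYOUT = (
    "k_bond_pp", "bond_pp", "k_bond_ps", "bond_ps", "k_bond_sb", "bond_sb",
    "k_angle", "angle0", "k_ss", "z_top",
)

_MIE_PREF = 3.0 * np.sqrt(3.0) / 2.0

# move-type indices
MOVE_TRANS = 0
MOVE_ROT = 1
MOVE_CRANK = 2
MOVE_CHAIN_Z = 3
MOVE_CHAIN_ROT = 4
N_MOVE_TYPES = 5


@njit(cache=True)
def wall_u(wtype, wp, z):
    """Wall potential at height z > 0 (kBT)."""
    if wtype == 0:
        return 0.0
    if wtype == 1:  # Debye-Hueckel-like
        return wp[1] * (wp[2] / z) ** 12 - wp[0] * np.exp(-z / wp[3])
    if wtype == 2:  # Mie 9-3
        s = wp[1] / z
        return wp[0] * _MIE_PREF * ((2.0 / 15.0) * s**9 - s**3)
    # square well
    if z < wp[1]:
        return -wp[0]
    return 0.0


@njit(cache=True)
def base_gmat(bases):
    """G-vector matrix for a set of base triangles.

    ``bases`` has shape (m, 3, 3): m residues, three base sites each.
    Returns the (m, m, 4) array of anisotropically scaled, smoothly
    truncated relative-position vectors (zero outside the cutoff).
    """
    m = bases.shape[0]
    cen = np.empty((m, 3))
    rot = np.empty((m, 3, 3))  # rows: local x, y, z axes
    for i in range(m):
        for k in range(3):
            cen[i, k] = (bases[i, 0, k] + bases[i, 1, k] + bases[i, 2, k]) / 3.0
        xv = bases[i, 0] - cen[i]
        xn = np.sqrt(xv[0] ** 2 + xv[1] ** 2 + xv[2] ** 2)
        xv = xv / xn
        v2 = bases[i, 1] - cen[i]
        zv = np.empty(3)
        zv[0] = xv[1] * v2[2] - xv[2] * v2[1]
        zv[1] = xv[2] * v2[0] - xv[0] * v2[2]
        zv[2] = xv[0] * v2[1] - xv[1] * v2[0]
        zn = np.sqrt(zv[0] ** 2 + zv[1] ** 2 + zv[2] ** 2)
        zv = zv / zn
        yv = np.empty(3)
        yv[0] = zv[1] * xv[2] - zv[2] * xv[1]
        yv[1] = zv[2] * xv[0] - zv[0] * xv[2]
        yv[2] = zv[0] * xv[1] - zv[1] * xv[0]
        rot[i, 0] = xv
        rot[i, 1] = yv
        rot[i, 2] = zv
    g = np.zeros((m, m, 4))
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            d0 = cen[j, 0] - cen[i, 0]
            d1 = cen[j, 1] - cen[i, 1]
            d2 = cen[j, 2] - cen[i, 2]
            dx = (rot[i, 0, 0] * d0 + rot[i, 0, 1] * d1 + rot[i, 0, 2] * d2) / ERMSD_SCALE_XY
            dy = (rot[i, 1, 0] * d0 + rot[i, 1, 1] * d1 + rot[i, 1, 2] * d2) / ERMSD_SCALE_XY
            dz = (rot[i, 2, 0] * d0 + rot[i, 2, 1] * d1 + rot[i, 2, 2] * d2) / ERMSD_SCALE_Z
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < ERMSD_CUTOFF and r > 1e-12:
                s = np.sin(ERMSD_GAMMA * r) / (r * ERMSD_GAMMA)
                g[i, j, 0] = s * dx
                g[i, j, 1] = s * dy
                g[i, j, 2] = s * dz
                g[i, j, 3] = (1.0 + np.cos(ERMSD_GAMMA * r)) / ERMSD_GAMMA
    return g


@njit(cache=True)
def ermsd_sq_between(g1, g2):
    """Squared eRMSD from two G-vector matrices over the same residue set."""
    m = g1.shape[0]
    acc = 0.0
    for i in range(m):
        for j in range(m):
            for k in range(4):
                d = g1[i, j, k] - g2[i, j, k]
                acc += d * d
    return acc / m


@njit(cache=True)
def stem_ermsd_sq(pos, res, gt):
    """Squared eRMSD of one stem against its (precomputed) template G-matrix."""
    m = res.shape[0]
    bases = np.empty((m, 3, 3))
    for a in range(m):
        i = res[a]
        for s in range(3):
            for k in range(3):
                bases[a, s, k] = pos[i, 2 + s, k]
    g = base_gmat(bases)
    return ermsd_sq_between(g, gt)


@njit(cache=True)
def restraint_energy_kernel(pos, p, stem_off, stem_res, gt_flat, gt_off):
    n_stem = stem_off.shape[0] - 1
    e = 0.0
    for s in range(n_stem):
        res = stem_res[stem_off[s]:stem_off[s + 1]]
        m = res.shape[0]
        gt = gt_flat[gt_off[s]:gt_off[s + 1]].reshape(m, m, 4)
        e += p[8] * stem_ermsd_sq(pos, res, gt)
    return e


@njit(cache=True)
def max_stem_ermsd(pos, stem_off, stem_res, gt_flat, gt_off):
    n_stem = stem_off.shape[0] - 1
    worst = 0.0
    for s in range(n_stem):
        res = stem_res[stem_off[s]:stem_off[s + 1]]
        m = res.shape[0]
        gt = gt_flat[gt_off[s]:gt_off[s + 1]].reshape(m, m, 4)
        v = np.sqrt(stem_ermsd_sq(pos, res, gt))
        if v > worst:
            worst = v
    return worst


@njit(cache=True)
def intra_energy_kernel(pos, p, radii, stem_off, stem_res, gt_flat, gt_off):
    """Bond + angle + hard-sphere + restraint energy; inf on any violation."""
    n = pos.shape[0]
    # wall plane and hard upper boundary
    for i in range(n):
        for s in range(5):
            z = pos[i, s, 2]
            if z <= 0.0 or z >= p[9]:
                return np.inf
    # hard-sphere excluded volume between nucleotides |i-j| >= 2
    for i in range(n):
        for j in range(i + 2, n):
            for si in range(5):
                for sj in range(5):
                    dx = pos[i, si, 0] - pos[j, sj, 0]
                    dy = pos[i, si, 1] - pos[j, sj, 1]
                    dz = pos[i, si, 2] - pos[j, sj, 2]
                    rc = radii[si] + radii[sj]
                    if dx * dx + dy * dy + dz * dz < rc * rc:
                        return np.inf
    e = 0.0
    # backbone P-P bonds
    for i in range(n - 1):
        dx = pos[i, 0, 0] - pos[i + 1, 0, 0]
        dy = pos[i, 0, 1] - pos[i + 1, 0, 1]
        dz = pos[i, 0, 2] - pos[i + 1, 0, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz) - p[1]
        e += 0.5 * p[0] * d * d
    # intra-nucleotide P-S and S-(base centroid) bonds
    for i in range(n):
        dx = pos[i, 0, 0] - pos[i, 1, 0]
        dy = pos[i, 0, 1] - pos[i, 1, 1]
        dz = pos[i, 0, 2] - pos[i, 1, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz) - p[3]
        e += 0.5 * p[2] * d * d
        bx = (pos[i, 2, 0] + pos[i, 3, 0] + pos[i, 4, 0]) / 3.0
        by = (pos[i, 2, 1] + pos[i, 3, 1] + pos[i, 4, 1]) / 3.0
        bz = (pos[i, 2, 2] + pos[i, 3, 2] + pos[i, 4, 2]) / 3.0
        dx = pos[i, 1, 0] - bx
        dy = pos[i, 1, 1] - by
        dz = pos[i, 1, 2] - bz
        d = np.sqrt(dx * dx + dy * dy + dz * dz) - p[5]
        e += 0.5 * p[4] * d * d
    # backbone bending angles
    for i in range(1, n - 1):
        ax = pos[i - 1, 0, 0] - pos[i, 0, 0]
        ay = pos[i - 1, 0, 1] - pos[i, 0, 1]
        az = pos[i - 1, 0, 2] - pos[i, 0, 2]
        bx = pos[i + 1, 0, 0] - pos[i, 0, 0]
        by = pos[i + 1, 0, 1] - pos[i, 0, 1]
        bz = pos[i + 1, 0, 2] - pos[i, 0, 2]
        na = np.sqrt(ax * ax + ay * ay + az * az)
        nb = np.sqrt(bx * bx + by * by + bz * bz)
        c = (ax * bx + ay * by + az * bz) / (na * nb)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        d = np.arccos(c) - p[7]
        e += 0.5 * p[6] * d * d
    # secondary-structure restraints
    e += restraint_energy_kernel(pos, p, stem_off, stem_res, gt_flat, gt_off)
    return e


@njit(cache=True)
def surface_energy_kernel(pos, wtype, wp):
    n = pos.shape[0]
    e = 0.0
    for i in range(n):
        e += wall_u(wtype, wp, pos[i, 0, 2])
    return e


@njit(cache=True)
def com_z(pos):
    n = pos.shape[0]
    acc = 0.0
    for i in range(n):
        for s in range(5):
            acc += pos[i, s, 2]
    return acc / (5.0 * n)


@njit(cache=True)
def total_energy_kernel(pos, p, radii, stem_off, stem_res, gt_flat, gt_off,
                        wtype, wp, ku, d0):
    e = intra_energy_kernel(pos, p, radii, stem_off, stem_res, gt_flat, gt_off)
    if not np.isfinite(e):
        return np.inf
    e += surface_energy_kernel(pos, wtype, wp)
    if ku > 0.0:
        d = com_z(pos) - d0
        e += 0.5 * ku * d * d
    return e


@njit(cache=True)
def _rotate_block(pos, i0, i1, px, py, pz, ax, ay, az, ang):
    """Rodrigues rotation of nucleotides i0..i1-1 about point p, axis a."""
    c = np.cos(ang)
    s = np.sin(ang)
    for i in range(i0, i1):
        for site in range(5):
            vx = pos[i, site, 0] - px
            vy = pos[i, site, 1] - py
            vz = pos[i, site, 2] - pz
            dot = ax * vx + ay * vy + az * vz
            cx = ay * vz - az * vy
            cy = az * vx - ax * vz
            cz = ax * vy - ay * vx
            pos[i, site, 0] = px + vx * c + cx * s + ax * dot * (1.0 - c)
            pos[i, site, 1] = py + vy * c + cy * s + ay * dot * (1.0 - c)
            pos[i, site, 2] = pz + vz * c + cz * s + az * dot * (1.0 - c)


@njit(cache=True)
def _rand_axis():
    while True:
        ax = np.random.normal()
        ay = np.random.normal()
        az = np.random.normal()
        n = np.sqrt(ax * ax + ay * ay + az * az)
        if n > 1e-8:
            return ax / n, ay / n, az / n


@njit(cache=True)
def run_mc(pos, p, radii, stem_off, stem_res, gt_flat, gt_off,
           wtype, wp, ku, d0,
           n_equil, n_prod, stride, seed, amps, move_probs,
           tune, track_ermsd):
    """Metropolis Monte Carlo run; returns CV series, snapshots, statistics.

    One sweep attempts ``n_nt + 2`` moves drawn from {single-nucleotide
    rigid translation, single-nucleotide rigid rotation, crankshaft,
    whole-chain z-translation, whole-chain rotation about the centre of
    mass}.  During equilibration (if ``tune``) amplitudes are adjusted
    toward ~40% acceptance every 50 sweeps and then frozen.

    Returns
    -------
    cv : (n_prod,) centre-of-mass height after each production sweep
    snaps : (n_snap, n, 5, 3) conformations stored every ``stride`` sweeps
    acc : (5,) accepted moves per type (production only)
    att : (5,) attempted moves per type (production only)
    ermsd_trace : (n_prod,) max stem eRMSD per sweep (zeros if not tracked)
    amps : final move amplitudes
    """
    np.random.seed(seed)
    n = pos.shape[0]
    cum = np.empty(N_MOVE_TYPES)
    acc_total = 0.0
    probs = move_probs.copy()
    if n < 3:
        probs[MOVE_TRANS] += probs[MOVE_CRANK]
        probs[MOVE_CRANK] = 0.0
    for k in range(N_MOVE_TYPES):
        acc_total += probs[k]
    run = 0.0
    for k in range(N_MOVE_TYPES):
        run += probs[k] / acc_total
        cum[k] = run

    e_cur = total_energy_kernel(pos, p, radii, stem_off, stem_res, gt_flat,
                                gt_off, wtype, wp, ku, d0)
    old = np.empty_like(pos)
    n_sweeps = n_equil + n_prod
    moves_per_sweep = n + 2
    n_snap = n_prod // stride
    cv = np.empty(n_prod)
    snaps = np.empty((n_snap, n, 5, 3))
    ermsd_trace = np.zeros(n_prod)
    acc = np.zeros(N_MOVE_TYPES)
    att = np.zeros(N_MOVE_TYPES)
    acc_t = np.zeros(N_MOVE_TYPES)
    att_t = np.zeros(N_MOVE_TYPES)
    snap_idx = 0

    for sweep in range(n_sweeps):
        in_prod = sweep >= n_equil
        for _ in range(moves_per_sweep):
            u = np.random.random()
            mt = 0
            for k in range(N_MOVE_TYPES):
                if u <= cum[k]:
                    mt = k
                    break
            for i in range(n):
                for s in range(5):
                    old[i, s, 0] = pos[i, s, 0]
                    old[i, s, 1] = pos[i, s, 1]
                    old[i, s, 2] = pos[i, s, 2]
            if mt == MOVE_TRANS:
                i = np.random.randint(n)
                dx = (2.0 * np.random.random() - 1.0) * amps[0]
                dy = (2.0 * np.random.random() - 1.0) * amps[0]
                dz = (2.0 * np.random.random() - 1.0) * amps[0]
                for s in range(5):
                    pos[i, s, 0] += dx
                    pos[i, s, 1] += dy
                    pos[i, s, 2] += dz
            elif mt == MOVE_ROT:
                i = np.random.randint(n)
                ax, ay, az = _rand_axis()
                ang = (2.0 * np.random.random() - 1.0) * amps[1]
                cx = 0.0
                cy = 0.0
                cz = 0.0
                for s in range(5):
                    cx += pos[i, s, 0]
                    cy += pos[i, s, 1]
                    cz += pos[i, s, 2]
                _rotate_block(pos, i, i + 1, cx / 5.0, cy / 5.0, cz / 5.0,
                              ax, ay, az, ang)
            elif mt == MOVE_CRANK:
                i = np.random.randint(n - 2)
                jmax = i + 8
                if jmax > n - 1:
                    jmax = n - 1
                j = i + 2 + np.random.randint(jmax - i - 1)
                ax = pos[j, 0, 0] - pos[i, 0, 0]
                ay = pos[j, 0, 1] - pos[i, 0, 1]
                az = pos[j, 0, 2] - pos[i, 0, 2]
                an = np.sqrt(ax * ax + ay * ay + az * az)
                if an < 1e-9:
                    att[mt] += 0.0
                    continue
                ang = (2.0 * np.random.random() - 1.0) * amps[2]
                _rotate_block(pos, i + 1, j, pos[i, 0, 0], pos[i, 0, 1],
                              pos[i, 0, 2], ax / an, ay / an, az / an, ang)
            elif mt == MOVE_CHAIN_Z:
                dz = (2.0 * np.random.random() - 1.0) * amps[3]
                for i in range(n):
                    for s in range(5):
                        pos[i, s, 2] += dz
            else:  # MOVE_CHAIN_ROT
                ax, ay, az = _rand_axis()
                ang = (2.0 * np.random.random() - 1.0) * amps[4]
                cx = 0.0
                cy = 0.0
                cz = 0.0
                for i in range(n):
                    for s in range(5):
                        cx += pos[i, s, 0]
                        cy += pos[i, s, 1]
                        cz += pos[i, s, 2]
                m = 5.0 * n
                _rotate_block(pos, 0, n, cx / m, cy / m, cz / m,
                              ax, ay, az, ang)

            e_new = total_energy_kernel(pos, p, radii, stem_off, stem_res,
                                        gt_flat, gt_off, wtype, wp, ku, d0)
            accept = False
            if np.isfinite(e_new):
                de = e_new - e_cur
                if de <= 0.0 or np.random.random() < np.exp(-de):
                    accept = True
            att_t[mt] += 1.0
            if in_prod:
                att[mt] += 1.0
            if accept:
                e_cur = e_new
                acc_t[mt] += 1.0
                if in_prod:
                    acc[mt] += 1.0
            else:
                for i in range(n):
                    for s in range(5):
                        pos[i, s, 0] = old[i, s, 0]
                        pos[i, s, 1] = old[i, s, 1]
                        pos[i, s, 2] = old[i, s, 2]

        if tune and (not in_prod) and (sweep + 1) % 50 == 0:
            for k in range(N_MOVE_TYPES):
                if att_t[k] > 0:
                    rate = acc_t[k] / att_t[k]
                    f = rate / 0.4
                    if f < 0.5:
                        f = 0.5
                    elif f > 2.0:
                        f = 2.0
                    amps[k] *= f
                    if k == 1 or k == 2 or k == 4:
                        hi = np.pi
                    else:
                        hi = 1.5
                    if amps[k] > hi:
                        amps[k] = hi
                    elif amps[k] < 0.01:
                        amps[k] = 0.01
                acc_t[k] = 0.0
                att_t[k] = 0.0

        if in_prod:
            t = sweep - n_equil
            cv[t] = com_z(pos)
            if track_ermsd and stem_off.shape[0] > 1:
                ermsd_trace[t] = max_stem_ermsd(pos, stem_off, stem_res,
                                                gt_flat, gt_off)
            if (t + 1) % stride == 0 and snap_idx < n_snap:
                for i in range(n):
                    for s in range(5):
                        snaps[snap_idx, i, s, 0] = pos[i, s, 0]
                        snaps[snap_idx, i, s, 1] = pos[i, s, 1]
                        snaps[snap_idx, i, s, 2] = pos[i, s, 2]
                snap_idx += 1

    return cv, snaps, acc, att, ermsd_trace, amps
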