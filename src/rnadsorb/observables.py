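"""Structural and energetic observables of adsorbed RNA ensembles.

* The per-monomer contact fraction is defined through the normalised
  attractive surface energy,

      phi = (1 / eps_min) * integral rho(z) * U_a(z) dz,
      U_a(z) = min{0, U_surf(z)},

  where rho(z) is the phosphate height distribution of bound
  conformations (normalised to unit integral) and eps_min the depth of
  the wall potential.  For a square-well wall phi is exactly the fraction
  of monomers inside the well.  The contact *number* is N_phosphates * phi.

* The radius of gyration is decomposed into its in-plane and normal
  components, Rg_par^2 = <(x - xbar)^2 + (y - ybar)^2> and
  Rg_perp^2 = <(z - zbar)^2>, whose ratio measures the flattening of the
  adsorbed chain (0.5 for an isotropic ensemble).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .surface import wall_energy, wall_minimum

__all__ = ["MonomerDensity", "GyrationComponents", "ContactResult",
           "monomer_density", "contact_number", "gyration_components",
           "ensemble_gyration", "is_bound", "BOUND_ENERGY_CUTOFF"]

# a conformation is "bound" when its total surface energy is below this
BOUND_ENERGY_CUTOFF = -0.5  # kBT


@dataclass
class MonomerDensity:
    """Normalised phosphate height distribution of bound conformations."""

    z: np.ndarray        # bin centers, nm
    rho: np.ndarray      # 1/nm, trapezoid-normalised to 1
    bound_criterion: str = f"surface energy < {BOUND_ENERGY_CUTOFF} kBT"

    def __post_init__(self):
        if np.any(self.rho < 0):
            raise ValueError("density must be non-negative")
        norm = np.trapezoid(self.rho, self.z)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"density integrates to {norm}, expected 1")


@dataclass(frozen=True)
class GyrationComponents:
    """Squared radius-of-gyration components (nm^2) and their ratio."""

    rg2_parallel: float
    rg2_perpendicular: float

    def __post_init__(self):
        if self.rg2_parallel < 0 or self.rg2_perpendicular < 0:
            raise ValueError("gyration components must be non-negative")

    @property
    def ratio(self) -> float:
        return self.rg2_perpendicular / self.rg2_parallel


@dataclass(frozen=True)
class ContactResult:
    contact_fraction: float   # phi in [0, 1]
    contact_number: float     # N_phosphates * phi


def is_bound(snapshot: np.ndarray, wall) -> bool:
    """Bound-state criterion: total wall energy below the cutoff."""
    e = float(np.sum(wall.energy(snapshot[:, 0, 2])))
    return e < BOUND_ENERGY_CUTOFF


def monomer_density(window_samples, wall, bin_width: float = 0.02,
                    z_max: float | None = None) -> MonomerDensity:
    """Phosphate z-histogram over bound conformations, normalised to 1.

    ``window_samples`` is an iterable of :class:`WindowSamples` (or any
    objects with a ``conformations`` array); conformations are classified
    bound by their total surface energy.
    """
    zs = []
    for ws in window_samples:
        for snap in ws.conformations:
            if is_bound(snap, wall):
                zs.append(snap[:, 0, 2])
    if not zs:
        raise ValueError(
            "no bound conformations found (criterion: surface energy < "
            f"{BOUND_ENERGY_CUTOFF} kBT); sample closer to the wall or "
            "increase the attraction"
        )
    zs = np.concatenate(zs)
    hi = z_max if z_max is not None else zs.max() + bin_width
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, edges = np.histogram(zs, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rho = counts.astype(float)
    norm = np.trapezoid(rho, centers)
    if norm <= 0:
        raise ValueError("degenerate phosphate histogram")
    return MonomerDensity(z=centers, rho=rho / norm)


def contact_number(density: MonomerDensity, wall, n_phosphates: int) -> ContactResult:
    """Per-monomer contact fraction and contact number from the monomer
    density and the wall potential (exact for a square-well wall)."""
    wm = wall_minimum(wall)
    if wm is None:
        raise ValueError("contact fraction requires an attractive wall")
    pos = density.z > 0
    if np.any(density.rho[~pos] > 0):
        raise ValueError("density has weight at z <= 0")
    u_a = np.zeros_like(density.z)
    u_a[pos] = np.minimum(0.0, wall_energy(wall, density.z[pos]))
    phi = float(np.trapezoid(density.rho * u_a, density.z) / wm.eps_min)
    return ContactResult(contact_fraction=phi, contact_number=n_phosphates * phi)


def gyration_components(coords: np.ndarray) -> GyrationComponents:
    """Gyration components of a single conformation over all sites.

    ``coords`` is (n_sites, 3) or (n_nt, 5, 3); all sites enter with equal
    weight.
    """
    xyz = np.asarray(coords, dtype=float).reshape(-1, 3)
    if xyz.shape[0] < 2:
        raise ValueError("gyration needs at least two sites")
    d = xyz - xyz.mean(axis=0)
    return GyrationComponents(
        rg2_parallel=float(np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)),
        rg2_perpendicular=float(np.mean(d[:, 2] ** 2)),
    )


def ensemble_gyration(snapshots, wall=None, bound_only: bool = False
                      ) -> GyrationComponents:
    """Ensemble-averaged gyration components: each component is averaged
    over conformations before the ratio is formed."""
    par, perp = [], []
    for snap in snapshots:
        if bound_only and wall is not None and not is_bound(snap, wall):
            continue
        g = gyration_components(snap)
        par.append(g.rg2_parallel)
        perp.append(g.rg2_perpendicular)
    if not par:
        raise ValueError("no conformations to average (bound filter too strict?)")
    return GyrationComponents(rg2_parallel=float(np.mean(par)),
                              rg2_perpendicular=float(np.mean(perp)))
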