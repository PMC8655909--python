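"""One-dimensional wall potentials acting on the RNA phosphate beads.

The substrate is a flat, featureless plane at z = 0.  Three families of wall
potential are provided:

* :class:`DebyeHuckelWall` -- a screened electrostatic attraction of range
  ``lambda_D`` combined with a steep short-range Lennard-Jones-type
  repulsion activated at ``lambda_r``:

      U(z) = eps_r * (lambda_r / z)**12 - eps_surf * exp(-z / lambda_D)

* :class:`MieWall` -- the wall-integrated Mie 9-3 potential, a
  van-der-Waals-type alternative used to check that the adsorption
  phenomenology is not specific to the electrostatic form.

* :class:`SquareWellWall` -- an idealised well of given depth and width, for
  which several observables (e.g. the contact fraction) are exactly known;
  used as an analytic reference.

Only phosphates feel the wall attraction; sugar and base sites merely may
not cross the plane (enforced by the sampler).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "DebyeHuckelWall",
    "MieWall",
    "SquareWellWall",
    "WallMinimum",
    "wall_energy",
    "wall_minimum",
    "surface_energy",
]

# integer tags used by the Monte Carlo kernels
WALL_NONE = 0
WALL_DEBYE_HUCKEL = 1
WALL_MIE = 2
WALL_SQUARE_WELL = 3

_MIE_PREFACTOR = 3.0 * np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class WallMinimum:
    """Location and depth of the attractive minimum of a wall potential."""

    z_min: float  # nm
    eps_min: float  # kBT, most negative value of the potential


@dataclass(frozen=True)
class DebyeHuckelWall:
    """Screened-electrostatic wall with short-range repulsion.

    Parameters
    ----------
    eps_surf:
        Attraction strength in kBT; the quantity scanned in adsorption
        studies (typically 0.44-1.78 kBT).
    eps_r:
        Repulsion amplitude in kBT (default 1).
    lambda_r:
        Activation distance of the repulsive term in nm (default 0.1,
        well below the 0.3 nm phosphate radius).
    lambda_d:
        Debye screening length in nm (default 1, physiological salt).
    """

    eps_surf: float
    eps_r: float = 1.0
    lambda_r: float = 0.1
    lambda_d: float = 1.0

    def __post_init__(self) -> None:
        if self.eps_surf < 0:
            raise ValueError("eps_surf must be non-negative")
        if not self.lambda_r < self.lambda_d:
            raise ValueError("lambda_r must be smaller than lambda_D")

    def energy(self, z):
        z = _check_z(z)
        return self.eps_r * (self.lambda_r / z) ** 12 - self.eps_surf * np.exp(
            -z / self.lambda_d
        )

    @property
    def attractive(self) -> bool:
        return self.eps_surf > 0

    def kernel_params(self):
        return WALL_DEBYE_HUCKEL, np.array(
            [self.eps_surf, self.eps_r, self.lambda_r, self.lambda_d]
        )


@dataclass(frozen=True)
class MieWall:
    """Wall-integrated Mie 9-3 potential.

    U(z) = eps * (3*sqrt(3)/2) * [(2/15)(sigma/z)^9 - (sigma/z)^3]

    The prefactor normalises the well depth to ``-eps``.
    """

    eps: float
    sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.eps < 0:
            raise ValueError("eps must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def energy(self, z):
        z = _check_z(z)
        s = self.sigma / z
        return self.eps * _MIE_PREFACTOR * ((2.0 / 15.0) * s**9 - s**3)

    @property
    def attractive(self) -> bool:
        return self.eps > 0

    def kernel_params(self):
        return WALL_MIE, np.array([self.eps, self.sigma, 0.0, 0.0])


@dataclass(frozen=True)
class SquareWellWall:
    """Idealised square well: -depth for 0 < z < width, zero beyond."""

    depth: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")

    def energy(self, z):
        z = _check_z(z)
        return np.where(z < self.width, -self.depth, 0.0) + 0.0

    @property
    def attractive(self) -> bool:
        return self.depth > 0

    def kernel_params(self):
        return WALL_SQUARE_WELL, np.array([self.depth, self.width, 0.0, 0.0])


def _check_z(z):
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("wall potential is defined for z > 0 only")
    return z


def wall_energy(wall, z):
    """Evaluate the wall potential at height(s) ``z`` (nm), in kBT."""
    return wall.energy(z)


def wall_minimum(wall) -> WallMinimum | None:
    """Locate the attractive minimum of a wall potential.

    Returns ``None`` for purely repulsive (or zero) walls.  For smooth
    walls the minimum is found by bounded scalar minimisation; for the
    square well it is the well floor.
    """
    if not wall.attractive:
        return None
    if isinstance(wall, SquareWellWall):
        return WallMinimum(z_min=0.5 * wall.width, eps_min=-wall.depth)
    if isinstance(wall, DebyeHuckelWall):
        hi = 5.0 * wall.lambda_d
        lo = 0.2 * wall.lambda_r
    else:
        hi = 5.0 * wall.sigma
        lo = 0.2 * wall.sigma
    res = minimize_scalar(
        lambda z: float(wall.energy(z)), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    z_min = float(res.x)
    eps_min = float(wall.energy(z_min))
    if eps_min >= 0:
        return None
    return WallMinimum(z_min=z_min, eps_min=eps_min)


def surface_energy(conf, wall) -> float:
    """Total RNA-substrate energy: sum of the wall potential over phosphates.

    Sugar and base sites do not feel the wall attraction; any site at
    z <= 0 yields an infinite (rejection) energy.
    """
    pos = conf.pos if hasattr(conf, "pos") else np.asarray(conf)
    if np.any(pos[..., 2] <= 0):
        return np.inf
    pz = pos[:, 0, 2]  # phosphate z-coordinates
    return float(np.sum(wall.energy(pz)))
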