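"""Run configuration: schema, validation, serialisation, seeding.

A run is fully described by a :class:`RunConfig` (fragment, wall family and
attraction scan, umbrella layout, sampling lengths, master seed, output
directory).  Configs are validated up front, serialised alongside every
output, and hashed so that cached window results can be reused only when
the configuration that produced them is identical.  Per-window RNG streams
are spawned deterministically from the master seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import constants
from .surface import DebyeHuckelWall, MieWall, SquareWellWall

__all__ = ["FragmentConfig", "WallConfig", "WindowConfig", "EdwardsConfig",
           "RunConfig", "load_config", "config_hash", "spawn_seeds"]


class FragmentConfig(BaseModel):
    label: str = "S1"
    structured: bool = True
    dotbracket: str | None = None   # overrides the built-in fixture
    sequence: str | None = None


class WallConfig(BaseModel):
    kind: str = "debye_huckel"
    eps_surf: list[float] = Field(default_factory=lambda: [0.44, 0.89, 1.33, 1.78])
    eps_r: float = 1.0
    lambda_r: float = 0.1
    lambda_d: float = 1.0
    sigma: float = 0.3       # Mie
    width: float = 0.5       # square well

    @field_validator("kind")
    @classmethod
    def _known_kind(cls, v):
        if v not in ("debye_huckel", "mie", "square_well"):
            raise ValueError(f"unknown wall kind {v!r}")
        return v

    @field_validator("eps_surf")
    @classmethod
    def _positive(cls, v):
        if not v or any(e < 0 for e in v):
            raise ValueError("eps_surf scan must be non-empty and non-negative")
        return v

    def build(self, eps: float):
        if self.kind == "debye_huckel":
            return DebyeHuckelWall(eps_surf=eps, eps_r=self.eps_r,
                                   lambda_r=self.lambda_r, lambda_d=self.lambda_d)
        if self.kind == "mie":
            return MieWall(eps=eps, sigma=self.sigma)
        return SquareWellWall(depth=eps, width=self.width)


class WindowConfig(BaseModel):
    centers: list[float] | None = None   # default: 0.5-4.0 step 0.25
    spring: float = constants.WINDOW_SPRING
    n_equil: int = 500
    n_prod: int = 2000
    sample_stride: int = 10

    @model_validator(mode="after")
    def _check(self):
        if self.spring <= 0:
            raise ValueError("spring must be positive")
        if self.n_prod <= 0 or self.n_equil < 0:
            raise ValueError("invalid sweep counts")
        centers = self.resolved_centers()
        if any(c <= 0 for c in centers):
            raise ValueError("window centers must be above the wall")
        return self

    def resolved_centers(self) -> list[float]:
        if self.centers is not None:
            return list(self.centers)
        return [float(c) for c in constants.WINDOW_CENTERS]


class EdwardsConfig(BaseModel):
    enabled: bool = True
    kuhn_length: float = 1.2
    z_max: float = 40.0
    dz: float = 1e-3


class RunConfig(BaseModel):
    fragment: FragmentConfig = Field(default_factory=FragmentConfig)
    wall: WallConfig = Field(default_factory=WallConfig)
    windows: WindowConfig = Field(default_factory=WindowConfig)
    edwards: EdwardsConfig = Field(default_factory=EdwardsConfig)
    seed: int = 1
    outdir: str = "rnadsorb_out"

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True)


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig(**data)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.canonical_json().encode()).hexdigest()[:16]


def spawn_seeds(master_seed: int, n: int, salt: str = "") -> list[int]:
    """Deterministic per-window seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence([master_seed, int.from_bytes(
        hashlib.sha256(salt.encode()).digest()[:4], "big")])
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]
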