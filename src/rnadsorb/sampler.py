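"""Umbrella-sampling Metropolis Monte Carlo on the centre-of-mass height.

The collective variable is the distance between the RNA centre of mass
(equal weights over all interaction sites) and the wall plane at z = 0,
i.e. simply the z-coordinate of the centre of mass.  Each umbrella window
restrains the CV with a harmonic spring and is sampled by an independent,
seeded Monte Carlo run whose move set is:

* rigid translation of a single nucleotide,
* rigid rotation of a single nucleotide about its centroid,
* crankshaft rotation of a short backbone segment about the axis through
  its flanking phosphates,
* whole-chain z-translation,
* whole-chain rotation about the centre of mass.

Move amplitudes are auto-tuned toward ~40% acceptance during
equilibration and frozen before production.  A hard reflecting boundary at
z = 8 nm bounds the desorbed state so the free-energy plateau is
sampleable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels, constants
from .cg_model import (
    AFormTemplate,
    Conformation,
    ForceFieldParams,
    FragmentTopology,
    stem_arrays_for,
)

__all__ = ["UmbrellaWindow", "WindowSamples", "collective_variable",
           "mc_sweep", "run_window", "run_window_scan", "run_unbiased",
           "default_windows"]

MOVE_NAMES = ("translate", "rotate", "crankshaft", "chain_z", "chain_rot")
DEFAULT_AMPLITUDES = np.array([0.25, 0.6, 0.7, 0.15, 0.4])
DEFAULT_MOVE_PROBS = np.array([0.35, 0.33, 0.20, 0.06, 0.06])


@dataclass(frozen=True)
class UmbrellaWindow:
    """One umbrella window: harmonic bias (k_u/2)(d_CM - center)^2."""

    center: float                     # nm
    spring: float = constants.WINDOW_SPRING   # kBT/nm^2
    n_equil: int = 500                # sweeps
    n_prod: int = 2000                # sweeps
    sample_stride: int = 10           # sweeps between stored conformations
    seed: int = 0

    def __post_init__(self):
        if self.spring <= 0:
            raise ValueError("umbrella spring constant must be positive")
        if self.n_prod <= 0:
            raise ValueError("n_prod must be positive")
        if self.center <= 0:
            raise ValueError("window center must be above the wall")


@dataclass
class WindowSamples:
    """Output of one umbrella-window run."""

    window: UmbrellaWindow
    cv_series: np.ndarray             # (n_prod,) d_CM per sweep, nm
    conformations: np.ndarray         # (n_snap, n, 5, 3) stored at stride
    acceptance: dict = field(default_factory=dict)   # per move type
    ermsd_trace: np.ndarray | None = None            # max stem eRMSD per sweep
    amplitudes: np.ndarray | None = None
    final_conformation: Conformation | None = None

    @property
    def bias_energy(self):
        d = self.cv_series - self.window.center
        return 0.5 * self.window.spring * d * d


def collective_variable(conf: Conformation) -> float:
    """Distance between the RNA centre of mass and the wall plane (nm)."""
    return conf.com_z


def default_windows(n_equil: int = 500, n_prod: int = 2000,
                    centers=None, spring: float = constants.WINDOW_SPRING,
                    sample_stride: int = 10, seeds=None) -> list[UmbrellaWindow]:
    """Standard window layout: centers 0.5-4.0 nm spaced 0.25 nm."""
    if centers is None:
        centers = constants.WINDOW_CENTERS
    if seeds is None:
        seeds = range(len(centers))
    return [
        UmbrellaWindow(center=float(c), spring=spring, n_equil=n_equil,
                       n_prod=n_prod, sample_stride=sample_stride, seed=int(s))
        for c, s in zip(centers, seeds)
    ]


def _kernel_args(topology, params, template, wall):
    params = params or ForceFieldParams()
    stem = stem_arrays_for(topology, template)
    if wall is None:
        wtype, wp = 0, np.zeros(4)
    else:
        wtype, wp = wall.kernel_params()
    return params, stem, wtype, wp


def mc_sweep(conf: Conformation, topology: FragmentTopology,
             params: ForceFieldParams | None, wall, window: UmbrellaWindow | None,
             seed: int, template: AFormTemplate | None = None,
             n_sweeps: int = 1, amplitudes=None) -> Conformation:
    """Run ``n_sweeps`` Metropolis sweeps and return the updated conformation.

    One sweep is ``n_nucleotides + 2`` attempted moves, each accepted with
    probability min(1, exp(-dE)) where the energy combines intramolecular,
    surface and umbrella-bias terms.  Deterministic for a given seed.
    """
    params, stem, wtype, wp = _kernel_args(topology, params, template, wall)
    ku = window.spring if window is not None else 0.0
    d0 = window.center if window is not None else 1.0
    pos = np.ascontiguousarray(conf.pos.copy())
    amps = np.array(amplitudes if amplitudes is not None else DEFAULT_AMPLITUDES,
                    dtype=float)
    _kernels.run_mc(pos, params.vector(), params.radii_array(), *stem,
                    wtype, wp, ku, d0, 0, n_sweeps, max(n_sweeps, 1),
                    seed, amps, DEFAULT_MOVE_PROBS.copy(), False, False)
    return Conformation(pos)


def run_window(topology: FragmentTopology, params: ForceFieldParams | None,
               wall, window: UmbrellaWindow,
               initial: Conformation, template: AFormTemplate | None = None,
               track_ermsd: bool | None = None) -> WindowSamples:
    """Sample one umbrella window; deterministic given ``window.seed``.

    The initial conformation is rigidly shifted so its centre of mass
    starts at the window center (never pushing sites below the wall).
    Acceptance fractions outside [0.05, 0.95] trigger a tuning warning.
    """
    params, stem, wtype, wp = _kernel_args(topology, params, template, wall)
    if track_ermsd is None:
        track_ermsd = topology.structured
    conf = initial.at_height(window.center)
    pos = np.ascontiguousarray(conf.pos.copy())
    amps = DEFAULT_AMPLITUDES.copy()
    cv, snaps, acc, att, ermsd_trace, amps = _kernels.run_mc(
        pos, params.vector(), params.radii_array(), *stem,
        wtype, wp, window.spring, window.center,
        window.n_equil, window.n_prod, window.sample_stride,
        window.seed, amps, DEFAULT_MOVE_PROBS.copy(),
        True, track_ermsd,
    )
    acceptance = {}
    for k, name in enumerate(MOVE_NAMES):
        if att[k] > 0:
            frac = acc[k] / att[k]
            acceptance[name] = frac
            if not 0.05 <= frac <= 0.95:
                warnings.warn(
                    f"acceptance fraction {frac:.2f} for move {name!r} in "
                    f"window at {window.center} nm is outside [0.05, 0.95]; "
                    "consider retuning amplitudes", RuntimeWarning,
                )
    return WindowSamples(
        window=window,
        cv_series=cv,
        conformations=snaps,
        acceptance=acceptance,
        ermsd_trace=ermsd_trace if track_ermsd else None,
        amplitudes=amps,
        final_conformation=Conformation(pos),
    )


def run_window_scan(topology: FragmentTopology, params: ForceFieldParams | None,
                    wall, windows, initial: Conformation,
                    template: AFormTemplate | None = None) -> list[WindowSamples]:
    """Run a set of umbrella windows sequentially, outside-in.

    Windows are processed in order of decreasing center; each window starts
    from the final conformation of the previous one, so the chain is pulled
    toward the wall gradually and the near-wall windows begin from a
    well-relaxed adsorbed state.  Results are returned in the original
    window order.
    """
    order = np.argsort([-w.center for w in windows])
    results: dict[int, WindowSamples] = {}
    conf = initial
    for idx in order:
        ws = run_window(topology, params, wall, windows[idx], conf, template)
        results[int(idx)] = ws
        conf = ws.final_conformation
    return [results[i] for i in range(len(windows))]


def run_unbiased(topology: FragmentTopology, params: ForceFieldParams | None,
                 wall, initial: Conformation, n_equil: int, n_prod: int,
                 seed: int, sample_stride: int = 10,
                 template: AFormTemplate | None = None) -> WindowSamples:
    """Unbiased Monte Carlo (no umbrella spring), e.g. for sampling the
    adsorbed ensemble directly."""
    params, stem, wtype, wp = _kernel_args(topology, params, template, wall)
    pos = np.ascontiguousarray(initial.pos.copy())
    amps = DEFAULT_AMPLITUDES.copy()
    cv, snaps, acc, att, ermsd_trace, amps = _kernels.run_mc(
        pos, params.vector(), params.radii_array(), *stem,
        wtype, wp, 0.0, 0.0, n_equil, n_prod, sample_stride,
        seed, amps, DEFAULT_MOVE_PROBS.copy(), True, topology.structured,
    )
    acceptance = {name: (acc[k] / att[k] if att[k] else np.nan)
                  for k, name in enumerate(MOVE_NAMES)}
    window = UmbrellaWindow(center=max(float(np.mean(cv)), 1e-6), spring=1e-12,
                            n_equil=n_equil, n_prod=n_prod,
                            sample_stride=sample_stride, seed=seed)
    return WindowSamples(window=window, cv_series=cv, conformations=snaps,
                         acceptance=acceptance,
                         ermsd_trace=ermsd_trace if topology.structured else None,
                         amplitudes=amps, final_conformation=Conformation(pos))
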