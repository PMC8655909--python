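"""Free-energy reconstruction from biased umbrella windows.

The potential of mean force F(d_CM) is obtained from the window histograms
by the weighted histogram analysis method (WHAM): the unbiased bin
probabilities and the per-window free energies are iterated to
self-consistency,

    P(b) = sum_k n_k(b) / sum_k N_k exp(f_k - c_k(b)),
    exp(-f_k) = sum_b P(b) exp(-c_k(b)),

with c_k(b) the bias energy of window k evaluated at bin b (everything in
kBT).  The PMF is -ln P re-referenced so that it averages to zero over the
outermost nanometre of the sampled range (the desorbed plateau).

Statistical errors are estimated by block bootstrap: the integrated
autocorrelation time of each window series is measured by blocking
analysis, decorrelated blocks are resampled, and WHAM is re-run for each
replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["PMFProfile", "BlockingResult", "blocking_analysis", "wham",
           "bootstrap_pmf", "adsorption_free_energy", "closest_approach",
           "pmf_from_samples"]

DEFAULT_BIN_WIDTH = 0.05  # nm
PLATEAU_SPAN = 1.0        # nm, outermost range used as the F = 0 reference


@dataclass
class PMFProfile:
    """Reconstructed free-energy profile along the CV."""

    bin_centers: np.ndarray    # nm
    free_energy: np.ndarray    # kBT, referenced to the plateau
    errors: np.ndarray | None = None  # kBT, bootstrap standard deviations
    reference: str = "plateau"

    def __post_init__(self):
        if self.errors is not None and np.any(self.errors < 0):
            raise ValueError("errors must be non-negative")


@dataclass(frozen=True)
class BlockingResult:
    """Blocking-analysis estimate of the integrated autocorrelation time."""

    tau: float                 # sweeps
    n_effective: float         # n / (2 tau + 1)
    plateau_found: bool
    block_length: int          # 2 tau rounded up to a power of two


def blocking_analysis(series: np.ndarray) -> BlockingResult:
    """Flyvbjerg-Petersen blocking estimate of the autocorrelation time.

    The series is repeatedly halved into block means; the statistical
    inefficiency g(L) = L * var(block means) / var(x) plateaus at
    g = 2 tau + 1 once blocks are longer than the correlation time.  If no
    plateau is detected the longest usable block level is returned and
    flagged as conservative.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 64:
        raise ValueError("blocking analysis needs at least 64 samples")
    var0 = x.var(ddof=1)
    if var0 == 0:
        warnings.warn("constant series: autocorrelation time is undefined, "
                      "returning tau = 0", RuntimeWarning)
        return BlockingResult(tau=0.0, n_effective=float(n),
                              plateau_found=False, block_length=1)
    g_prev = 1.0
    g_levels = []
    y = x.copy()
    L = 1
    while y.size >= 16:
        g = L * y.var(ddof=1) / var0
        g_levels.append(g)
        if y.size % 2 == 1:
            y = y[:-1]
        y = 0.5 * (y[::2] + y[1::2])
        L *= 2
    plateau_found = False
    g_est = g_levels[-1]
    for k in range(1, len(g_levels)):
        if g_levels[k] <= g_levels[k - 1] * 1.05:
            g_est = max(g_levels[k], g_levels[k - 1])
            plateau_found = True
            break
    if not plateau_found:
        warnings.warn("no blocking plateau detected; using the longest block "
                      "level (conservative)", RuntimeWarning)
    g_est = max(g_est, 1.0)
    tau = 0.5 * (g_est - 1.0)
    block_length = 1 << int(np.ceil(np.log2(max(2.0 * tau, 1.0))))
    return BlockingResult(tau=float(tau), n_effective=n / (2 * tau + 1),
                          plateau_found=plateau_found,
                          block_length=int(block_length))


def _histograms(cv_sets, edges):
    counts = np.array([np.histogram(cv, bins=edges)[0] for cv in cv_sets],
                      dtype=float)
    return counts


def _check_overlap(counts, centers):
    """Adjacent windows (ordered by mean CV) must share occupied bins."""
    order = np.argsort([c.argmax() for c in counts])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            raise ValueError(
                f"no histogram overlap between adjacent windows {a} and {b} "
                f"(peaks near {centers[counts[a].argmax()]:.2f} and "
                f"{centers[counts[b].argmax()]:.2f} nm); add windows in the gap"
            )


def wham(cv_sets, bias_funcs, bin_width: float = DEFAULT_BIN_WIDTH,
         tol: float = 1e-8, max_iter: int = 100000,
         reference: str = "plateau", min_count: int = 10) -> PMFProfile:
    """Self-consistent WHAM over a set of biased CV series.

    Parameters
    ----------
    cv_sets:
        Sequence of 1D arrays, one biased CV series per window.
    bias_funcs:
        Sequence of callables ``u_k(d)`` returning the bias energy (kBT)
        of window k at CV value d; pass ``lambda d: 0*d`` for unbiased data.
    bin_width:
        Histogram bin width in nm.
    tol:
        Convergence tolerance on the window free energies (kBT).
    reference:
        "plateau" re-zeroes on the outermost nanometre of the sampled
        range; "min" sets the minimum to zero; "none" leaves -ln P.
    """
    cv_sets = [np.asarray(c, dtype=float) for c in cv_sets]
    if len(cv_sets) != len(bias_funcs):
        raise ValueError("need one bias function per window")
    lo = min(c.min() for c in cv_sets)
    hi = max(c.max() for c in cv_sets)
    edges = np.arange(lo - bin_width, hi + 2 * bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = _histograms(cv_sets, edges)
    occupied = counts.sum(axis=0) > 0
    _check_overlap(counts, centers)

    n_k = counts.sum(axis=1)                       # samples per window
    c_kb = np.array([u(centers) for u in bias_funcs], dtype=float)
    f_k = np.zeros(len(cv_sets))
    log_nk = np.log(n_k)
    log_counts_tot = np.where(occupied, np.log(counts.sum(axis=0),
                                               where=occupied,
                                               out=np.full(centers.size, -np.inf)),
                              -np.inf)
    for _ in range(max_iter):
        # log denominator per bin: logsumexp_k [log N_k + f_k - c_kb]
        log_den = logsumexp(log_nk[:, None] + f_k[:, None] - c_kb, axis=0)
        log_p = np.where(occupied, log_counts_tot - log_den, -np.inf)
        log_p -= logsumexp(log_p[occupied])
        f_new = -logsumexp(log_p[None, :] - c_kb, axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f_k))
        f_k = f_new
        if delta < tol:
            break
    else:
        warnings.warn("WHAM did not converge to tolerance", RuntimeWarning)

    f = np.where(occupied, -log_p, np.nan)
    # bins with only a handful of counts carry O(1/sqrt(n)) ~ O(1) noise in
    # -ln P and would fake minima at the edges of the sampled range
    keep = occupied & (counts.sum(axis=0) >= min_count)
    centers, f = centers[keep], f[keep]
    f = _re_reference(centers, f, reference)
    return PMFProfile(bin_centers=centers, free_energy=f, reference=reference)


def _re_reference(centers, f, reference):
    if reference == "plateau":
        mask = centers >= centers.max() - PLATEAU_SPAN
        return f - np.mean(f[mask])
    if reference == "min":
        return f - np.nanmin(f)
    if reference == "none":
        return f
    raise ValueError(f"unknown reference convention {reference!r}")


def pmf_from_samples(window_samples, bin_width: float = DEFAULT_BIN_WIDTH,
                     **kwargs) -> PMFProfile:
    """WHAM over a list of :class:`~rnadsorb.sampler.WindowSamples`."""
    cv_sets = [ws.cv_series for ws in window_samples]
    bias_funcs = [
        (lambda d, k=ws.window.spring, c=ws.window.center:
         0.5 * k * (d - c) ** 2)
        for ws in window_samples
    ]
    return wham(cv_sets, bias_funcs, bin_width=bin_width, **kwargs)


def bootstrap_pmf(cv_sets, bias_funcs, n_boot: int, seed: int,
                  bin_width: float = DEFAULT_BIN_WIDTH,
                  block_lengths=None, reference: str = "plateau") -> np.ndarray:
    """Per-bin bootstrap errors of the WHAM PMF.

    Each replicate resamples decorrelated blocks (block length from
    blocking analysis, a power of two >= 2 tau) within every window and
    re-runs WHAM.  Returns the per-bin standard deviation on the binning
    of the full-data profile.
    """
    if n_boot < 20:
        raise ValueError("at least 20 bootstrap replicates are required")
    cv_sets = [np.asarray(c, dtype=float) for c in cv_sets]
    if block_lengths is None:
        block_lengths = [blocking_analysis(c).block_length for c in cv_sets]
    base = wham(cv_sets, bias_funcs, bin_width=bin_width, reference=reference)
    rng = np.random.default_rng(seed)
    profiles = np.full((n_boot, base.bin_centers.size), np.nan)
    for r in range(n_boot):
        resampled = []
        for c, L in zip(cv_sets, block_lengths):
            n_blocks = max(len(c) // L, 1)
            starts = rng.integers(0, max(len(c) - L + 1, 1), size=n_blocks)
            resampled.append(np.concatenate([c[s:s + L] for s in starts]))
        try:
            prof = wham(resampled, bias_funcs, bin_width=bin_width,
                        reference="none")
        except ValueError:
            continue  # a replicate may lose the overlap; skip it
        # re-reference on the *base* grid so the zero convention uses the
        # same bins in every replicate (the sampled range itself jitters)
        interp = np.interp(base.bin_centers, prof.bin_centers,
                           prof.free_energy, left=np.nan, right=np.nan)
        if reference == "plateau":
            mask = base.bin_centers >= base.bin_centers.max() - PLATEAU_SPAN
            interp = interp - np.nanmean(interp[mask])
        elif reference == "min":
            interp = interp - np.nanmin(interp)
        profiles[r] = interp
    errors = np.nanstd(profiles, axis=0)
    base.errors = errors
    return errors


def adsorption_free_energy(pmf: PMFProfile) -> float:
    """Adsorption free energy F_m: the minimum of the plateau-referenced
    PMF (<= 0 when bound, ~0 when the wall never attracts)."""
    if pmf.reference != "plateau":
        raise ValueError("F_m requires a plateau-referenced PMF")
    return float(np.nanmin(pmf.free_energy))


def closest_approach(pmf: PMFProfile, threshold: float = 4.0) -> float:
    """Smallest thermally accessible CV value: the innermost bin whose free
    energy lies within ``threshold`` kBT of the PMF minimum.  Bins below
    that distance are only reachable by the umbrella bias, not thermally."""
    fmin = np.nanmin(pmf.free_energy)
    ok = pmf.free_energy <= fmin + threshold
    return float(pmf.bin_centers[ok].min())
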