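"""Multimodality battery: dip test, critical bandwidth, mode counting, SiZer.

These are the prerequisite checks run on the outcome before a cusp model
is entertained: the cusp's central assumption is bimodality/multimodality
of the state variable.

* ``dip_statistic`` / ``dip_test`` — Hartigan & Hartigan's dip: the sup
  distance between the empirical CDF and the nearest unimodal CDF,
  computed by the iterative greatest-convex-minorant / least-concave-
  majorant modal-interval algorithm; p-values by seeded Monte Carlo from
  the uniform null.
* ``critical_bandwidth`` / ``silverman_test`` — the smallest Gaussian-KDE
  bandwidth at which the density estimate has at most k modes, with a
  variance-corrected smoothed-bootstrap p-value.
* ``count_modes`` — strict local maxima of the Gaussian KDE on a grid.
* ``sizer_map`` — a simplified SiZer (SIgnificant ZERo crossings) map
  classifying the KDE slope across location and bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _dip

__all__ = [
    "DipResult",
    "SilvermanResult",
    "SizerMap",
    "dip_statistic",
    "dip_test",
    "critical_bandwidth",
    "silverman_test",
    "count_modes",
    "sizer_map",
    "mode_ladder",
]


# --------------------------------------------------------------------------
# Hartigan & Hartigan dip
# --------------------------------------------------------------------------

def dip_statistic(sample) -> float:
    """Hartigan & Hartigan's dip statistic of a sample.

    The sup-distance between the empirical CDF and the nearest unimodal
    CDF.  For a candidate mode at the j-th order statistic, the convex
    branch must fit the prefix of the empirical CDF (its deficiency is
    measured against the greatest convex minorant of the lower step
    values), the concave branch the suffix (least concave majorant of the
    upper step values), and the two branches must hand over at the mode;
    the dip is the smallest deviation budget for which some mode admits
    all three, found by bisection over a monotone feasibility check (see
    ``_dip`` for the kernels).  Always >= 1/(2n); 0 only for a constant
    sample.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("dip requires at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample must be finite")
    if x[0] == x[-1]:
        return 0.0
    return _dip.dip_counts(x) / (2.0 * n)


@dataclass(frozen=True)
class DipResult:
    D: float
    p: float
    n: int
    n_mc: int
    seed: int

    def to_dict(self) -> dict:
        return {"D": self.D, "p": self.p, "n": self.n, "n_mc": self.n_mc, "seed": self.seed}


def dip_test(sample, n_mc: int = 9999, seed: int = 0) -> DipResult:
    """Dip test of unimodality with a seeded Monte-Carlo uniform null.

    p = (1 + #{null dips >= observed}) / (n_mc + 1); the +1 continuity
    correction keeps p in (0, 1].  The uniform(0, 1) null is the standard
    calibration (the dip is distribution-free only asymptotically; the
    uniform is the least-favorable unimodal null).
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 4:
        raise ValueError("dip test requires at least 4 observations")
    d_obs = dip_statistic(x)
    t_obs = d_obs * 2.0 * len(x)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_mc):
        if _dip.dip_at_least(np.sort(rng.uniform(size=len(x))), t_obs):
            exceed += 1
    p = (1.0 + exceed) / (n_mc + 1.0)
    return DipResult(D=float(d_obs), p=float(p), n=len(x), n_mc=n_mc, seed=seed)


# --------------------------------------------------------------------------
# Gaussian-KDE mode counting and Silverman's critical bandwidth
# --------------------------------------------------------------------------

def _silverman_rule(x: np.ndarray) -> float:
    sd = np.std(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * len(x) ** (-0.2)


def _kde_on_grid(x: np.ndarray, h: float, grid: np.ndarray) -> np.ndarray:
    z = (grid[:, None] - x[None, :]) / h
    return np.exp(-0.5 * z * z).sum(axis=1) / (len(x) * h * np.sqrt(2.0 * np.pi))


def count_modes(sample, bandwidth: float | None = None, grid_size: int = 512) -> int:
    """Strict local maxima of the Gaussian KDE at the given bandwidth.

    Default bandwidth is Silverman's rule of thumb; the KDE is evaluated
    on a ``grid_size``-point grid spanning the data range +/- 3 bandwidths.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 1:
        raise ValueError("empty sample")
    if np.ptp(x) == 0.0:
        return 1
    h = float(bandwidth) if bandwidth is not None else _silverman_rule(x)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(x.min() - 3.0 * h, x.max() + 3.0 * h, grid_size)
    if h < 4.0 * (grid[1] - grid[0]):
        # grid cannot resolve the kernel; pin the exact peak locations
        grid = np.union1d(grid, x)
    dens = _kde_on_grid(x, h, grid)
    # plateau-aware: count rise->fall transitions of the compressed slope signs
    signs = np.sign(np.diff(dens))
    signs = signs[signs != 0]
    if len(signs) == 0:
        return 1
    return int(np.sum((signs[:-1] > 0) & (signs[1:] < 0)))


def critical_bandwidth(
    sample, k: int = 1, tol_factor: float = 1e-4, grid_size: int = 512
) -> float:
    """Smallest bandwidth at which the Gaussian KDE has at most k modes.

    Bisection (tolerance ``tol_factor`` times the sample SD) using the
    monotonicity of the Gaussian-kernel mode count in the bandwidth.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0.0:
        raise ValueError("critical bandwidth needs a non-degenerate sample")
    if k < 1:
        raise ValueError("k must be >= 1")
    tol = tol_factor * np.std(x)
    h_hi = float(np.ptp(x))
    while count_modes(x, h_hi, grid_size) > k:
        h_hi *= 2.0
    h_lo = h_hi / 2.0 ** 12
    while count_modes(x, h_lo, grid_size) <= k:
        h_lo /= 2.0
        if h_lo < tol / 100.0:  # sample has at most k modes at any bandwidth
            return float(h_lo)
    while h_hi - h_lo > tol:
        mid = 0.5 * (h_lo + h_hi)
        if count_modes(x, mid, grid_size) <= k:
            h_hi = mid
        else:
            h_lo = mid
    return float(h_hi)


@dataclass(frozen=True)
class SilvermanResult:
    k_null: int
    h_crit: float
    p: float
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "k_null": self.k_null,
            "h_crit": self.h_crit,
            "p": self.p,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def silverman_test(
    sample, k_null: int = 1, n_boot: int = 500, seed: int = 0, grid_size: int = 512
) -> SilvermanResult:
    """Silverman's critical-bandwidth test of "at most k_null modes".

    The statistic is the critical bandwidth h_crit; the p-value is the
    fraction of variance-corrected smoothed-bootstrap resamples (drawn at
    h_crit) whose KDE at h_crit shows more than k_null modes.  Known to be
    somewhat anti-conservative without the Hall-York calibration, which is
    deliberately omitted here.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 10:
        raise ValueError("silverman test requires at least 10 observations")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate (zero-variance) sample")
    h = critical_bandwidth(x, k_null, grid_size=grid_size)
    rng = np.random.default_rng(seed)
    n = len(x)
    var = np.var(x)
    shrink = 1.0 / np.sqrt(1.0 + h * h / var)
    mean = np.mean(x)
    exceed = 0
    for _ in range(n_boot):
        star = rng.choice(x, size=n, replace=True)
        smooth = mean + (star - mean + h * rng.standard_normal(n)) * shrink
        if count_modes(smooth, h, grid_size) > k_null:
            exceed += 1
    return SilvermanResult(
        k_null=k_null, h_crit=float(h), p=exceed / n_boot, n_boot=n_boot, seed=seed
    )


def mode_ladder(
    sample,
    level: float = 0.05,
    max_k: int = 6,
    n_boot: int = 500,
    seed: int = 0,
    grid_size: int = 512,
) -> tuple[int | None, list[SilvermanResult]]:
    """Stepwise mode search: test k = 1, 2, ... until the null is retained.

    Returns the first k whose "at most k modes" null is not rejected at
    ``level`` (None if all of 1..max_k are rejected) together with the
    full ladder of results, so either reading of a reported reference
    mode count can be recovered.
    """
    results = []
    for k in range(1, max_k + 1):
        res = silverman_test(sample, k_null=k, n_boot=n_boot, seed=seed + k, grid_size=grid_size)
        results.append(res)
        if res.p > level:
            return k, results
    return None, results


# --------------------------------------------------------------------------
# SiZer
# --------------------------------------------------------------------------

@dataclass
class SizerMap:
    """Per-(bandwidth, location) classification of the KDE slope.

    ``classes`` holds one of "increasing", "decreasing", "zero",
    "insufficient-data" per cell, with bandwidths down the rows.
    """

    locations: np.ndarray
    bandwidths: np.ndarray
    classes: np.ndarray  # shape (n_bandwidths, n_locations), dtype object/str
    level: float

    def to_dict(self) -> dict:
        return {
            "locations": self.locations.tolist(),
            "bandwidths": self.bandwidths.tolist(),
            "classes": [list(row) for row in self.classes],
            "level": self.level,
        }


SIZER_CLASSES = ("increasing", "decreasing", "zero", "insufficient-data")
_MIN_LOCAL_N = 5.0


def sizer_map(
    sample,
    grid_size: int = 101,
    n_bandwidths: int = 21,
    level: float = 0.05,
) -> SizerMap:
    """Simplified SiZer map of the sample's density slope.

    At each location/bandwidth cell the Gaussian-KDE derivative estimate
    and its pointwise normal confidence interval classify the slope as
    increasing (CI above 0), decreasing (CI below 0) or zero (CI straddles
    0); cells whose effective local sample size falls below 5 are marked
    insufficient-data.
    """
    x = np.asarray(sample, dtype=float)
    n = len(x)
    if n < 20:
        raise ValueError("sizer map requires at least 20 observations")
    span = np.ptp(x)
    if span == 0.0:
        raise ValueError("degenerate (zero-variance) sample")
    locations = np.linspace(x.min(), x.max(), grid_size)
    bandwidths = np.geomspace(2.0 * span / grid_size, span, n_bandwidths)
    zcrit = stats.norm.ppf(1.0 - level / 2.0)
    classes = np.empty((n_bandwidths, grid_size), dtype=object)
    for bi, h in enumerate(bandwidths):
        u = (locations[:, None] - x[None, :]) / h
        phi = np.exp(-0.5 * u * u) / (h * np.sqrt(2.0 * np.pi))
        dphi = -u / h * phi  # d/dx of the scaled kernel
        est = dphi.mean(axis=1)
        sd = dphi.std(axis=1, ddof=1) / np.sqrt(n)
        ess = phi.sum(axis=1) * h * np.sqrt(2.0 * np.pi)
        lo = est - zcrit * sd
        hi = est + zcrit * sd
        row = np.where(lo > 0, "increasing", np.where(hi < 0, "decreasing", "zero"))
        row = np.where(ess < _MIN_LOCAL_N, "insufficient-data", row)
        classes[bi] = row
    return SizerMap(locations=locations, bandwidths=bandwidths, classes=classes, level=level)
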