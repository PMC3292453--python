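"""Insertion-age distributions, exponential fits, and recent-deficit tests.

Under constant transposition and a constant per-copy loss/obscuring hazard,
the ages of surviving recognizable copies are approximately exponential; the
fitted half-life ln2/lambda summarizes how fast the record of insertions
decays looking back in time.  A recent suppression of successful insertions
(e.g., the onset of selfing) shows up as a deficit of young elements relative
to the exponential extrapolated into the recent window; the deficit is tested
with an exact Poisson ratio against that extrapolation, with the fit taken
strictly outside the tested window to avoid circularity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2, chisquare

from .errors import ConfigError, FitError

__all__ = [
    "AgeDistribution",
    "ExponentialFit",
    "DropReport",
    "build_age_distribution",
    "fit_exponential",
    "detect_drop",
    "rate_sensitivity",
    "poisson_interval",
]

MIN_FIT_N = 30


@dataclass(frozen=True)
class AgeDistribution:
    genome_id: str
    scope: str
    bin_width: float
    bin_edges: np.ndarray  # right-open bins [k*w, (k+1)*w)
    counts: np.ndarray
    percent: np.ndarray
    n_total: int
    mean_age: float


@dataclass(frozen=True)
class ExponentialFit:
    rate_lambda: float  # 1/Myr
    half_life: float  # Myr, = ln2 / rate_lambda
    fit_window: tuple[float, float]
    n_used: int
    goodness_chi2: float
    goodness_p: float


@dataclass(frozen=True)
class DropReport:
    window: tuple[float, float]
    observed: int
    expected: float
    ratio: float
    poisson_interval: tuple[float, float]  # 95% interval on the ratio
    drop_detected: bool
    low_power: bool


def build_age_distribution(
    ages, bin_width: float, scope: str = "all", genome_id: str = ""
) -> AgeDistribution:
    """Histogram of ages into right-open bins [k*w, (k+1)*w).

    Boundary ages fall into the upper bin (right-open convention).  Percent
    representation sums to 100 for non-empty input.
    """
    if bin_width <= 0:
        raise ConfigError("bin_width must be > 0")
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 0):
        raise ConfigError("ages must be >= 0")
    if len(ages) == 0:
        warnings.warn("empty age set; returning empty distribution")
        return AgeDistribution(
            genome_id, scope, bin_width, np.zeros(1), np.zeros(0, int),
            np.zeros(0), 0, math.nan,
        )
    nbins = int(np.floor(ages.max() / bin_width)) + 1
    idx = np.floor(ages / bin_width).astype(int)
    counts = np.bincount(idx, minlength=nbins)
    edges = np.arange(nbins + 1) * bin_width
    return AgeDistribution(
        genome_id=genome_id,
        scope=scope,
        bin_width=bin_width,
        bin_edges=edges,
        counts=counts,
        percent=100.0 * counts / len(ages),
        n_total=len(ages),
        mean_age=float(ages.mean()),
    )


def fit_exponential(ages, fit_window=None) -> ExponentialFit:
    """Maximum-likelihood exponential fit, optionally truncated to a window.

    With ``fit_window=None`` the usual untruncated MLE lambda = 1/mean is
    used.  With a window (a, b) only ages in [a, b) enter, and lambda solves
    the truncated-mean equation
    mean(t - a) = 1/lambda - L*exp(-lambda*L)/(1 - exp(-lambda*L)), L = b-a.
    A truncated fit may return a negative rate when the density increases
    with age (sample mean above the window midpoint); the identity
    half_life * lambda = ln 2 holds regardless of sign.  Goodness is a
    chi-square over the deciles of the fitted distribution.
    """
    ages = np.asarray(ages, dtype=float)
    if fit_window is not None:
        a, b = fit_window
        if not (0 <= a < b):
            raise ConfigError("fit_window must satisfy 0 <= a < b")
        sel = ages[(ages >= a) & (ages < b)]
    else:
        a, b = 0.0, math.inf
        sel = ages[ages >= 0]
    if len(sel) < MIN_FIT_N:
        raise FitError(f"need >= {MIN_FIT_N} ages in the fit window, got {len(sel)}")
    shifted = sel - a
    m = float(shifted.mean())
    if m <= 0 or np.ptp(sel) == 0:
        raise FitError("degenerate sample: all ages identical")
    if math.isinf(b):
        lam = 1.0 / m
    else:
        span = b - a
        if not (0 < m < span):
            raise FitError("truncated sample mean outside (0, window span)")

        def mean_eq(lam):
            if lam == 0.0:
                return span / 2.0 - m
            x = lam * span
            # span * e^{-x} / (1 - e^{-x}) == span / (e^x - 1), stable for
            # large |x| (limits: span as x -> -inf, 0 as x -> +inf)
            tail = 0.0 if x > 700 else span / math.expm1(x)
            return 1.0 / lam - tail - m

        # mean_eq is continuous and decreasing in lambda over the whole real
        # line (limit span/2 at 0); a sample mean above span/2 yields a
        # negative rate, i.e. density increasing with age within the window
        hi = max(4.0 / m, 1.0)
        while mean_eq(hi) > 0:
            hi *= 4
        lo = -hi
        while mean_eq(lo) < 0:
            lo *= 4
        lam = brentq(mean_eq, lo, hi, xtol=1e-12, rtol=1e-12)
        if lam == 0.0:
            lam = 1e-12
    # decile chi-square against the fitted (truncated) exponential
    if math.isinf(b):
        qs = a - np.log1p(-np.arange(1, 10) / 10.0) / lam
    else:
        mass = -math.expm1(-lam * (b - a))
        qs = a - np.log1p(-np.arange(1, 10) / 10.0 * mass) / lam
    edges = np.concatenate([[a], qs, [b if not math.isinf(b) else np.inf]])
    obs, _ = np.histogram(shifted + a, bins=edges)
    stat, p = chisquare(obs)
    return ExponentialFit(
        rate_lambda=float(lam),
        half_life=math.log(2) / lam,
        fit_window=(a, b),
        n_used=len(sel),
        goodness_chi2=float(stat),
        goodness_p=float(p),
    )


def poisson_interval(k: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) two-sided confidence interval for a Poisson count."""
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else chi2.ppf(alpha / 2, 2 * k) / 2.0
    hi = chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2.0
    return float(lo), float(hi)


def detect_drop(ages, window=(0.0, 0.5), fit=None, fit_window=None) -> DropReport:
    """Test for a deficit of young elements against the exponential tail.

    The exponential is fitted on ages outside the tested window (default fit
    window: [w1, 2*w1 + 2] Myr) and extrapolated into it; expected =
    n_fit * mass(window)/mass(fit window).  The observed count's exact 95%
    Poisson interval, divided by the expectation, gives the interval on the
    ratio; a drop is declared when its upper bound is < 1.
    """
    ages = np.asarray(ages, dtype=float)
    w0, w1 = window
    if not (0 <= w0 < w1):
        raise ConfigError("window must satisfy 0 <= w0 < w1")
    if fit is None:
        if fit_window is None:
            fit_window = (w1, 2.0 * w1 + 2.0)
        fit = fit_exponential(ages, fit_window)
    a, b = fit.fit_window
    if a < w1:
        raise ConfigError("fit window must lie outside (above) the tested window")
    lam = fit.rate_lambda

    def mass(lo, hi):
        return math.exp(-lam * lo) - (0.0 if math.isinf(hi) else math.exp(-lam * hi))

    expected = fit.n_used * mass(w0, w1) / mass(a, b)
    if expected <= 0:
        raise FitError("non-positive expected count under the fitted exponential")
    observed = int(((ages >= w0) & (ages < w1)).sum())
    lo, hi = poisson_interval(observed)
    return DropReport(
        window=(w0, w1),
        observed=observed,
        expected=float(expected),
        ratio=observed / expected,
        poisson_interval=(lo / expected, hi / expected),
        drop_detected=hi / expected < 1.0,
        low_power=expected < 5,
    )


def rate_sensitivity(divergences_K, r_values, window=(0.0, 0.5), r_ref=0.015):
    """Re-run the drop test under alternative substitution rates.

    ``divergences_K`` are per-copy nearest-neighbor divergences (K, not
    times), so ages are recomputed as K/2r per rate.  The tested window is
    specified at the reference rate ``r_ref`` and rescaled by r_ref/r, so
    halving r exactly doubles every age and both window boundaries.
    Returns a list of (r, scaled_window, DropReport).
    """
    K = np.asarray(divergences_K, dtype=float)
    base_fit = (window[1], 2.0 * window[1] + 2.0)
    out = []
    for r in r_values:
        if r <= 0:
            raise ConfigError("substitution rates must be > 0")
        scale = r_ref / r
        win = (window[0] * scale, window[1] * scale)
        fit_win = (base_fit[0] * scale, base_fit[1] * scale)
        ages = K / (2.0 * r)
        out.append((r, win, detect_drop(ages, window=win, fit_window=fit_win)))
    return out
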