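"""Statistical primitives behind the assays.

Pearson correlation with its exact two-sided t test, Fisher r-to-z comparison
of two correlation coefficients, simple linear trendlines, Costes automatic
colocalization thresholding, trapezoidal area under a curve, and a Poisson
fit to log-transformed histograms with a likelihood-ratio comparison of two
samples.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "FisherZResult",
    "CostesResult",
    "PoissonFitResult",
    "pearson_with_test",
    "p_from_r_n",
    "fisher_z_compare",
    "linear_trendline",
    "costes_colocalization",
    "poisson_hist_fit",
    "auc_trapezoid",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided test (t with n-2 df)."""

    r: float
    n: int
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class FisherZResult:
    """Two-sided comparison of two independent correlation coefficients."""

    z: float
    p: float
    r1: float
    n1: int
    r2: float
    n2: int


@dataclass(frozen=True)
class CostesResult:
    """Costes automatic-threshold colocalization readout.

    The threshold pair is (T1, T2 = slope*T1 + intercept); ``r_below`` is the
    correlation over voxel pairs below both thresholds at the stopping point
    and ``r_above`` the correlation over voxels above both thresholds.
    """

    slope: float
    intercept: float
    threshold1: float
    threshold2: float
    r_below: float
    r_above: float
    n_above: int
    regression: str = "ols"


@dataclass(frozen=True)
class PoissonFitResult:
    """Poisson rate(s) fit to binned log-transformed values.

    Rates are in bin-index units of the log histogram (bin k = floor(ln x /
    bin_width)); ``loglik`` is the maximized Poisson log-likelihood.  With two
    samples, ``lrt`` and ``p`` compare the two rates against a pooled rate
    (chi-square, 1 df).
    """

    rate_a: float
    loglik: float
    bin_width: float
    rate_b: Optional[float] = None
    lrt: Optional[float] = None
    p: Optional[float] = None
    #: bins are re-indexed from this offset when values below 1 produce
    #: negative log-bins (Poisson support is non-negative)
    bin_offset: int = 0


def pearson_with_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson r with two-sided p from the t transformation (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need n >= 4 observations, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: a series has zero variance")
    xm = x - x.mean()
    ym = y - y.mean()
    r = float(np.dot(xm, ym) / np.sqrt(np.dot(xm, xm) * np.dot(ym, ym)))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) >= 1.0:
        return CorrelationResult(r=r, n=n, t=math_inf_sign(r), df=df, p=0.0)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df)
    return CorrelationResult(r=r, n=n, t=float(t), df=df, p=float(p))


def math_inf_sign(r: float) -> float:
    return float(np.inf if r > 0 else -np.inf)


def p_from_r_n(r: float, n: int) -> float:
    """Two-sided p for a Pearson coefficient ``r`` at sample size ``n``.

    p = 2 P(T_{n-2} > |r| sqrt(n-2) / sqrt(1-r^2)).  |r| >= 1 returns 0.
    """
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if abs(r) >= 1.0:
        return 0.0
    df = n - 2
    t = abs(r) * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(t, df))


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> FisherZResult:
    """Test equality of two independent correlations via Fisher's z.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), p two-sided normal.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both sample sizes must exceed 3")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1 for the z transformation")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return FisherZResult(z=float(z), p=float(p), r1=r1, n1=n1, r2=r2, n2=n2)


def linear_trendline(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Ordinary least-squares slope and intercept of y on x."""
    slope, intercept = np.polyfit(np.asarray(x, float), np.asarray(y, float), 1)
    return float(slope), float(intercept)


def _orthogonal_fit(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    # first principal axis of the (x, y) cloud
    xm, ym = x.mean(), y.mean()
    cov = np.cov(x - xm, y - ym)
    evals, evecs = np.linalg.eigh(cov)
    vx, vy = evecs[:, np.argmax(evals)]
    if vx == 0:
        raise ValueError("orthogonal fit degenerate: vertical principal axis")
    slope = vy / vx
    return float(slope), float(ym - slope * xm)


def _pearson_or_nan(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def costes_colocalization(ch1: np.ndarray, ch2: np.ndarray,
                          mask: Optional[np.ndarray] = None,
                          regression: str = "ols",
                          min_voxels_above: int = 10) -> CostesResult:
    """Costes automatic-threshold colocalization of two channels.

    A line ch2 = a*ch1 + b is fit over the (masked) voxels; the channel-1
    threshold T1 is scanned downward from max(ch1) in unit intensity steps,
    at each step computing Pearson r over voxel pairs with ch1 < T1 and
    ch2 < a*T1 + b, stopping at the first T1 where that r <= 0 (or the
    intensity range is exhausted).  ``r_above`` is the Pearson coefficient
    over voxels with ch1 >= T1 and ch2 >= a*T1 + b.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValueError("channels must have the same shape")
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.shape != ch1.shape:
            raise ValueError("mask shape mismatch")
        v1, v2 = ch1[m], ch2[m]
    else:
        v1, v2 = ch1.ravel(), ch2.ravel()
    if v1.size < min_voxels_above:
        raise ValueError("insufficient voxels for colocalization analysis")
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("a channel is constant over the mask")
    if regression == "ols":
        a, b = linear_trendline(v1, v2)
    elif regression == "orthogonal":
        a, b = _orthogonal_fit(v1, v2)
    else:
        raise ValueError(f"unknown regression {regression!r}")

    t1 = float(np.floor(v1.max()))
    t1_min = float(np.floor(v1.min()))
    r_below = np.nan
    while t1 > t1_min:
        below = (v1 < t1) & (v2 < a * t1 + b)
        r = _pearson_or_nan(v1[below], v2[below])
        if not np.isnan(r):
            r_below = r
            if r <= 0:
                break
        t1 -= 1.0
    above = (v1 >= t1) & (v2 >= a * t1 + b)
    if int(above.sum()) < min_voxels_above:
        raise ValueError(
            f"only {int(above.sum())} voxels above threshold (need {min_voxels_above})")
    r_above = _pearson_or_nan(v1[above], v2[above])
    return CostesResult(slope=a, intercept=b, threshold1=t1, threshold2=a * t1 + b,
                        r_below=float(r_below), r_above=float(r_above),
                        n_above=int(above.sum()), regression=regression)


def _log_bins(sample: np.ndarray, bin_width: float) -> np.ndarray:
    if np.any(sample <= 0):
        bad = sample[sample <= 0]
        raise ValueError(f"log transform undefined for non-positive values: {bad[:5]}")
    return np.floor(np.log(sample) / bin_width).astype(int)


def _poisson_loglik(k: np.ndarray, lam: float) -> float:
    if lam <= 0:
        lam = 1e-12
    return float(np.sum(sps.poisson.logpmf(k, lam)))


def poisson_hist_fit(sample_a: Sequence[float],
                     sample_b: Optional[Sequence[float]] = None,
                     bin_width: float = 0.25) -> PoissonFitResult:
    """Fit Poisson rate(s) to log-binned samples; optionally compare two rates.

    Each positive value x is assigned the histogram bin floor(ln x /
    bin_width); the bin indices are modeled as Poisson counts, whose ML rate
    is their mean.  With two samples the likelihood-ratio statistic
    2(l_separate - l_pooled) is referred to chi-square with 1 df.
    """
    a = np.asarray(sample_a, dtype=float)
    ka = _log_bins(a, bin_width)
    kb = None if sample_b is None else _log_bins(np.asarray(sample_b, float),
                                                bin_width)
    # Poisson support is non-negative: re-index from the lowest occupied bin
    # when values below 1 produce negative bins
    low = min(int(ka.min()), int(kb.min()) if kb is not None else 0)
    offset = min(0, low)
    ka = ka - offset
    lam_a = float(ka.mean())
    ll_a = _poisson_loglik(ka, lam_a)
    if kb is None:
        return PoissonFitResult(rate_a=lam_a, loglik=ll_a, bin_width=bin_width,
                                bin_offset=offset)
    kb = kb - offset
    lam_b = float(kb.mean())
    ll_b = _poisson_loglik(kb, lam_b)
    pooled = np.concatenate([ka, kb])
    lam_pool = float(pooled.mean())
    ll_pool = _poisson_loglik(pooled, lam_pool)
    lrt = max(0.0, 2.0 * (ll_a + ll_b - ll_pool))
    p = float(sps.chi2.sf(lrt, df=1))
    return PoissonFitResult(rate_a=lam_a, rate_b=lam_b, loglik=ll_a + ll_b,
                            bin_width=bin_width, lrt=lrt, p=p, bin_offset=offset)


def auc_trapezoid(t: Sequence[float], y: Sequence[float]) -> float:
    """Trapezoidal integral of ``y`` over strictly increasing nodes ``t``."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape:
        raise ValueError("t and y must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    return float(np.trapezoid(y, t))
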