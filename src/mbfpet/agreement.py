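"""Method-agreement statistics: Deming regression, Lin CCC, Bland-Altman.

Used to compare image-derived against arterial-sample kinetic parameters and
rubidium- against water-based flows.  Two distinct percent-difference
conventions exist in this package, deliberately: the curve-validation metric
(reference in the denominator) lives in :mod:`mbfpet.blood`; the Bland-Altman
percent differences here use the pair mean as denominator, which is what the
reproducibility coefficient is defined on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DemingFit",
    "BlandAltman",
    "AgreementReport",
    "deming_regression",
    "lin_ccc",
    "bland_altman_percent",
    "paired_t_pvalue",
    "compare_methods",
]


@dataclass(frozen=True)
class DemingFit:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    variance_ratio: float


@dataclass(frozen=True)
class BlandAltman:
    mean_percent_diff: float
    lower_limit: float
    upper_limit: float
    reproducibility_coefficient: float


@dataclass(frozen=True)
class AgreementReport:
    deming: DemingFit
    lin_ccc: float
    bland_altman: BlandAltman
    paired_t_p: float


def _deming_point(x: np.ndarray, y: np.ndarray, delta: float) -> tuple[float, float]:
    mx, my = np.mean(x), np.mean(y)
    sxx = np.sum((x - mx) ** 2)
    syy = np.sum((y - my) ** 2)
    sxy = np.sum((x - mx) * (y - my))
    if sxy == 0:
        # no covariance: slope from the variance balance alone
        slope = np.sqrt(syy / sxx / delta) if sxx > 0 else np.nan
    else:
        disc = (syy - delta * sxx) ** 2 + 4.0 * delta * sxy**2
        slope = (syy - delta * sxx + np.sqrt(disc)) / (2.0 * sxy)
    return float(slope), float(my - slope * mx)


def deming_regression(
    x: np.ndarray, y: np.ndarray, variance_ratio: float = 1.0
) -> DemingFit:
    """Errors-in-both-variables straight-line fit (closed form).

    ``variance_ratio`` δ is the ratio of the error variance of y to that of x:
    δ → ∞ recovers ordinary least squares of y on x, δ → 0 the inverse
    regression.  Standard errors are leave-one-out jackknife estimates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    if variance_ratio <= 0:
        raise ValueError("variance_ratio must be > 0")
    slope, intercept = _deming_point(x, y, variance_ratio)
    slopes = np.empty(n)
    intercepts = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        slopes[i], intercepts[i] = _deming_point(x[keep], y[keep], variance_ratio)
    se_slope = float(np.sqrt((n - 1) / n * np.sum((slopes - np.mean(slopes)) ** 2)))
    se_int = float(np.sqrt((n - 1) / n * np.sum((intercepts - np.mean(intercepts)) ** 2)))
    return DemingFit(slope, intercept, se_slope, se_int, variance_ratio)


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin concordance correlation: absolute agreement with the identity line.

    ccc = 2·cov(x,y) / (var(x) + var(y) + (mean(x) − mean(y))²), using
    population (1/n) moments.  Bounded by the Pearson correlation in absolute
    value; equality requires matched means and variances.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size != x.size:
        raise ValueError("need >= 2 paired points")
    vx, vy = np.var(x), np.var(y)
    if vx == 0 and vy == 0:
        raise ValueError("both vectors are constant")
    cov = np.mean((x - np.mean(x)) * (y - np.mean(y)))
    return float(2.0 * cov / (vx + vy + (np.mean(x) - np.mean(y)) ** 2))


def bland_altman_percent(x: np.ndarray, y: np.ndarray) -> BlandAltman:
    """Bland-Altman on pairwise percent differences, pair-mean denominator.

    d_i = 100·(y_i − x_i)/mean(x_i, y_i); reports mean(d), the 95 % limits of
    agreement mean(d) ± 1.96·SD(d), and the reproducibility coefficient
    RPC = 1.96·SD(d) (sample SD).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size != x.size:
        raise ValueError("need >= 2 pairs")
    pair_mean = 0.5 * (x + y)
    if np.any(pair_mean == 0):
        raise ValueError("a pair mean is zero")
    d = 100.0 * (y - x) / pair_mean
    mean_d = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    rpc = 1.96 * sd
    return BlandAltman(mean_d, mean_d - rpc, mean_d + rpc, rpc)


def paired_t_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired t-test p-value; identical vectors give p = 1."""
    d = np.asarray(y, dtype=float) - np.asarray(x, dtype=float)
    if np.allclose(d, 0.0):
        return 1.0
    if np.std(d, ddof=1) == 0:
        return 0.0  # constant nonzero offset: infinitely significant
    return float(stats.ttest_rel(x, y).pvalue)


def compare_methods(
    x: np.ndarray, y: np.ndarray, variance_ratio: float = 1.0
) -> AgreementReport:
    """Full agreement panel between a reference method x and a test method y."""
    return AgreementReport(
        deming=deming_regression(x, y, variance_ratio),
        lin_ccc=lin_ccc(x, y),
        bland_altman=bland_altman_percent(x, y),
        paired_t_p=paired_t_pvalue(x, y),
    )
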