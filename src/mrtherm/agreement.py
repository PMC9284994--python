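"""Method-comparison statistics for paired ablation-volume measurements.

Implements the Bland-Altman limits-of-agreement analysis, Pearson
correlation with ordinary least squares, the paired Student t-test and
mean ± SEM summaries used to compare MR-thermometry-predicted ablation
volumes against histologically measured ones.

Conventions
-----------
* Differences are computed as ``a - b``.  Callers comparing histology
  against MR thermal imaging should pass histology as ``a`` so that a
  positive mean difference means histology reads larger.
* Standard deviations use the sample (n-1) denominator.
* Limits of agreement are ``mean_diff ± 1.96 · sd_diff`` with the fixed
  normal quantile 1.96, not a t-based interval.
* The percent difference normalises the mean difference by the grand
  mean of all 2n measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementResult",
    "CorrelationResult",
    "bland_altman",
    "correlation",
    "paired_t",
    "summarize_metric",
]

_LOA_Z = 1.96


@dataclass(frozen=True)
class AgreementResult:
    """Full summary of a two-method agreement analysis.

    ``percent_diff`` is NaN when the grand mean of the measurements is
    zero (the normalisation is undefined in that case).
    """

    n: int
    mean_diff: float
    sd_diff: float
    sem_diff: float
    loa_low: float
    loa_high: float
    percent_diff: float
    pearson_r: float
    r_squared: float
    t_stat: float
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return a, b


def bland_altman(a, b) -> AgreementResult:
    """Bland-Altman agreement between two paired measurement series.

    Parameters
    ----------
    a, b : array-like, same length >= 2
        Paired measurements of the same quantity by two methods
        (e.g. histology and MRTI ablation volumes, cm^3).  Differences
        are ``a - b``.

    Returns
    -------
    AgreementResult
        Mean difference, its SD/SEM, the 95% limits of agreement
        ``mean ± 1.96·SD``, the percent difference relative to the grand
        mean, Pearson r / r^2, and the paired t-test.
    """
    a, b = _paired(a, b)
    n = a.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    d = a - b
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    sem_diff = sd_diff / np.sqrt(n)
    grand_mean = float(np.mean(np.concatenate([a, b])))
    if grand_mean == 0.0:
        percent_diff = float("nan")
    else:
        percent_diff = 100.0 * mean_diff / grand_mean
    if np.std(a) > 0 and np.std(b) > 0:
        corr = correlation(a, b)
        pearson_r, r_squared = corr.pearson_r, corr.r_squared
    else:
        pearson_r = r_squared = float("nan")
    t_stat, p_value = paired_t(a, b)
    return AgreementResult(
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        sem_diff=float(sem_diff),
        loa_low=mean_diff - _LOA_Z * sd_diff,
        loa_high=mean_diff + _LOA_Z * sd_diff,
        percent_diff=percent_diff,
        pearson_r=pearson_r,
        r_squared=r_squared,
        t_stat=t_stat,
        p_value=p_value,
    )


def correlation(a, b) -> CorrelationResult:
    """Pearson correlation and OLS regression of ``b`` on ``a``.

    Requires n >= 3 and nonzero variance in both series.
    """
    a, b = _paired(a, b)
    if a.size < 3:
        raise ValueError(f"need at least 3 pairs for a correlation, got {a.size}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: one input has zero variance")
    r = float(stats.pearsonr(a, b).statistic)
    slope, intercept = np.polyfit(a, b, 1)
    return CorrelationResult(
        pearson_r=r,
        r_squared=r * r,
        slope=float(slope),
        intercept=float(intercept),
    )


def paired_t(a, b) -> tuple[float, float]:
    """Two-sided paired Student t-test on ``a - b``.

    Returns ``(t_stat, p_value)`` with ``df = n - 1``.  A degenerate
    series with zero SD of differences yields ``t = ±inf, p = 0`` when
    the mean difference is nonzero, and ``t = 0, p = 1`` when the two
    series are identical.
    """
    a, b = _paired(a, b)
    n = a.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    d = a - b
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    if sd_diff == 0.0:
        if mean_diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(mean_diff)) * float("inf"), 0.0
    t = mean_diff / (sd_diff / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return float(t), p


def summarize_metric(values) -> tuple[float, float]:
    """Mean and standard error (sample SD / sqrt(n)) of a metric series."""
    v = _as_1d(values, "values")
    if v.size < 2:
        raise ValueError(f"need at least 2 values, got {v.size}")
    return float(np.mean(v)), float(np.std(v, ddof=1) / np.sqrt(v.size))
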