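"""Descriptive statistics and the m ± 3s outlier screen.

Each survey date's phase values are summarised (mean, sample variance,
extrema, coefficient of variation) and screened against the thresholds

    lower, upper = m - 3s, m + 3s

where m is the dataset mean and s the sample standard deviation.  Values
strictly outside the band are flagged as outliers; values exactly on a
threshold are kept ("below or above" is read strictly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["DescriptiveStats", "descriptive_stats", "compute_thresholds", "flag_outliers"]


@dataclass(frozen=True)
class DescriptiveStats:
    mean: float
    variance: float  # sample variance, n-1 denominator
    sd: float
    minimum: float
    maximum: float
    n: int
    cv: float  # s/m; NaN (flagged) when the mean is zero
    lower_threshold: float
    upper_threshold: float
    degenerate: bool = False  # n == 1 or zero mean: some fields are conventions


def compute_thresholds(m: float, s: float) -> tuple[float, float]:
    """Outlier thresholds (m - 3s, m + 3s)."""
    if s < 0:
        raise ValueError(f"standard deviation must be >= 0, got {s}")
    return m - 3.0 * s, m + 3.0 * s


def descriptive_stats(values: Sequence[float]) -> DescriptiveStats:
    """Univariate summary of one date's phase values.

    Uses the n-1 denominator for the variance; a single observation yields
    variance 0 by convention with the ``degenerate`` flag set.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("descriptive_stats requires at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("descriptive_stats requires finite values")
    n = int(v.size)
    m = float(v.mean())
    var = float(v.var(ddof=1)) if n > 1 else 0.0
    s = math.sqrt(var)
    lower, upper = compute_thresholds(m, s)
    zero_mean = m == 0.0
    return DescriptiveStats(
        mean=m,
        variance=var,
        sd=s,
        minimum=float(v.min()),
        maximum=float(v.max()),
        n=n,
        cv=float("nan") if zero_mean else s / m,
        lower_threshold=lower,
        upper_threshold=upper,
        degenerate=(n == 1) or zero_mean,
    )


def flag_outliers(values: Sequence[float], stats: DescriptiveStats) -> np.ndarray:
    """Boolean flag per value: True iff strictly outside [lower, upper]."""
    v = np.asarray(values, dtype=float)
    return (v < stats.lower_threshold) | (v > stats.upper_threshold)
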