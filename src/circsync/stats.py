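"""Small statistical utilities: correlation significance and t-tests.

Correlation p-values follow the standard parametric test: for a sample
Pearson coefficient r computed over n paired observations,
``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` follows a t distribution with
``n - 2`` degrees of freedom under the null of no association. No
multiple-comparison correction is applied anywhere in the package: pair
counts at a fixed alpha are descriptive summaries of a correlation matrix,
not gene-level hypothesis tests.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_pvalue",
    "pearson_pvalues",
    "critical_r",
    "one_sample_ttest",
    "unpaired_ttest",
]


def pearson_pvalue(r: float, n: int) -> float:
    """Two-tailed p-value for a Pearson coefficient from n observations."""
    if n < 3:
        raise ValidationError("pearson_pvalue requires n >= 3")
    if abs(r) > 1 + 1e-12:
        raise ValidationError(f"|r| > 1: {r}")
    r = min(1.0, max(-1.0, float(r)))
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def pearson_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Vectorized :func:`pearson_pvalue` over an array of coefficients."""
    if n < 3:
        raise ValidationError("pearson_pvalues requires n >= 3")
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    out = np.zeros_like(r)
    interior = np.abs(r) < 1.0
    t = np.zeros_like(r)
    t[interior] = r[interior] * math.sqrt(n - 2) / np.sqrt(1.0 - r[interior] ** 2)
    out[interior] = 2.0 * sps.t.sf(np.abs(t[interior]), n - 2)
    return out


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at ``alpha`` (two-tailed) for n observations.

    Inverts the t transform: r* = t* / sqrt(n - 2 + t*^2) with
    t* = t_{1-alpha/2, n-2}.
    """
    if n < 3:
        raise ValidationError("critical_r requires n >= 3")
    t_star = sps.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t_star / math.sqrt(n - 2 + t_star**2))


def one_sample_ttest(values: Sequence[float], mu0: float = 0.0) -> tuple[float, float]:
    """One-sample t-test of the mean against ``mu0`` (two-tailed)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("one_sample_ttest requires at least 2 values")
    if np.ptp(x) == 0:
        raise ValidationError("one_sample_ttest requires nonzero variance")
    res = sps.ttest_1samp(x, popmean=mu0)
    return float(res.statistic), float(res.pvalue)


def unpaired_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: str = "student",
) -> tuple[float, float]:
    """Unpaired two-tailed t-test (``student`` pooled-variance or ``welch``).

    Degenerate zero-variance groups are handled explicitly: equal means give
    (t=0, p=1); different means give an infinite statistic with p -> 0 and a
    logged warning rather than an exception, since such inputs arise from
    saturated |r| populations.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("unpaired_ttest requires >= 2 values per group")
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        logger.warning("unpaired_ttest: both groups constant with different means")
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)
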