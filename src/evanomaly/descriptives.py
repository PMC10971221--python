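"""Descriptive statistics accompanying the anomaly lists.

Per protein and comparison: a two-sample t-test tier (significant /
marginal / not significant), within-group sample variances and their
absolute difference, the coefficient of variation, a quadratic fit of
distance against log fold change (the U-shaped relation between
displacement magnitude and fold change), and Venn region counts over
named accession sets.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import stats

__all__ = [
    "TIER_SIGNIFICANT",
    "TIER_MARGINAL",
    "TIER_NS",
    "ProteinStats",
    "QuadraticFit",
    "p_value_tier",
    "protein_ttest",
    "within_group_variance",
    "abs_var_diff",
    "coefficient_of_variation",
    "quadratic_fit",
    "venn_regions",
]

logger = logging.getLogger(__name__)

TIER_SIGNIFICANT = "sig"        # p < 0.05
TIER_MARGINAL = "marginal"      # 0.05 <= p < 0.1
TIER_NS = "ns"                  # p >= 0.1


@dataclasses.dataclass(frozen=True)
class ProteinStats:
    """Per-protein descriptive statistics for one comparison."""

    accession: str
    p_value: float
    tier: str
    var_ref: float
    var_trt: float
    abs_var_diff: float
    cv_ref: float
    cv_trt: float


@dataclasses.dataclass(frozen=True)
class QuadraticFit:
    """Least-squares d ~ a*logFC^2 + b*logFC + c with its R^2."""

    a: float
    b: float
    c: float
    r_squared: float


def p_value_tier(p: float) -> str:
    """Half-open tiers: [0, 0.05) sig, [0.05, 0.1) marginal, [0.1, 1] ns."""
    if p < 0.05:
        return TIER_SIGNIFICANT
    if p < 0.1:
        return TIER_MARGINAL
    return TIER_NS


def protein_ttest(ref_values: Sequence[float], trt_values: Sequence[float],
                  variant: str = "student") -> tuple[float, str]:
    """Two-sided two-sample t-test p-value and its tier.

    ``student`` (default) pools the variances; ``welch`` does not. With
    zero pooled variance the p-value is 1 for equal means and 0 (the
    limit) for unequal means.
    """
    if variant not in {"student", "welch"}:
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = np.asarray(ref_values, dtype=float)
    b = np.asarray(trt_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0, TIER_NS
        logger.info("degenerate t-test: zero variance, unequal means -> p=0")
        return 0.0, TIER_SIGNIFICANT
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    p = float(res.pvalue)
    return p, p_value_tier(p)


def within_group_variance(values: Sequence[float]) -> float:
    """Sample variance (ddof=1) of one protein's values in one condition."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    return float(v.var(ddof=1))


def abs_var_diff(v1: float, v2: float) -> float:
    """Absolute difference between two within-group variances."""
    if v1 < 0 or v2 < 0:
        raise ValueError("variances must be >= 0")
    return abs(v1 - v2)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample SD normalized by the mean; NaN when the mean is zero."""
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean == 0:
        return math.nan
    return float(v.std(ddof=1) / mean)


def quadratic_fit(x: Sequence[float], y: Sequence[float]) -> QuadraticFit:
    """Ordinary least-squares degree-2 polynomial of y on x.

    R^2 = 1 - SS_res / SS_tot, defined as 0 for constant y. Raises on
    fewer than 3 points or when all x are identical (rank-deficient).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points for a quadratic fit")
    if np.all(x == x[0]):
        raise ValueError("all x identical: quadratic fit is rank-deficient")
    coeffs = npoly.polyfit(x, y, 2)  # [c, b, a]
    pred = npoly.polyval(x, coeffs)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return QuadraticFit(a=float(coeffs[2]), b=float(coeffs[1]),
                        c=float(coeffs[0]), r_squared=r2)


def venn_regions(sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Exclusive region counts for 2 or 3 named accession sets.

    Keys are "&"-joined sorted name combinations; each count is the number
    of accessions in exactly those sets (isoform accessions are distinct
    identities). Counts over all regions sum to the size of the union.
    """
    names = sorted(sets)
    if len(names) not in (2, 3):
        raise ValueError("venn_regions takes 2 or 3 named sets")
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) \
                if len(combo) < len(names) else set()
            regions["&".join(combo)] = len(inside - outside)
    return regions
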