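"""Comparison metrics between TTC-, OED- and NOAEL-based margins of exposure.

The scientific question behind each metric: is the cheap structure-based
threshold (TTC) at least as protective as the data-hungry alternatives?

* ``conservativeness_fractions`` — on the chemicals common to two MoE
  tables, the fraction where the first is strictly smaller (more
  protective).
* ``log_r2`` — squared Pearson correlation of log10 MoEs (how well one
  metric ranks like the other).
* ``median_moe_ratio`` — type-2 median of per-chemical MoE ratios (how many
  fold apart the two metrics sit).
* ``group_difference_tests`` — two-sided Wilcoxon rank-sum and two-sample
  Kolmogorov-Smirnov tests between per-category samples (e.g. OEDs vs
  exposures within a TTC category).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .pod import quantile_type2

#: per-group sample-size bound below which the rank-sum test is enumerated
#: exactly rather than normal-approximated
EXACT_RANKSUM_MAX_N = 10


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    computed: bool = True
    note: str = ""


@dataclass
class ComparisonSummary:
    n_common: int
    frac_ttc_lt_oed: Optional[float] = None
    frac_ttc_lt_noael: Optional[float] = None
    frac_oed_lt_noael: Optional[float] = None
    r2_log_noael_vs_ttc: Optional[float] = None
    r2_log_noael_vs_oed: Optional[float] = None
    median_ratio_noael_over_oed: Optional[float] = None
    median_ratio_noael_over_ttc: Optional[float] = None
    per_category_tests: dict = field(default_factory=dict)


def _common(
    moe_a: Mapping[str, float], moe_b: Mapping[str, float]
) -> tuple[list[float], list[float]]:
    keys = sorted(set(moe_a) & set(moe_b))
    if not keys:
        raise RuntimeError("MoE tables share no chemicals")
    return [float(moe_a[k]) for k in keys], [float(moe_b[k]) for k in keys]


def conservativeness_fractions(
    moe_a: Mapping[str, float], moe_b: Mapping[str, float]
) -> tuple[int, float]:
    """(n_common, fraction of common chemicals where a < b, strictly)."""
    a, b = _common(moe_a, moe_b)
    n = len(a)
    n_less = sum(1 for x, y in zip(a, b) if x < y)
    return n, n_less / n


def log_r2(
    moe_a: Mapping[str, float], moe_b: Mapping[str, float]
) -> Optional[float]:
    """Squared Pearson correlation of log10-transformed MoEs.

    Chemicals with non-positive MoEs are excluded (with a warning); returns
    None when either vector has zero variance or fewer than 3 pairs remain.
    """
    a, b = _common(moe_a, moe_b)
    pairs = [(x, y) for x, y in zip(a, b) if x > 0 and y > 0]
    n_dropped = len(a) - len(pairs)
    if n_dropped:
        warnings.warn(
            f"log_r2: excluded {n_dropped} chemicals with non-positive MoEs",
            stacklevel=2,
        )
    if len(pairs) < 3:
        warnings.warn("log_r2: fewer than 3 usable pairs", stacklevel=2)
        return None
    la = np.log10([p[0] for p in pairs])
    lb = np.log10([p[1] for p in pairs])
    if np.std(la) == 0 or np.std(lb) == 0:
        warnings.warn("log_r2: zero variance in log MoEs", stacklevel=2)
        return None
    r = np.corrcoef(la, lb)[0, 1]
    return float(r * r)


def median_moe_ratio(
    moe_num: Mapping[str, float], moe_den: Mapping[str, float]
) -> float:
    """Type-2 median of per-chemical MoE ratios (numerator/denominator)."""
    num, den = _common(moe_num, moe_den)
    if any(d <= 0 for d in den):
        raise ValueError("denominator MoEs must be positive")
    ratios = [x / y for x, y in zip(num, den)]
    return quantile_type2(ratios, 0.5)


def group_difference_tests(
    x_samples: Sequence[float], y_samples: Sequence[float]
) -> tuple[TestResult, TestResult]:
    """Two-sided rank-sum and two-sample KS tests between two samples.

    Rank-sum: Mann-Whitney U, enumerated exactly when both samples have at
    most ``EXACT_RANKSUM_MAX_N`` observations and no ties, otherwise the
    normal approximation with tie and continuity corrections. KS: D =
    sup|ECDF_x - ECDF_y| with the asymptotic Kolmogorov p-value. Samples
    with fewer than 2 observations yield not-computed results.
    """
    x = np.asarray(list(x_samples), dtype=float)
    y = np.asarray(list(y_samples), dtype=float)
    if x.size < 2 or y.size < 2:
        nc = TestResult(math.nan, math.nan, computed=False, note="n < 2")
        return nc, nc
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if x.size <= EXACT_RANKSUM_MAX_N and y.size <= EXACT_RANKSUM_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    mwu = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    rank_sum = TestResult(float(mwu.statistic), float(mwu.pvalue), note=method)
    ks = sps.ks_2samp(x, y, alternative="two-sided", method="asymp")
    ks_res = TestResult(float(ks.statistic), float(ks.pvalue), note="asymp")
    return rank_sum, ks_res


def compare_moe_tables(
    ttc: Optional[Mapping[str, float]] = None,
    oed: Optional[Mapping[str, float]] = None,
    noael: Optional[Mapping[str, float]] = None,
    categories: Optional[Mapping[str, str]] = None,
    category_samples: Optional[Mapping[str, tuple[Sequence[float], Sequence[float]]]] = None,
) -> ComparisonSummary:
    """All pairwise comparison metrics available from the supplied tables.

    ``category_samples`` optionally maps a category name to an (x, y) pair
    of samples (e.g. OEDs vs exposures) on which the rank-sum/KS tests are
    run; categories with fewer than 2 observations in either group are
    reported as not computed.
    """
    tables = {"TTC": ttc, "OED": oed, "NOAEL": noael}
    present = {k: v for k, v in tables.items() if v}
    if len(present) < 2 and not category_samples:
        raise ValueError("need at least two MoE tables (or category samples)")
    ids = None
    for v in present.values():
        ids = set(v) if ids is None else ids & set(v)
    summary = ComparisonSummary(n_common=len(ids or ()))

    if ttc and oed:
        _, summary.frac_ttc_lt_oed = conservativeness_fractions(ttc, oed)
    if ttc and noael:
        _, summary.frac_ttc_lt_noael = conservativeness_fractions(ttc, noael)
        summary.r2_log_noael_vs_ttc = log_r2(noael, ttc)
        summary.median_ratio_noael_over_ttc = median_moe_ratio(noael, ttc)
    if oed and noael:
        _, summary.frac_oed_lt_noael = conservativeness_fractions(oed, noael)
        summary.r2_log_noael_vs_oed = log_r2(noael, oed)
        summary.median_ratio_noael_over_oed = median_moe_ratio(noael, oed)

    if category_samples:
        for cat, (xs, ys) in sorted(category_samples.items()):
            rank_sum, ks = group_difference_tests(xs, ys)
            summary.per_category_tests[cat] = {
                "rank_sum": rank_sum,
                "ks": ks,
            }
    return summary
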