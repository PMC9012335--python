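"""Two-group comparison of feature distributions.

The group test is the two-sided Wilcoxon rank-sum (Mann-Whitney) test. The
p-value uses the exact permutation distribution when the combined sample is
small (<= 20) and tie-free, and otherwise a tie-corrected normal
approximation with continuity correction; ``method`` makes the choice
explicit. Summaries are median and interquartile range, with quartiles by
linear interpolation between order statistics (numpy's default rule).

Each segment is treated as an independent sample by default, replicating the
source analysis even though segments from one recording are correlated;
``by_recording=True`` averages segments within a recording first. No
multiple-testing correction is applied across features unless requested
(Holm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import Phase
from .features import FEATURE_NAMES

#: Largest combined sample size for which the exact permutation p-value is
#: used automatically (ties force the asymptotic path regardless).
EXACT_MAX_COMBINED_N = 20


class Direction(str, Enum):
    PP_GT_LP = "PP>LP"
    LP_GT_PP = "LP>PP"
    NONE = "none"


@dataclass
class RankSumResult:
    statistic: float  # rank sum W of the first group
    p_value: float
    method: str  # "exact" or "asymptotic"


def rank_sum_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    method: str = "auto",
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank sum of ``group_a`` (mid-ranks for ties) and the
    two-sided p-value. ``method`` is "auto", "exact" or "asymptotic"; exact
    mode requires tie-free data.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("NaN values must be removed before testing")

    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    w = float(ranks[: a.size].sum())

    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (pooled.size <= EXACT_MAX_COMBINED_N and not has_ties) else "asymptotic"
    if method not in ("exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exact" and has_ties:
        raise ValueError("exact method requires tie-free data")

    if np.ptp(pooled) == 0:  # all pooled values identical: no evidence of shift
        return RankSumResult(statistic=w, p_value=1.0, method=method)

    if method == "exact":
        res = sstats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sstats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return RankSumResult(statistic=w, p_value=min(1.0, float(res.pvalue)), method=method)


def median_iqr(values: np.ndarray) -> tuple[float, float]:
    """Sample median and interquartile range Q3 - Q1 (linear interpolation)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("cannot summarize an empty list")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q3 - q1)


@dataclass
class GroupComparison:
    feature_name: str
    n_pp: int
    n_lp: int
    median_pp: float
    iqr_pp: float
    median_lp: float
    iqr_lp: float
    rank_sum_statistic: float
    p_value: float
    direction: Direction
    significant: bool

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["direction"] = self.direction.value
        return d


def compare_phases(
    features: pd.DataFrame,
    feature_name: str,
    alpha: float = 0.05,
    method: str = "auto",
    by_recording: bool = False,
) -> GroupComparison:
    """Compare one feature between PP and LP segments of a feature table.

    NaN feature values (undefined features) are excluded. ``by_recording``
    averages segment values per recording before testing.
    """
    if feature_name not in features.columns:
        raise KeyError(f"feature {feature_name!r} not in table")
    df = features[["recording_id", "phase", feature_name]].dropna(subset=[feature_name])
    if by_recording:
        df = df.groupby(["recording_id", "phase"], as_index=False)[feature_name].mean()
    pp = df.loc[df["phase"] == Phase.PP.value, feature_name].to_numpy(dtype=float)
    lp = df.loc[df["phase"] == Phase.LP.value, feature_name].to_numpy(dtype=float)
    if pp.size == 0 or lp.size == 0:
        raise ValueError(
            f"both phases must be present for {feature_name!r}: "
            f"n_pp={pp.size}, n_lp={lp.size}"
        )
    test = rank_sum_test(pp, lp, method=method)
    med_pp, iqr_pp = median_iqr(pp)
    med_lp, iqr_lp = median_iqr(lp)
    if med_pp > med_lp:
        direction = Direction.PP_GT_LP
    elif med_lp > med_pp:
        direction = Direction.LP_GT_PP
    else:
        direction = Direction.NONE
    return GroupComparison(
        feature_name=feature_name,
        n_pp=int(pp.size),
        n_lp=int(lp.size),
        median_pp=med_pp,
        iqr_pp=iqr_pp,
        median_lp=med_lp,
        iqr_lp=iqr_lp,
        rank_sum_statistic=test.statistic,
        p_value=test.p_value,
        direction=direction,
        significant=bool(test.p_value < alpha),
    )


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    m = len(p_values)
    order = np.argsort(p_values)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def compare_all_features(
    features: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "auto",
    by_recording: bool = False,
    correction: str = "none",
) -> list[GroupComparison]:
    """Run compare_phases for all six features, optionally Holm-corrected."""
    comparisons = [
        compare_phases(features, name, alpha=alpha, method=method, by_recording=by_recording)
        for name in FEATURE_NAMES
    ]
    if correction == "holm":
        adjusted = holm_adjust([c.p_value for c in comparisons])
        for c, p in zip(comparisons, adjusted):
            c.p_value = p
            c.significant = bool(p < alpha)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return comparisons


def comparison_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.as_dict() for c in comparisons])
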