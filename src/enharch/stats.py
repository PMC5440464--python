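"""Nonparametric group comparisons and boxplot-style summaries.

Distributions of per-enhancer metrics (length, site counts, normalised
sites, average motif hit probability) are compared between groups with the
two-sided Mann-Whitney rank-sum test — chosen because enhancer metrics are
skewed and no normality assumption is tenable — with Bonferroni correction
across the family of pairwise comparisons within one metric.  Summaries
follow the usual boxplot conventions: quartiles by linear interpolation,
whiskers at 1.5*IQR beyond the quartiles, outliers beyond the whiskers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

METRICS = ("length_bp", "n_total", "normalized_sites", "p_av")

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "group_summary",
    "mann_whitney",
    "pairwise_comparisons",
    "compare_two_cohorts",
    "METRICS",
]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    p_adjusted: float
    family_size: int
    method: str  # 'exact' or 'asymptotic'


def group_summary(values: Sequence[float], label: str) -> GroupSummary:
    """Boxplot summary: linear-interpolation quartiles, 1.5*IQR fences."""
    x = np.asarray([v for v in values if not np.isnan(v)], dtype=float)
    if x.size == 0:
        raise ValueError(f"group {label!r} has no values")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(sorted(x[(x < lo) | (x > hi)]))
    return GroupSummary(
        group=label, n=int(x.size), median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(lo), whisker_high=float(hi), outliers=outliers,
    )


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration for tie-free samples with min(n) <= 8, normal
    approximation with tie correction otherwise.  Returns (U of sample a,
    two-sided p, method used).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    tie_free = np.unique(np.concatenate([a, b])).size == a.size + b.size
    if tie_free and min(a.size, b.size) <= 8:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def _clean(values: Sequence[float]) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    return x[~np.isnan(x)]


def pairwise_comparisons(
    profiles: pd.DataFrame,
    metric: str,
    grouping: Sequence[str],
) -> tuple[list[ComparisonResult], list[str]]:
    """All unordered pairwise group comparisons of one metric, Bonferroni-adjusted.

    ``grouping`` fixes the group order (e.g. developmental stages); groups
    with zero usable members are excluded and reported.  family_size is the
    number of pairs actually compared.
    """
    if metric not in profiles.columns:
        raise KeyError(f"metric {metric!r} absent from profiles")
    samples = {
        g: _clean(profiles.loc[profiles["group"] == g, metric]) for g in grouping
    }
    excluded = [g for g, x in samples.items() if x.size == 0]
    usable = [g for g in grouping if samples[g].size > 0]
    if len(usable) < 2:
        raise ValueError("need at least two groups with members to compare")
    pairs = list(itertools.combinations(usable, 2))
    family = len(pairs)
    results = []
    for ga, gb in pairs:
        u, p, method = mann_whitney(samples[ga], samples[gb])
        results.append(
            ComparisonResult(
                metric=metric, group_a=ga, group_b=gb,
                n_a=int(samples[ga].size), n_b=int(samples[gb].size),
                u_statistic=u, p_value=p,
                p_adjusted=min(1.0, p * family), family_size=family,
                method=method,
            )
        )
    return results, excluded


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def pairwise_matrix(results: Sequence[ComparisonResult], grouping: Sequence[str]) -> pd.DataFrame:
    """Symmetric matrix of Bonferroni-adjusted p-values (NaN on the diagonal)."""
    m = pd.DataFrame(np.nan, index=list(grouping), columns=list(grouping))
    for r in results:
        m.loc[r.group_a, r.group_b] = r.p_adjusted
        m.loc[r.group_b, r.group_a] = r.p_adjusted
    return m


def compare_two_cohorts(
    profiles: pd.DataFrame,
    metrics: Sequence[str] = METRICS,
) -> list[ComparisonResult]:
    """Per-metric two-group comparison (the axis-patterning analysis surface).

    Each metric is its own comparison family of one, so p_adjusted = p.
    """
    groups = sorted(profiles["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    ga, gb = groups
    results = []
    for metric in metrics:
        if metric not in profiles.columns:
            raise KeyError(f"metric {metric!r} absent from profiles")
        xa = _clean(profiles.loc[profiles["group"] == ga, metric])
        xb = _clean(profiles.loc[profiles["group"] == gb, metric])
        u, p, method = mann_whitney(xa, xb)
        results.append(
            ComparisonResult(
                metric=metric, group_a=ga, group_b=gb,
                n_a=int(xa.size), n_b=int(xb.size),
                u_statistic=u, p_value=p, p_adjusted=p, family_size=1,
                method=method,
            )
        )
    return results


def compare_motif_specificities(
    contents_a: Sequence[float], contents_b: Sequence[float],
    label_a: str = "A", label_b: str = "B",
) -> ComparisonResult:
    """Compare the per-TF motif hit probabilities (2^-I) of two motif panels."""
    pa = 2.0 ** -np.asarray(contents_a, dtype=float)
    pb = 2.0 ** -np.asarray(contents_b, dtype=float)
    u, p, method = mann_whitney(pa, pb)
    return ComparisonResult(
        metric="motif_hit_probability", group_a=label_a, group_b=label_b,
        n_a=int(pa.size), n_b=int(pb.size), u_statistic=u, p_value=p,
        p_adjusted=p, family_size=1, method=method,
    )
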