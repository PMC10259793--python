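"""Nonparametric group comparison of per-cell measurements.

Measurements (d_h, hyphal length, peak distances) are compared between
strains/conditions with the Kruskal-Wallis rank test (tie-corrected H,
chi-square p with k-1 degrees of freedom); samples are first screened with
the D'Agostino-Pearson omnibus normality test, which motivates the
rank-based comparison. p-values are mapped onto asterisk labels with the
thresholds ****<0.0001, ***<0.001, **<0.01, *<0.1, n.s. otherwise. For more
than two groups, pairwise Kruskal-Wallis comparisons with Bonferroni
correction are provided as the post-hoc procedure (an implementation choice;
no specific post-hoc test is canonical here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    ConfigurationError,
    DegenerateSampleError,
    InsufficientSampleError,
)

__all__ = ["DEFAULT_THRESHOLDS", "ComparisonResult", "test_normality",
           "kruskal_wallis", "significance_label", "compare_groups",
           "group_table"]

# ordered (threshold, label): first threshold bounding p from above wins
DEFAULT_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.1, "*"),
)

MIN_NORMALITY_N = 20
MIN_GROUP_N = 5


@dataclass(frozen=True)
class ComparisonResult:
    """Kruskal-Wallis comparison of one metric across groups."""

    metric: str
    groups: tuple[str, ...]
    H_statistic: float
    p_value: float
    group_n: tuple[int, ...]
    group_mean: tuple[float, ...]
    group_sd: tuple[float, ...]
    significance_label: str

    def summary(self) -> str:
        lines = [f"{self.metric}: Kruskal-Wallis H = {self.H_statistic:.4g}, "
                 f"p = {self.p_value:.3g} ({self.significance_label})"]
        for g, n, m, s in zip(self.groups, self.group_n, self.group_mean,
                              self.group_sd):
            lines.append(f"  {g}: n = {n}, mean = {m:.4g}, SD = {s:.4g}")
        return "\n".join(lines)


def test_normality(values: Sequence[float]) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus test (K² combining skew and kurtosis).

    Requires n >= 20 (the kurtosis z-transform is unreliable below that) and
    a non-degenerate sample. Returns (K², p) with p from chi-square(df=2).
    """
    arr = np.asarray(values, float)
    if not np.all(np.isfinite(arr)):
        raise DegenerateSampleError("non-finite values in sample")
    if arr.size < MIN_NORMALITY_N:
        raise InsufficientSampleError(
            f"normality test needs n >= {MIN_NORMALITY_N}, got {arr.size}")
    if np.ptp(arr) == 0:
        raise DegenerateSampleError("constant sample has no defined skewness")
    stat, p = sps.normaltest(arr)
    return float(stat), float(p)


def significance_label(p: float,
                       thresholds: Sequence[tuple[float, str]] = DEFAULT_THRESHOLDS,
                       ns_label: str = "n.s.") -> str:
    """Map a p-value to the first label whose threshold bounds it."""
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"p-value {p} outside [0, 1]")
    cuts = [t for t, _ in thresholds]
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ConfigurationError(
            f"thresholds must be strictly increasing, got {cuts}")
    for cut, label in thresholds:
        if p < cut:
            return label
    return ns_label


def kruskal_wallis(groups: Mapping[str, Sequence[float]], metric: str = "value",
                   thresholds: Sequence[tuple[float, str]] = DEFAULT_THRESHOLDS,
                   ) -> ComparisonResult:
    """Tie-corrected Kruskal-Wallis H test over two or more groups.

    Literally identical groups (zero rank variance) are the p = 1 boundary
    case and return H = 0 rather than failing.
    """
    if len(groups) < 2:
        raise InsufficientSampleError("need at least two groups")
    names = tuple(groups.keys())
    samples = [np.asarray(groups[g], float) for g in names]
    for g, s in zip(names, samples):
        if s.size < MIN_GROUP_N:
            raise InsufficientSampleError(
                f"group {g!r} has n = {s.size} < {MIN_GROUP_N}")
        if not np.all(np.isfinite(s)):
            raise DegenerateSampleError(f"group {g!r} has non-finite values")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)
    label = significance_label(float(p), thresholds)
    return ComparisonResult(
        metric=metric, groups=names,
        H_statistic=float(h), p_value=float(p),
        group_n=tuple(int(s.size) for s in samples),
        group_mean=tuple(float(s.mean()) for s in samples),
        group_sd=tuple(float(s.std(ddof=1)) if s.size > 1 else 0.0
                       for s in samples),
        significance_label=label,
    )


def compare_groups(table: pd.DataFrame, metric: str,
                   thresholds: Sequence[tuple[float, str]] = DEFAULT_THRESHOLDS,
                   ) -> tuple[ComparisonResult, pd.DataFrame]:
    """Omnibus comparison of one metric plus Bonferroni-corrected pairs.

    ``table`` is long-format with columns ``group``, ``cell_id``, ``metric``,
    ``value``. Returns the omnibus result and a pairwise frame (empty for
    two groups, where the omnibus already is the pairwise test).
    """
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise InsufficientSampleError(f"no rows for metric {metric!r}")
    groups = {g: d["value"].to_numpy() for g, d in sub.groupby("group")}
    omnibus = kruskal_wallis(groups, metric=metric, thresholds=thresholds)
    pairs = []
    names = list(groups)
    if len(names) > 2:
        m = len(list(combinations(names, 2)))
        for a, b in combinations(names, 2):
            res = kruskal_wallis({a: groups[a], b: groups[b]}, metric=metric,
                                 thresholds=thresholds)
            p_adj = min(res.p_value * m, 1.0)
            pairs.append({"group_a": a, "group_b": b,
                          "H": res.H_statistic, "p_raw": res.p_value,
                          "p_bonferroni": p_adj,
                          "label": significance_label(p_adj, thresholds)})
    return omnibus, pd.DataFrame(pairs)


def group_table(records: Sequence[Mapping[str, object]]) -> pd.DataFrame:
    """Assemble a long-format group table and validate it.

    Each record needs ``group``, ``cell_id``, ``metric``, ``value``; values
    must be finite.
    """
    df = pd.DataFrame(records, columns=["group", "cell_id", "metric", "value"])
    if df.empty:
        raise InsufficientSampleError("empty group table")
    if not np.all(np.isfinite(df["value"].to_numpy(float))):
        raise DegenerateSampleError("group table contains non-finite values")
    return df
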