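"""Per-field summaries and nonparametric group comparisons.

The unit of statistical analysis is the image field: each field yields
percent-positive values for the four marker calls, and treatment groups
are compared per metric with two-sided Mann-Whitney U tests.  Group sizes
in this assay are small (typically 6-13 fields), so the exact permutation
null is used whenever it is feasible (min group size <= 8 and no ties);
otherwise the normal approximation with tie and continuity corrections is
used.  Significance is annotated with the conventional star scheme using
strict thresholds: * P < 0.05, ** P < 0.01, *** P < 0.001,
**** P < 0.0001.  No multiple-testing correction is applied; comparisons
are reported per contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .marker_calls import CellCall

#: Metrics available for group comparison.
FIELD_METRICS = ("pct_cyto_cc3", "pct_bleb", "pct_gh2ax", "pct_coloc")


class StatsError(ValueError):
    pass


@dataclass
class FieldSummary:
    """Percent-positive cells for one field.

    ``pct_gh2ax_of_which_bleb`` is the percentage of gammaH2AX+ cells that
    are also CC3(bleb)+ (NaN when the field has no gammaH2AX+ cells); it
    satisfies ``pct_gh2ax_of_which_bleb * pct_gh2ax / 100 == pct_coloc``
    exactly on counts.
    """

    field_id: str
    group_label: str
    n_cells: int
    pct_cyto_cc3: float
    pct_bleb: float
    pct_gh2ax: float
    pct_coloc: float
    pct_gh2ax_of_which_bleb: float

    def as_dict(self) -> dict:
        return {
            "field_id": self.field_id,
            "group_label": self.group_label,
            "n_cells": self.n_cells,
            "pct_cyto_cc3": self.pct_cyto_cc3,
            "pct_bleb": self.pct_bleb,
            "pct_gh2ax": self.pct_gh2ax,
            "pct_coloc": self.pct_coloc,
            "pct_gh2ax_of_which_bleb": self.pct_gh2ax_of_which_bleb,
        }


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    metric: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation"
    stars: str

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def summarize_field(calls: list[CellCall], field_id: str, group_label: str = "") -> FieldSummary:
    """Aggregate per-cell calls into per-field percent-positive values."""
    n = len(calls)
    if n == 0:
        raise StatsError(f"field {field_id!r} has zero evaluable cells")
    n_cyto = sum(c.cyto_cc3_pos for c in calls)
    n_bleb = sum(c.cc3_bleb_pos for c in calls)
    n_gh = sum(c.gh2ax_pos for c in calls)
    n_coloc = sum(c.coloc_pos for c in calls)
    return FieldSummary(
        field_id=field_id,
        group_label=group_label,
        n_cells=n,
        pct_cyto_cc3=100.0 * n_cyto / n,
        pct_bleb=100.0 * n_bleb / n,
        pct_gh2ax=100.0 * n_gh / n,
        pct_coloc=100.0 * n_coloc / n,
        pct_gh2ax_of_which_bleb=(100.0 * n_coloc / n_gh) if n_gh else math.nan,
    )


def significance_stars(p: float) -> str:
    """Map a p-value to the assay's star annotation (strict thresholds)."""
    if not 0.0 < p <= 1.0:
        raise StatsError(f"p-value out of range (0, 1]: {p}")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mann_whitney(
    a: list[float] | np.ndarray,
    b: list[float] | np.ndarray,
    group_a: str = "a",
    group_b: str = "b",
    metric: str = "",
) -> GroupComparison:
    """Two-sided Mann-Whitney U test between two sets of per-field values.

    Uses the exact permutation null when ``min(n_a, n_b) <= 8`` and the
    pooled data contain no ties; otherwise the normal approximation with
    tie correction and continuity correction.  Deterministic; symmetric in
    its arguments (identical p-value either way round).
    """
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise StatsError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= 8 and not has_ties:
        method, method_name = "exact", "exact"
    else:
        method, method_name = "asymptotic", "normal-approximation"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    p = float(min(max(res.pvalue, np.nextafter(0.0, 1.0)), 1.0))
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        metric=metric,
        n_a=int(x.size),
        n_b=int(y.size),
        u_statistic=float(res.statistic),
        p_value=p,
        method=method_name,
        stars=significance_stars(p),
    )


def compare_groups(
    summaries: list[FieldSummary],
    group_a: str,
    group_b: str,
    metric: str,
) -> GroupComparison:
    """Mann-Whitney comparison of one per-field metric between two groups."""
    if metric not in FIELD_METRICS:
        raise StatsError(f"unknown metric {metric!r}; choose from {FIELD_METRICS}")
    va = [getattr(s, metric) for s in summaries if s.group_label == group_a]
    vb = [getattr(s, metric) for s in summaries if s.group_label == group_b]
    if not va or not vb:
        raise StatsError(
            f"comparison {group_a!r} vs {group_b!r} on {metric}: a group has no fields"
        )
    return mann_whitney(va, vb, group_a=group_a, group_b=group_b, metric=metric)
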