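"""Cohort-level summaries: group medians, fold changes, total daily
production, and small-sample nonparametric group comparisons."""

from __future__ import annotations

import itertools
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QUANTITIES",
    "validate_cohort_table",
    "FoldChange",
    "median_fold_change",
    "total_daily_production",
    "GroupComparison",
    "compare_groups",
    "dunn_posthoc",
]

QUANTITIES = frozenset(
    {"production_rate", "loss_rate", "ki67_fraction", "trec_content", "count"}
)
_COLUMNS = ["individual", "group", "subset", "quantity", "value"]


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format cohort table: required columns, known
    quantities, one value per (individual, subset, quantity)."""
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    bad_q = set(table["quantity"]) - QUANTITIES
    if bad_q:
        raise ValueError(f"unknown quantities {sorted(bad_q)}")
    dupes = table.duplicated(subset=["individual", "subset", "quantity"])
    if dupes.any():
        raise ValueError(
            f"duplicate (individual, subset, quantity) rows at index "
            f"{list(table.index[dupes])}"
        )
    return table


def _group_values(table, subset, quantity, group):
    sel = (
        (table["subset"] == subset)
        & (table["quantity"] == quantity)
        & (table["group"] == group)
    )
    return table.loc[sel, "value"].to_numpy(dtype=float)


class FoldChange(NamedTuple):
    value: float
    presented: float  # rounded to the nearest half for reporting


def median_fold_change(
    table: pd.DataFrame,
    subset: str,
    quantity: str,
    numerator: str = "patient",
    denominator: str = "healthy_control",
) -> FoldChange:
    """Ratio of group medians, patients over controls.

    The presented form rounds to the nearest 0.5 (folds are quoted as
    integers or halves).
    """
    num = _group_values(table, subset, quantity, numerator)
    den = _group_values(table, subset, quantity, denominator)
    if len(num) < 2 or len(den) < 2:
        raise ValueError("need >= 2 values per group for a fold change")
    med_den = float(np.median(den))
    if med_den == 0:
        raise ValueError("control median is zero; fold change undefined")
    fold = float(np.median(num)) / med_den
    return FoldChange(fold, round(fold * 2.0) / 2.0)


def total_daily_production(rate: float, median_count: float) -> float:
    """Cells produced per day: per-cell rate x median subset count."""
    if rate < 0 or median_count < 0:
        raise ValueError("rate and count must be >= 0")
    return rate * median_count


class GroupComparison(NamedTuple):
    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None  # Dunn table for > 2 groups


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(a), len(b)) <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z-tests on pooled ranks with tie correction, Bonferroni
    adjusted over all pairs."""
    names = list(groups)
    values = np.concatenate([groups[g] for g in names])
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    ranks = stats.rankdata(values)
    n = len(values)
    # tie correction term
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[labels == g].mean() for g in names}
    sizes = {g: (labels == g).sum() for g in names}
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for g1, g2 in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = 0.0 if se == 0 else (mean_ranks[g1] - mean_ranks[g2]) / se
        p = min(2.0 * stats.norm.sf(abs(z)) * len(pairs), 1.0)
        rows.append({"group1": g1, "group2": g2, "z": z, "p_adjusted": p})
    return pd.DataFrame(rows)


def compare_groups(
    table: pd.DataFrame,
    subset: str,
    quantity: str,
    groups: Sequence[str] | None = None,
) -> GroupComparison:
    """Two groups: two-sided Mann-Whitney (exact for n <= 8 per group,
    midrank/asymptotic with ties). More: Kruskal-Wallis with Dunn's
    correction for the pairwise comparisons."""
    if groups is None:
        groups = sorted(table["group"].unique())
    samples = {g: _group_values(table, subset, quantity, g) for g in groups}
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has < 2 values")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(groups) == 2:
        a, b = samples[groups[0]], samples[groups[1]]
        stat, p = _mann_whitney(a, b)
        return GroupComparison("mann_whitney", stat, p, None)
    values = [samples[g] for g in groups]
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):  # all identical: no evidence at all
        return GroupComparison("kruskal_wallis", 0.0, 1.0, dunn_posthoc(samples))
    stat, p = stats.kruskal(*values)
    return GroupComparison("kruskal_wallis", float(stat), float(p), dunn_posthoc(samples))
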