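"""Cross-sample CMP conservation statistics.

A CMP is *conserved* within a replicate group when its exact bit pattern
recurs in the top-N (default 54) most-abundant CMP lists of the group's
samples: in all three samples (3-of-3) or in exactly two (2-of-3).  The
summary mirrors the paper-style layout: one column for the full CMP ranking
("All") plus one column per marker using marker-specific (lead-protein)
tables, each giving the 3-of-3 count, the mean per-sample 2-of-3 count, and
their total, with a final row counting conserved CMPs common to both groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .catalog import CMPTable, marker_specific_table, top_n

__all__ = [
    "conserved_3of3",
    "conserved_2of3",
    "conserved_union",
    "ConservationSummary",
    "conservation_summary",
    "RankSumResult",
    "rank_sum_test",
]


def _check_panels(tables: Sequence[CMPTable]) -> None:
    if len({t.n_markers for t in tables}) > 1:
        raise ValueError("tables come from different marker panels")


def conserved_3of3(tables: Sequence[CMPTable]) -> frozenset[str]:
    """CMPs present (exact bit match) in every sample's top-N list."""
    if len(tables) < 2:
        raise ValueError("need at least two samples")
    _check_panels(tables)
    sets = [t.cmp_set for t in tables]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return frozenset(out)


def conserved_2of3(
    tables: Sequence[CMPTable], *, allow_any_group_size: bool = False
) -> tuple[list[int], Fraction]:
    """2-of-3 match counts from the three pairwise comparisons, plus mean.

    The three counts come from the pairwise comparisons (#1 vs #2, #1 vs #3,
    #2 vs #3): each is the number of CMPs shared by that pair of top-N lists
    but present in *exactly* two of the group's samples (3-of-3 CMPs are
    tabulated separately).  Every distinct 2-of-3 CMP sits in exactly one
    pairwise intersection, so the counts sum to the number of distinct
    2-of-3 CMPs, and the mean (kept exact as a Fraction, e.g. 33 matches /
    3 comparisons = 11) is the per-sample 2-of-3 rate entering the summary
    table.

    Designed for groups of 3 (three comparisons); other sizes enumerate all
    pairs and require ``allow_any_group_size=True``.
    """
    if len(tables) != 3 and not allow_any_group_size:
        raise ValueError("group size != 3; pass allow_any_group_size=True to generalize")
    _check_panels(tables)
    sets = [t.cmp_set for t in tables]
    counts = []
    for i, j in combinations(range(len(sets)), 2):
        pair = sets[i] & sets[j]
        n = sum(
            1 for cmp_ in pair if sum(cmp_ in other for other in sets) == 2
        )
        counts.append(n)
    mean = Fraction(sum(counts), len(counts))
    return counts, mean


def conserved_union(tables: Sequence[CMPTable]) -> frozenset[str]:
    """CMPs present in at least two samples (3-of-3 plus 2-of-3 sets)."""
    _check_panels(tables)
    sets = [t.cmp_set for t in tables]
    out: set[str] = set()
    for a, b in combinations(sets, 2):
        out |= a & b
    return frozenset(out)


@dataclass
class ConservationSummary:
    """Tidy per-column conservation counts for two (or more) groups.

    ``table`` rows: (group, statistic) for statistic in {3of3, 2of3_mean,
    total}; columns: "All" then one per marker.  ``common`` counts conserved
    CMPs shared by the two groups per column; ``pvalue`` compares the two
    groups' column totals by Wilcoxon rank-sum, as is conventional for this
    table layout (a pseudo-replication caveat: columns are not independent).
    """

    table: pd.DataFrame
    common: pd.Series | None
    pvalue: float | None
    n_top: int
    common_mode: str


def conservation_summary(
    groups: Mapping[str, Sequence[CMPTable]],
    n_top: int = 54,
    common_mode: str = "2of3",
) -> ConservationSummary:
    """Build the conservation summary over All + per-marker columns.

    ``groups`` maps group name -> full (untruncated) CMP tables, one per
    sample.  For the "All" column each sample's table is cut to its top
    ``n_top`` rows; for marker column m the marker-specific table (top
    ``n_top`` CMPs containing m) is used.  ``common_mode`` selects which
    conserved set enters the Common row: ``"2of3"`` (present in >=2 samples
    of the group, the default) or ``"3of3"``.
    """
    if common_mode not in ("2of3", "3of3"):
        raise ValueError("common_mode must be '2of3' or '3of3'")
    names = list(groups)
    if not names or any(len(v) == 0 for v in groups.values()):
        raise ValueError("every group needs at least one sample table")
    M = next(iter(groups.values()))[0].n_markers
    columns = ["All"] + list(range(M))

    def column_tables(tables: Sequence[CMPTable], col) -> list[CMPTable]:
        if col == "All":
            return [top_n(t, n_top) for t in tables]
        return [marker_specific_table(t, col, n_top) for t in tables]

    rows = {}
    conserved_sets: dict[tuple[str, object], frozenset[str]] = {}
    for g in names:
        c3, c2, tot = [], [], []
        for col in columns:
            tabs = column_tables(groups[g], col)
            s3 = conserved_3of3(tabs)
            _, mean2 = conserved_2of3(tabs, allow_any_group_size=True)
            c3.append(len(s3))
            c2.append(float(mean2))
            tot.append(len(s3) + float(mean2))
            conserved_sets[(g, col)] = (
                conserved_union(tabs) if common_mode == "2of3" else s3
            )
        rows[(g, "3of3")] = c3
        rows[(g, "2of3_mean")] = c2
        rows[(g, "total")] = tot

    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["group", "statistic"])

    common = None
    pvalue = None
    if len(names) == 2:
        a, b = names
        common = pd.Series(
            {
                col: len(conserved_sets[(a, col)] & conserved_sets[(b, col)])
                for col in columns
            }
        )
        res = rank_sum_test(
            table.loc[(a, "total")].to_numpy(), table.loc[(b, "total")].to_numpy()
        )
        pvalue = res.pvalue
    return ConservationSummary(
        table=table, common=common, pvalue=pvalue, n_top=n_top, common_mode=common_mode
    )


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum W of the first sample
    pvalue: float
    method: str  # "exact" or "asymptotic"


def rank_sum_test(a, b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both samples have n <= 25 and the
    pooled data are tie-free, otherwise the normal approximation with tie
    correction.  The reported statistic is the rank sum W of the first
    sample (W = U + n1(n1+1)/2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (a.size <= 25 and b.size <= 25 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic) + a.size * (a.size + 1) / 2
    return RankSumResult(statistic=w, pvalue=float(res.pvalue), method=method)
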