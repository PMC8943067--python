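"""Hierarchical clustering of cell profiles, cluster scoring, association.

Cells are clustered on their fraction profiles (f vectors) by agglomerative
clustering (Ward linkage on Euclidean distance by default) and the tree is
cut to a user-chosen number of clusters k, as is conventional when the
dendrogram itself guides the choice.  Each cluster is then *scored* against
a two-level factor (treatment or sex) with the 2/3-1/3 rule: a cluster is
"predominantly A" when level A makes up at least 2/3 of its cells,
"predominantly B" when at most 1/3, and "mixed" in between.  The thresholds
are compared as exact rationals (1/3, 2/3), not rounded percentages, so a
2-of-6 cluster counts as predominantly-B.  Association between factor and
cluster membership is quantified by Cramér's V.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage, to_tree
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .conservation import rank_sum_test

__all__ = [
    "ClusterAssignment",
    "hierarchical_cluster",
    "linkage_to_newick",
    "composition_table",
    "ClusterScoring",
    "score_clusters",
    "cramers_v",
    "group_marker_means",
    "default_contrasts",
    "pairwise_marker_tests",
]


@dataclass
class ClusterAssignment:
    labels: pd.Series  # index = cell id, values 1..k (contiguous)
    k: int
    method: str
    metric: str
    linkage_matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("cluster").rename_axis("cell").reset_index()


def hierarchical_cluster(
    profiles: np.ndarray | pd.DataFrame,
    k: int,
    method: str = "ward",
    metric: str = "euclidean",
    ids: Sequence | None = None,
) -> ClusterAssignment:
    """Agglomerative clustering of cell profile vectors, cut to k clusters.

    Deterministic given input order (SciPy breaks merge ties by pair index).
    Cluster ids are relabelled 1..k in order of first appearance so they are
    contiguous and stable.
    """
    X = np.asarray(profiles, dtype=float)
    if isinstance(profiles, pd.DataFrame) and ids is None:
        ids = profiles.index
    if X.ndim != 2:
        raise ValueError("profiles must be a 2-D array (cells x markers)")
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    if ids is None:
        ids = range(n)
    Z = scipy_linkage(X, method=method, metric=metric)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel contiguously in order of first appearance
    remap: dict[int, int] = {}
    lab = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        lab[i] = remap[r]
    return ClusterAssignment(
        labels=pd.Series(lab, index=pd.Index(ids, name="cell")),
        k=int(lab.max()),
        method=method,
        metric=metric,
        linkage_matrix=Z,
    )


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str] | None = None) -> str:
    """Export a SciPy linkage matrix as a Newick string (branch lengths =
    merge-height differences)."""
    tree = to_tree(Z)
    n = tree.count
    if leaf_names is None:
        leaf_names = [str(i) for i in range(n)]

    def rec(node, parent_height) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def composition_table(
    assignment: ClusterAssignment | pd.Series,
    metadata: pd.DataFrame,
    factor: str,
) -> pd.DataFrame:
    """Cross-tabulate factor level x cluster (rows = levels, cols = clusters).

    ``metadata`` is indexed by cell id and must cover every clustered cell.
    """
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else assignment
    missing = labels.index.difference(metadata.index)
    if len(missing):
        raise ValueError(f"metadata missing for cells: {list(missing)[:5]}")
    levels = metadata.loc[labels.index, factor]
    return pd.crosstab(levels, labels.rename("cluster"))


@dataclass
class ClusterScoring:
    """Per-cluster 2/3-1/3 labels and the aggregate category summary.

    ``per_cluster`` columns: cluster, n_reference, n_total, reference_fraction,
    label.  ``summary`` is indexed by label with n_clusters, n_cells and
    percent of all cells.
    """

    per_cluster: pd.DataFrame
    summary: pd.DataFrame
    reference_level: str
    other_level: str


def score_clusters(
    table: pd.DataFrame,
    reference_level: str,
    lo: Fraction = Fraction(1, 3),
    hi: Fraction = Fraction(2, 3),
) -> ClusterScoring:
    """Label clusters predominant/mixed by the reference level's share.

    ``table`` is a 2 x k contingency table (rows = the two factor levels,
    columns = clusters).  A cluster is "predominantly <reference>" when the
    reference fraction is >= ``hi``, "predominantly <other>" when <= ``lo``,
    otherwise "mixed"; comparisons are exact rational arithmetic, so a
    2-of-6 cluster (exactly 1/3) is predominantly-other.
    """
    if table.shape[0] != 2:
        raise ValueError("scoring requires a two-level factor")
    if reference_level not in table.index:
        raise ValueError(f"{reference_level!r} not among factor levels {list(table.index)}")
    if not 0 < lo < hi < 1:
        raise ValueError("need 0 < lo < hi < 1")
    other_level = [lv for lv in table.index if lv != reference_level][0]
    rows = []
    for cluster in table.columns:
        n_ref = int(table.loc[reference_level, cluster])
        n_tot = int(table[cluster].sum())
        if n_tot == 0:
            raise ValueError(f"cluster {cluster} is empty")
        frac = Fraction(n_ref, n_tot)
        if frac >= hi:
            label = f"predominantly {reference_level}"
        elif frac <= lo:
            label = f"predominantly {other_level}"
        else:
            label = "mixed"
        rows.append(
            dict(cluster=cluster, n_reference=n_ref, n_total=n_tot,
                 reference_fraction=float(frac), label=label)
        )
    per_cluster = pd.DataFrame(rows)
    grand = per_cluster["n_total"].sum()
    order = [f"predominantly {reference_level}", f"predominantly {other_level}", "mixed"]
    summary = (
        per_cluster.groupby("label")
        .agg(n_clusters=("cluster", "size"), n_cells=("n_total", "sum"))
        .reindex(order, fill_value=0)
    )
    summary["percent"] = 100.0 * summary["n_cells"] / grand
    return ClusterScoring(
        per_cluster=per_cluster,
        summary=summary,
        reference_level=reference_level,
        other_level=other_level,
    )


def cramers_v(table: pd.DataFrame | np.ndarray) -> float:
    """Cramér's V association: sqrt(chi2 / (n * (min(r, c) - 1))).

    Pearson chi-square without continuity correction; a zero row or column
    margin makes the table degenerate and is rejected.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    chi2 = chi2_contingency(arr, correction=False)[0]
    n = arr.sum()
    return float(np.sqrt(chi2 / (n * (min(arr.shape) - 1))))


def group_marker_means(
    profiles: pd.DataFrame, by: Sequence[str] | str | None = None
) -> pd.DataFrame:
    """Mean fraction per marker for cell groups (treatment, sex, both, or All).

    ``profiles`` is a profiles_frame output; ``by`` is None (single "All"
    row), a column name, or a list of columns.  Each row reports the group
    n alongside the per-marker means of the f_ columns.
    """
    fcols = [c for c in profiles.columns if c.startswith("f_")]
    if not fcols:
        raise ValueError("profiles frame has no f_ columns")
    if by is None:
        out = profiles[fcols].mean().to_frame().T
        out.insert(0, "n", len(profiles))
        out.index = pd.Index(["All"], name="group")
        return out
    grouped = profiles.groupby(by)
    if any(n == 0 for n in grouped.size()):
        raise ValueError("empty group")
    out = grouped[fcols].mean()
    out.insert(0, "n", grouped.size())
    return out


def default_contrasts(
    group_levels: tuple[str, str], sex_levels: tuple[str, str]
) -> list[tuple[str, dict, dict]]:
    """The six standard contrasts: treatment within each sex and overall,
    sex within each treatment and overall."""
    g1, g2 = group_levels
    s1, s2 = sex_levels
    return [
        (f"{g1} vs {g2} (all)", {"group": g1}, {"group": g2}),
        (f"{g1} vs {g2} ({s1})", {"group": g1, "sex": s1}, {"group": g2, "sex": s1}),
        (f"{g1} vs {g2} ({s2})", {"group": g1, "sex": s2}, {"group": g2, "sex": s2}),
        (f"{s1} vs {s2} ({g1})", {"sex": s1, "group": g1}, {"sex": s2, "group": g1}),
        (f"{s1} vs {s2} ({g2})", {"sex": s1, "group": g2}, {"sex": s2, "group": g2}),
        (f"{s1} vs {s2} (all)", {"sex": s1}, {"sex": s2}),
    ]


def pairwise_marker_tests(
    profiles: pd.DataFrame,
    contrasts: list[tuple[str, dict, dict]] | None = None,
    markers: Sequence[int] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum tests per (contrast, marker) with BH adjustment across all.

    Each contrast selects two cell subsets by metadata equality; each
    marker's f_ values are compared by a two-sided Wilcoxon rank-sum test.
    Benjamini-Hochberg adjustment is applied jointly across the full
    contrast x marker family (6 x 7 = 42 tests for the default design), and
    significance is flagged at adjusted p < ``alpha``.
    """
    if contrasts is None:
        groups = sorted(profiles["group"].dropna().unique())
        sexes = sorted(profiles["sex"].dropna().unique())
        if len(groups) != 2 or len(sexes) != 2:
            raise ValueError("default contrasts need exactly two groups and two sexes")
        contrasts = default_contrasts(tuple(groups), tuple(sexes))
    fcols = [c for c in profiles.columns if c.startswith("f_")]
    if markers is None:
        markers = [int(c.split("_", 1)[1]) for c in fcols]

    def select(query: dict) -> pd.DataFrame:
        mask = pd.Series(True, index=profiles.index)
        for col, val in query.items():
            mask &= profiles[col] == val
        return profiles[mask]

    rows = []
    for name, qa, qb in contrasts:
        sub_a, sub_b = select(qa), select(qb)
        if len(sub_a) < 2 or len(sub_b) < 2:
            raise ValueError(f"contrast {name!r} has fewer than 2 cells per side")
        for m in markers:
            res = rank_sum_test(sub_a[f"f_{m}"], sub_b[f"f_{m}"])
            rows.append(
                dict(contrast=name, marker=m, n_a=len(sub_a), n_b=len(sub_b),
                     statistic=res.statistic, pvalue=res.pvalue, method=res.method)
            )
    out = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(out["pvalue"], alpha=alpha, method="fdr_bh")
    out["p_adjusted"] = p_adj
    out["significant"] = reject
    return out
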