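"""Two-way hierarchical clustering on Spearman-correlation distance.

Heatmap-style analysis of the normalized log2 matrix: rows (proteins) are
centred on their mean, pairwise distances are ``1 - rho`` with mid-rank
Spearman correlation, trees are average-linkage, and the two main groups
are read off by removing the final merge. A dilution-replicate QC checks
that technical dilution lanes of the same sample always cluster together
before any other sample's lane joins them — Spearman distance is invariant
to the per-lane dilution scaling, so this is a pure concordance check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from skbio.tree import TreeNode

from .datatypes import CountMatrix, Dataset, ValidationError


def _frame(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, CountMatrix) else matrix


def heatmap_scale(expr) -> pd.DataFrame:
    """Centre each protein (row) on its across-lane mean log2 value."""
    df = _frame(expr)
    return df.sub(df.mean(axis=1), axis=0)


def spearman_distance(matrix, axis: str = "columns") -> tuple[pd.DataFrame, list[str]]:
    """Symmetric ``1 - rho`` distance matrix between rows or columns.

    Items with constant profiles have undefined correlation; they are
    excluded and reported in the second return value.
    """
    df = _frame(matrix)
    if axis == "columns":
        df = df.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    if df.shape[0] < 2:
        raise ValidationError("need at least 2 items to compute distances")
    if df.shape[1] < 3:
        raise ValidationError("need at least 3 observations per item")
    ranks = np.apply_along_axis(rankdata, 1, df.to_numpy(dtype=float))
    sd = ranks.std(axis=1)
    excluded = [str(df.index[i]) for i in np.flatnonzero(sd == 0)]
    keep = np.flatnonzero(sd > 0)
    rho = np.corrcoef(ranks[keep])
    rho = np.clip(rho, -1.0, 1.0)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    items = df.index[keep]
    return pd.DataFrame(dist, index=items, columns=items), excluded


@dataclass
class ClusteringResult:
    items: list[str]
    linkage: np.ndarray  # scipy linkage matrix over ``items`` order
    leaf_order: list[str]
    two_cut: pd.Series  # item -> group label in {1, 2}

    def newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        tree = TreeNode.from_linkage_matrix(self.linkage, self.items)
        return str(tree).strip()


def hierarchical_cluster(
    distance: pd.DataFrame, linkage_method: str = "average"
) -> ClusteringResult:
    """Agglomerative clustering of a precomputed distance matrix.

    Items are pre-sorted lexicographically so distance ties break
    deterministically; the 2-group cut removes the final merge.
    """
    if distance.shape[0] != distance.shape[1]:
        raise ValidationError("distance matrix must be square")
    if distance.shape[0] < 2:
        raise ValidationError("need at least 2 items to cluster")
    order = sorted(distance.index)
    d = distance.loc[order, order].to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage_method)
    labels = hierarchy.fcluster(z, t=2, criterion="maxclust")
    leaf_order = [order[i] for i in hierarchy.leaves_list(z)]
    return ClusteringResult(
        items=list(order),
        linkage=z,
        leaf_order=leaf_order,
        two_cut=pd.Series(labels, index=order, name="cluster"),
    )


def two_way_cluster(
    expr, scale: bool = True, linkage_method: str = "average"
) -> tuple[ClusteringResult, ClusteringResult, pd.DataFrame]:
    """Cluster proteins (rows) and lanes (columns) of a log2 matrix.

    Returns (row result, column result, matrix used for clustering);
    by default the row-centred (heatmap-scaled) matrix.
    """
    df = heatmap_scale(expr) if scale else _frame(expr)
    row_dist, row_excluded = spearman_distance(df, axis="rows")
    col_dist, col_excluded = spearman_distance(df, axis="columns")
    rows = hierarchical_cluster(row_dist, linkage_method)
    cols = hierarchical_cluster(col_dist, linkage_method)
    if row_excluded or col_excluded:
        rows.two_cut.attrs["excluded"] = row_excluded
        cols.two_cut.attrs["excluded"] = col_excluded
    return rows, cols, df


# ------------------------------------------------------- dilution QC

def _leaf_sets(z: np.ndarray, n: int) -> list[set[int]]:
    """Leaf sets of every node (leaves then internal merges, scipy order)."""
    sets = [{i} for i in range(n)]
    for left, right, _, _ in z:
        sets.append(sets[int(left)] | sets[int(right)])
    return sets


def dilution_replicate_check(
    dataset: Dataset, linkage_method: str = "average"
) -> tuple[dict[str, bool], pd.DataFrame]:
    """Check that each sample's dilution replicates cluster together.

    Lanes are clustered on log2(raw endogenous counts + 0.5) with Spearman
    distance. A sample passes when the smallest subtree containing all its
    replicate lanes contains no other sample's lane.
    """
    meta = dataset.sample_frame()
    tagged = meta[meta["dilution_tag"].notna()]
    groups = tagged.groupby(["patient_id", "specimen"]).groups
    replicated = {k: list(v) for k, v in groups.items() if len(v) >= 2}
    if len(replicated) < 2:
        raise ValidationError(
            "dilution QC needs >= 2 samples with >= 2 dilution replicates"
        )
    lanes = sorted(l for lanes_ in replicated.values() for l in lanes_)
    endo = dataset.probes_of_class("endogenous")
    logs = np.log2(dataset.counts.values.loc[endo, lanes] + 0.5)
    dist, excluded = spearman_distance(logs, axis="columns")
    if excluded:
        raise ValidationError(f"constant lanes in dilution QC: {excluded}")
    result = hierarchical_cluster(dist, linkage_method)
    order = result.items
    index = {lane: i for i, lane in enumerate(order)}
    sets = _leaf_sets(result.linkage, len(order))

    passes: dict[str, bool] = {}
    rows = []
    for (patient, specimen), group_lanes in sorted(replicated.items()):
        target = {index[l] for l in group_lanes}
        enclosing = min(
            (s for s in sets if target <= s), key=len
        )  # smallest node containing all replicates
        ok = enclosing == target
        key = f"{patient}/{specimen}"
        passes[key] = bool(ok)
        rows.append(
            {
                "sample": key,
                "n_replicates": len(group_lanes),
                "lanes": ",".join(sorted(group_lanes)),
                "pass": bool(ok),
            }
        )
    return passes, pd.DataFrame(rows)
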