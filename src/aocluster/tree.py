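"""Hierarchical clustering of clusters from 1-AO distances, and merging.

The AO similarity matrix is converted to a distance (``1 - AO``) and the
clusters are agglomerated with a monotone linkage.  Because every pair is
standardized against one shared shuffle null, the pair with the highest
AO z-score is exactly the pair at the smallest 1-AO distance, so merging
"the most significant pair first" coincides with ordinary nearest-pair
agglomeration; the merge log reports both the AO and the z-score of each
step for interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ao import AOMatrix

__all__ = [
    "ClusterTree",
    "linkage_from_distance",
    "linkage_from_ao",
    "merge_to_k",
    "merge_with_recompute",
    "to_newick",
]

LINKAGES = ("average", "complete", "single")


@dataclass
class ClusterTree:
    """Agglomerative merge history over K leaf clusters.

    Nodes are numbered scipy-style: leaves ``0..K-1`` in ``leaf_ids``
    order, the node created by merge step ``s`` (0-based) is ``K + s``.
    ``merges`` holds ``(node_a, node_b, height, new_node_id)`` tuples in
    merge order; heights are non-decreasing for monotone linkages.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float, int]]
    method: str = "average"

    def __post_init__(self):
        k = len(self.leaf_ids)
        if len(self.merges) != max(k - 1, 0):
            raise ValueError(f"expected {k - 1} merges for {k} leaves")
        consumed: set[int] = set()
        for a, b, h, new in self.merges:
            if a in consumed or b in consumed:
                raise ValueError("a node may be consumed at most once")
            if h < 0:
                raise ValueError("merge heights must be non-negative")
            consumed.update((a, b))

    @property
    def k(self) -> int:
        return len(self.leaf_ids)

    def node_members(self, node: int) -> list[str]:
        """Leaf labels under ``node``, in leaf order."""
        k = self.k
        if node < k:
            return [self.leaf_ids[node]]
        a, b, _, _ = self.merges[node - k]
        return self.node_members(a) + self.node_members(b)

    def node_label(self, node: int) -> str:
        """Concatenated member labels (the merged cluster's name)."""
        return "+".join(self.node_members(node))

    def linkage_matrix(self) -> np.ndarray:
        """Scipy-format (K-1) x 4 linkage matrix for dendrogram plotting."""
        sizes = {i: 1 for i in range(self.k)}
        out = np.zeros((len(self.merges), 4))
        for s, (a, b, h, new) in enumerate(self.merges):
            sizes[new] = sizes[a] + sizes[b]
            out[s] = (a, b, h, sizes[new])
        return out


def linkage_from_distance(
    distance, ids: list[str] | None = None, method: str = "average"
) -> ClusterTree:
    """Agglomerate clusters from a symmetric distance matrix.

    Uses Lance–Williams updates for ``average`` (UPGMA), ``complete`` and
    ``single`` linkage.  Ties in distance are broken deterministically by
    the lexicographically smallest pair of (sorted) member-label tuples,
    so the merge order is identical across platforms.
    """
    if isinstance(distance, pd.DataFrame):
        if ids is None:
            ids = [str(c) for c in distance.columns]
        distance = distance.to_numpy()
    D = np.asarray(distance, dtype=float)
    k = D.shape[0]
    if D.shape != (k, k):
        raise ValueError("distance must be square")
    if k < 2:
        raise ValueError("need at least 2 clusters to build a tree")
    if not np.allclose(D, D.T):
        raise ValueError("distance must be symmetric")
    if ids is None:
        ids = [str(i) for i in range(k)]
    if method not in LINKAGES:
        raise ValueError(f"method must be one of {LINKAGES}")

    active = list(range(k))
    sizes = {i: 1 for i in range(k)}
    # tie-break key: sorted tuple of member leaf labels per node
    key: dict[int, tuple[str, ...]] = {i: (ids[i],) for i in range(k)}
    dist = {
        (i, j): float(D[i, j]) for i in range(k) for j in range(i + 1, k)
    }
    merges: list[tuple[int, int, float, int]] = []
    next_id = k
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = dist[(min(i, j), max(i, j))]
                tie = tuple(sorted((key[i], key[j])))
                cand = (d, tie, min(i, j), max(i, j))
                if best is None or cand < best:
                    best = cand
        d, _, i, j = best
        new = next_id
        next_id += 1
        merges.append((i, j, d, new))
        active.remove(i)
        active.remove(j)
        for other in active:
            dio = dist.pop((min(i, other), max(i, other)))
            djo = dist.pop((min(j, other), max(j, other)))
            if method == "average":
                dn = (sizes[i] * dio + sizes[j] * djo) / (sizes[i] + sizes[j])
            elif method == "complete":
                dn = max(dio, djo)
            else:
                dn = min(dio, djo)
            dist[(min(new, other), max(new, other))] = dn
        sizes[new] = sizes[i] + sizes[j]
        key[new] = tuple(sorted(key[i] + key[j]))
        active.append(new)
    return ClusterTree(leaf_ids=list(ids), merges=merges, method=method)


def linkage_from_ao(ao: AOMatrix, method: str = "average") -> ClusterTree:
    """Cluster tree from an AO matrix using the distance ``1 - AO``."""
    if ao.k < 2:
        raise ValueError("need at least 2 clusters to build a tree")
    return linkage_from_distance(1.0 - ao.similarity, ao.cluster_ids, method)


def to_newick(tree: ClusterTree, digits: int = 6) -> str:
    """Newick serialization with branch lengths from merge heights.

    A node's branch length is its parent's merge height minus its own
    (leaves sit at height 0), so a two-leaf tree at height h renders as
    ``(A:h,B:h);``.
    """
    k = tree.k
    heights = {i: 0.0 for i in range(k)}
    for a, b, h, new in tree.merges:
        heights[new] = h

    def render(node: int, parent_h: float) -> str:
        bl = max(parent_h - heights[node], 0.0)
        if node < k:
            return f"{tree.leaf_ids[node]}:{bl:.{digits}g}"
        a, b, h, _ = tree.merges[node - k]
        return f"({render(a, h)},{render(b, h)}):{bl:.{digits}g}"

    root = tree.merges[-1][3] if tree.merges else 0
    if not tree.merges:
        return f"{tree.leaf_ids[0]};"
    a, b, h, _ = tree.merges[-1]
    return f"({render(a, h)},{render(b, h)});"


def merge_to_k(
    labels,
    tree: ClusterTree,
    ao: AOMatrix | None = None,
    k_target: int = 1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Merge per-cell cluster labels along the tree until K groups remain.

    Applies the tree's first ``K - k_target`` merges, i.e. repeatedly
    joins the currently most similar pair (highest AO z-score under the
    shared null).  Returns the merged labels — each merged group named by
    the ``+``-concatenation of its member cluster labels — and a merge
    log with one row per step (step, merged_a, merged_b, ao, zscore).
    """
    labels = np.asarray(labels, dtype=object)
    k = tree.k
    if not 1 <= k_target <= k:
        raise ValueError(f"k_target must be in 1..{k}")
    observed = set(labels)
    known = set(tree.leaf_ids)
    if not observed <= known:
        raise ValueError(f"labels not in tree: {sorted(observed - known)[:5]}")

    current = labels.copy()
    log_rows = []
    for step, (a, b, h, new) in enumerate(tree.merges[: k - k_target], start=1):
        la, lb = tree.node_label(a), tree.node_label(b)
        merged = tree.node_label(new)
        current[(current == la) | (current == lb)] = merged
        sim = 1.0 - h
        row = {"step": step, "merged_a": la, "merged_b": lb, "ao": sim}
        if ao is not None:
            row["zscore"] = ao.null_model.zscore(sim)
        log_rows.append(row)
    cols = ["step", "merged_a", "merged_b", "ao"] + (
        ["zscore"] if ao is not None else []
    )
    return current, pd.DataFrame(log_rows, columns=cols)


def merge_with_recompute(
    data,
    k_target: int,
    n_markers: int = 25,
    m_shuffles: int = 1000,
    seed: int | None = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stricter merge variant: re-derive markers and AO after every merge.

    After each single merge of the most similar pair, the marker tables,
    top-k union and AO matrix are recomputed on the merged labels before
    choosing the next pair.  On well-separated data this agrees with the
    fixed-tree :func:`merge_to_k`; it is an explicit opt-in because it is
    K times more expensive.
    """
    from .markers import rank_all_clusters, rankings_on_union, top_k_union
    from .ao import pairwise_ao

    k0 = len(set(data.cluster_labels))
    if not 1 <= k_target <= k0:
        raise ValueError(f"k_target must be in 1..{k0}")
    work = data
    log_rows = []
    step = 0
    while len(set(work.cluster_labels)) > k_target:
        tables = rank_all_clusters(work)
        union = top_k_union(tables.values(), n_markers)
        rankings = rankings_on_union(tables.values(), union)
        ao = pairwise_ao(rankings, m_shuffles=m_shuffles, seed=seed)
        tri = ao.similarity.copy()
        np.fill_diagonal(tri, -np.inf)
        # highest-AO pair; lexicographic tie-break on the id pair
        best = None
        for i in range(ao.k):
            for j in range(i + 1, ao.k):
                pair_ids = tuple(sorted((ao.cluster_ids[i], ao.cluster_ids[j])))
                cand = (-tri[i, j], pair_ids)
                if best is None or cand < best:
                    best = cand
        sim = -best[0]
        la, lb = best[1]
        merged = "+".join(sorted(set(la.split("+")) | set(lb.split("+"))))
        new_labels = work.cluster_labels.copy()
        new_labels[(new_labels == la) | (new_labels == lb)] = merged
        work = work.with_labels(new_labels)
        step += 1
        log_rows.append(
            {
                "step": step,
                "merged_a": la,
                "merged_b": lb,
                "ao": sim,
                "zscore": ao.null_model.zscore(sim),
            }
        )
    return work.cluster_labels, pd.DataFrame(
        log_rows, columns=["step", "merged_a", "merged_b", "ao", "zscore"]
    )
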