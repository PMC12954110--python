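"""Per-cluster ranked marker genes via one-vs-rest Wilcoxon rank-sum tests.

Each cluster's marker ranking orders all genes by the significance of
their over-expression in the cluster relative to every other cell.  The
rankings feed the average-overlap comparison: the union of every
cluster's top-k markers forms a shared gene universe, and each cluster
re-ranks that union by its own full differential-expression ordering so
all lists have equal length.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ao import RankedList
from .dataset import LabeledDataset

__all__ = [
    "lognormalize",
    "rank_genes_vs_rest",
    "rank_all_clusters",
    "top_k_union",
    "rankings_on_union",
]

#: pseudocount used on de-logged means when forming fold changes
_LFC_EPS = 1e-9

MARKER_COLUMNS = [
    "cluster_id",
    "gene",
    "score",
    "p_value",
    "p_adj",
    "log_fold_change",
    "rank",
]


def lognormalize(data: LabeledDataset | np.ndarray) -> np.ndarray:
    """Library-size normalize to the median library size, then log1p.

    Each cell's counts are scaled so its total equals the median total
    across cells; a cell with zero total count is an error (it cannot be
    scaled and indicates missing upstream QC).
    """
    counts = data.counts if isinstance(data, LabeledDataset) else np.asarray(data)
    counts = np.atleast_2d(counts).astype(float)
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        if isinstance(data, LabeledDataset):
            names = [data.cell_ids[i] for i in zero[:5]]
        else:
            names = [f"row {i}" for i in zero[:5]]
        raise ValueError(f"cells with zero total count cannot be normalized: {names}")
    target = float(np.median(totals))
    return np.log1p(counts * (target / totals)[:, None])


@dataclass
class _DEWorkspace:
    """Cached per-dataset quantities shared by all one-vs-rest tests."""

    normalized: np.ndarray  # cells x genes, log-normalized
    ranks: np.ndarray       # per-gene midranks of normalized expression
    tie_term: np.ndarray    # per-gene sum of (t^3 - t) over tied groups


def prepare_de(data: LabeledDataset, normalized: np.ndarray | None = None) -> _DEWorkspace:
    if normalized is None:
        normalized = lognormalize(data)
    ranks = stats.rankdata(normalized, axis=0)
    n = normalized.shape[0]
    tie_term = np.empty(normalized.shape[1])
    for j in range(normalized.shape[1]):
        _, counts = np.unique(normalized[:, j], return_counts=True)
        tie_term[j] = np.sum(counts.astype(float) ** 3 - counts)
    return _DEWorkspace(normalized=normalized, ranks=ranks, tie_term=tie_term)


def _cluster_table(
    data: LabeledDataset, ws: _DEWorkspace, cluster_id: str
) -> pd.DataFrame:
    mask = data.cluster_labels == cluster_id
    n1 = int(mask.sum())
    n = data.n_cells
    n2 = n - n1
    if n1 < 2:
        raise ValueError(f"cluster {cluster_id!r} has fewer than 2 cells")
    if n2 < 1:
        raise ValueError(f"cluster {cluster_id!r} leaves an empty rest group")

    # tie-corrected normal approximation of the rank-sum statistic
    r1 = ws.ranks[mask].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    var = (n1 * n2 / 12.0) * ((n + 1) - ws.tie_term / (n * (n - 1.0)))
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (r1 - mu) / np.sqrt(var), 0.0)
    pvals = stats.norm.sf(z)  # one-sided: over-expression in the cluster
    p_adj = multipletests(pvals, method="fdr_bh")[1]

    mean_in = ws.normalized[mask].mean(axis=0)
    mean_rest = ws.normalized[~mask].mean(axis=0)
    lfc = np.log2(
        (np.expm1(mean_in) + _LFC_EPS) / (np.expm1(mean_rest) + _LFC_EPS)
    )

    tab = pd.DataFrame(
        {
            "cluster_id": cluster_id,
            "gene": data.gene_ids,
            "score": z,
            "p_value": pvals,
            "p_adj": p_adj,
            "log_fold_change": lfc,
        }
    )
    # total deterministic order: enrichment, then effect size, then gene ID
    tab = (
        tab.assign(abs_lfc=np.abs(lfc))
        .sort_values(["score", "abs_lfc", "gene"], ascending=[False, False, True])
        .drop(columns="abs_lfc")
    )
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab.reset_index(drop=True)[MARKER_COLUMNS]


def rank_genes_vs_rest(
    data: LabeledDataset,
    cluster_id: str,
    normalized: np.ndarray | None = None,
) -> pd.DataFrame:
    """One-vs-rest marker table for one cluster.

    Per gene, a two-sample Wilcoxon rank-sum test (normal approximation
    with tie correction) of in-cluster versus all remaining cells on the
    log-normalized expression.  Genes are ordered by the signed rank-sum
    z score (over-expression first), with |log2 fold change| and then the
    gene ID breaking ties, and assigned ranks 1..n_genes.

    Returns a DataFrame with columns
    ``cluster_id, gene, score, p_value, p_adj, log_fold_change, rank``.
    """
    if cluster_id not in set(data.cluster_labels):
        raise KeyError(f"no such cluster: {cluster_id!r}")
    return _cluster_table(data, prepare_de(data, normalized), cluster_id)


def rank_all_clusters(
    data: LabeledDataset, normalized: np.ndarray | None = None
) -> dict[str, pd.DataFrame]:
    """Marker tables for every cluster, sharing one rank workspace."""
    ws = prepare_de(data, normalized)
    return {c: _cluster_table(data, ws, c) for c in data.cluster_ids()}


def top_k_union(tables: Iterable[pd.DataFrame], k: int) -> list[str]:
    """Union of each cluster's top-``k`` marker genes, sorted.

    The union is the shared gene universe over which all clusters are
    re-ranked; its size lies in ``[k, K*k]`` for K clusters.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one marker table")
    if k < 1:
        raise ValueError("k must be positive")
    union: set[str] = set()
    for tab in tables:
        if k > len(tab):
            raise ValueError(f"k={k} exceeds table size {len(tab)}")
        top = tab.nsmallest(k, "rank")["gene"]
        union.update(top)
    return sorted(union)


def rankings_on_union(
    tables: Iterable[pd.DataFrame], union: Sequence[str]
) -> dict[str, RankedList]:
    """Re-rank the union genes by each cluster's own full DE ordering.

    The relative order of any two union genes in a cluster's list equals
    their relative order in that cluster's marker table, so every list
    has length ``|union|`` over the same universe.
    """
    union_set = set(union)
    if not union_set:
        raise ValueError("union must be non-empty")
    out: dict[str, RankedList] = {}
    for tab in tables:
        cid = tab["cluster_id"].iloc[0]
        genes = tab.sort_values("rank")["gene"]
        missing = union_set - set(genes)
        if missing:
            raise ValueError(
                f"union genes missing from table for cluster {cid!r}: "
                f"{sorted(missing)[:5]}"
            )
        out[cid] = RankedList([g for g in genes if g in union_set])
    return out
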