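"""Benchmarking harness: agreement metrics, purity, centroid distances,
baseline cluster-distance metrics, and composite-z reference annotation.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    fowlkes_mallows_score,
)

from .ao import average_overlap
from .dataset import LabeledDataset
from .markers import lognormalize, rankings_on_union, top_k_union

__all__ = [
    "EvaluationReport",
    "agreement_metrics",
    "average_cluster_purity",
    "centroid_expression_distance",
    "baseline_distance_matrix",
    "stouffer_composite",
    "score_marker_set_on_reference",
    "evaluate_labels",
]

BASELINE_METRICS = ("pearson", "spearman", "kendall", "euclidean", "direct_overlap", "ao")
FEATURE_KINDS = ("marker_expression", "principal_components")


@dataclass
class EvaluationReport:
    """Bundle of agreement scores for one merged labeling vs ground truth."""

    ari: float
    ami: float
    fms: float
    purity: float
    centroid_distance: float | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "ari": self.ari,
            "ami": self.ami,
            "fms": self.fms,
            "purity": self.purity,
            "centroid_distance": self.centroid_distance,
        }
        out.update(self.metadata)
        return out


def _check_lengths(truth, pred):
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError("truth and predicted labels must be equal-length vectors")
    return truth, pred


def agreement_metrics(truth, pred) -> tuple[float, float, float]:
    """Adjusted Rand index, adjusted mutual information, Fowlkes–Mallows.

    All three are invariant to label renaming and equal 1 when the two
    partitions coincide; ARI and AMI are chance-adjusted to ≈0 for
    random labelings.
    """
    truth, pred = _check_lengths(truth, pred)
    t = pd.factorize(truth)[0]
    p = pd.factorize(pred)[0]
    return (
        float(adjusted_rand_score(t, p)),
        float(adjusted_mutual_info_score(t, p)),
        float(fowlkes_mallows_score(t, p)),
    )


def average_cluster_purity(truth, pred, cell_weighted: bool = True) -> float:
    """Mean majority-truth fraction over predicted clusters.

    Per predicted cluster, purity is the fraction of its cells carrying
    the cluster's most common ground-truth label.  With
    ``cell_weighted=True`` (default) clusters are weighted by size, which
    equals the overall fraction of cells assigned to their cluster's
    majority identity; ``cell_weighted=False`` gives each cluster equal
    weight.
    """
    truth, pred = _check_lengths(truth, pred)
    df = pd.DataFrame({"truth": truth, "pred": pred})
    per_cluster = df.groupby("pred", sort=True)["truth"].agg(
        lambda s: s.value_counts().iloc[0] / len(s)
    )
    if cell_weighted:
        sizes = df["pred"].value_counts().reindex(per_cluster.index)
        return float((per_cluster * sizes).sum() / sizes.sum())
    return float(per_cluster.mean())


def _standardized_expression(data: LabeledDataset) -> tuple[np.ndarray, list[str]]:
    """Log-normalize then z-score each gene across cells.

    Genes with zero variance across cells are dropped with a warning
    (they carry no information and are not standardizable).
    """
    X = lognormalize(data)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance genes before standardization"
        )
    X = X[:, keep]
    sd = sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    genes = [g for g, k in zip(data.gene_ids, keep) if k]
    return Z, genes


def _majority_truth(truth: np.ndarray, mask: np.ndarray, truth_sizes: pd.Series) -> str:
    """Majority truth label of a cell subset; ties broken toward the
    larger truth population, then lexicographically."""
    counts = pd.Series(truth[mask]).value_counts()
    top = counts[counts == counts.iloc[0]].index
    if len(top) == 1:
        return top[0]
    ranked = sorted(top, key=lambda t: (-truth_sizes[t], t))
    return ranked[0]


def centroid_expression_distance(
    data: LabeledDataset, merged=None
) -> tuple[pd.Series, float]:
    """Euclidean distance between merged-cluster and truth centroids.

    Expression is log-normalized and scaled to zero mean / unit variance
    per gene across all cells; each merged cluster is matched to its
    majority ground-truth population, and the distance between the two
    centroid vectors is returned per cluster along with the mean.
    """
    if data.truth_labels is None:
        raise ValueError("dataset has no ground-truth labels")
    labels = np.asarray(
        merged if merged is not None else data.cluster_labels, dtype=object
    )
    truth = data.truth_labels
    Z, _ = _standardized_expression(data)
    truth_sizes = pd.Series(truth).value_counts()
    truth_centroids = {
        t: Z[truth == t].mean(axis=0) for t in truth_sizes.index
    }
    dists = {}
    for c in sorted(set(labels)):
        mask = labels == c
        match = _majority_truth(truth, mask, truth_sizes)
        dists[c] = float(
            np.linalg.norm(Z[mask].mean(axis=0) - truth_centroids[match])
        )
    per_cluster = pd.Series(dists)
    return per_cluster, float(per_cluster.mean())


def _cluster_marker_features(
    data: LabeledDataset, tables: Sequence[pd.DataFrame], n_markers: int
) -> pd.DataFrame:
    """Per-cluster mean log-normalized expression over the union marker set."""
    union = top_k_union(tables, n_markers)
    X = lognormalize(data)
    cols = {g: i for i, g in enumerate(data.gene_ids)}
    idx = [cols[g] for g in union]
    rows = {}
    for tab in tables:
        c = tab["cluster_id"].iloc[0]
        mask = data.cluster_labels == c
        rows[c] = X[np.asarray(mask)][:, idx].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=union)


def _cluster_pc_features(
    data: LabeledDataset, clusters: Sequence[str], n_pcs: int
) -> pd.DataFrame:
    """Per-cluster mean of cell scores on the first ``n_pcs`` components."""
    Z, _ = _standardized_expression(data)
    n_pcs = min(n_pcs, min(Z.shape) - 1)
    scores = PCA(n_components=n_pcs, random_state=0).fit_transform(Z)
    rows = {
        c: scores[np.asarray(data.cluster_labels == c)].mean(axis=0)
        for c in clusters
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def baseline_distance_matrix(
    data: LabeledDataset,
    tables: Sequence[pd.DataFrame],
    metric: str = "ao",
    features: str = "marker_expression",
    n_markers: int = 25,
    n_pcs: int = 50,
) -> pd.DataFrame:
    """K x K cluster distance matrix under a chosen metric and feature set.

    Correlation metrics (``pearson``, ``spearman``, ``kendall``) and
    ``euclidean`` operate on cluster-level feature vectors: the mean
    expression of the union marker genes, or the cluster-mean of cell
    principal-component scores.  Correlations become distances as
    ``1 - r`` (anticorrelated clusters are maximally distant).

    ``direct_overlap`` is the un-ranked baseline
    ``1 - |top-k(a) ∩ top-k(b)| / k`` on the clusters' top-``n_markers``
    sets, and ``ao`` is ``1 - AO`` on the union re-rankings; both ignore
    ``features``.
    """
    if metric not in BASELINE_METRICS:
        raise ValueError(f"metric must be one of {BASELINE_METRICS}")
    if features not in FEATURE_KINDS:
        raise ValueError(f"features must be one of {FEATURE_KINDS}")
    tables = list(tables)
    ids = [tab["cluster_id"].iloc[0] for tab in tables]
    k = len(ids)
    D = np.zeros((k, k))

    if metric == "ao":
        union = top_k_union(tables, n_markers)
        rankings = rankings_on_union(tables, union)
        for i in range(k):
            for j in range(i + 1, k):
                d = 1.0 - average_overlap(rankings[ids[i]], rankings[ids[j]])
                D[i, j] = D[j, i] = d
        return pd.DataFrame(D, index=ids, columns=ids)

    if metric == "direct_overlap":
        tops = [set(tab.nsmallest(n_markers, "rank")["gene"]) for tab in tables]
        for i in range(k):
            for j in range(i + 1, k):
                d = 1.0 - len(tops[i] & tops[j]) / n_markers
                D[i, j] = D[j, i] = d
        return pd.DataFrame(D, index=ids, columns=ids)

    if features == "marker_expression":
        feats = _cluster_marker_features(data, tables, n_markers)
    else:
        feats = _cluster_pc_features(data, ids, n_pcs)
    feats = feats.loc[ids]
    V = feats.to_numpy()
    for i in range(k):
        for j in range(i + 1, k):
            if metric == "euclidean":
                d = float(np.linalg.norm(V[i] - V[j]))
            elif metric == "pearson":
                d = 1.0 - float(stats.pearsonr(V[i], V[j])[0])
            elif metric == "spearman":
                d = 1.0 - float(stats.spearmanr(V[i], V[j])[0])
            else:  # kendall
                d = 1.0 - float(stats.kendalltau(V[i], V[j])[0])
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=ids, columns=ids)


def stouffer_composite(z_values: Iterable[float]) -> float:
    """Stouffer's method: ``sum(z_i) / sqrt(n)`` for n z-scores."""
    z = np.asarray(list(z_values), dtype=float)
    if z.size == 0:
        raise ValueError("need at least one z-value")
    return float(z.sum() / np.sqrt(z.size))


def score_marker_set_on_reference(
    markers: Iterable[str], reference: pd.DataFrame
) -> pd.Series:
    """Composite-z profile of a marker set across reference populations.

    ``reference`` is a genes x populations expression matrix (e.g. sorted
    bulk populations).  Each gene's expression is z-scored across
    populations; per population, the marker genes' z-values are combined
    with Stouffer's method.  The resulting per-population profile drives
    cluster annotation (the population with the highest composite z is
    the best match).  Constant-expression genes have undefined z and are
    dropped with a warning.
    """
    markers = [m for m in markers]
    present = [m for m in markers if m in reference.index]
    if not present:
        raise ValueError("no marker genes found in the reference matrix")
    sub = reference.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant reference rows (undefined z)"
        )
        sub = sub.loc[~constant]
        sd = sd[~constant]
    if sub.empty:
        raise ValueError("all marker genes have constant reference expression")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return pd.Series(
        {pop: stouffer_composite(z[pop].to_numpy()) for pop in reference.columns},
        name="composite_z",
    )


def evaluate_labels(
    data: LabeledDataset, pred=None, with_centroids: bool = True, **metadata
) -> EvaluationReport:
    """Full report of a predicted labeling against the dataset's truth."""
    if data.truth_labels is None:
        raise ValueError("dataset has no ground-truth labels")
    pred = np.asarray(
        pred if pred is not None else data.cluster_labels, dtype=object
    )
    ari, ami, fms = agreement_metrics(data.truth_labels, pred)
    purity = average_cluster_purity(data.truth_labels, pred)
    centroid = (
        centroid_expression_distance(data, pred)[1] if with_centroids else None
    )
    return EvaluationReport(
        ari=ari, ami=ami, fms=fms, purity=purity,
        centroid_distance=centroid, metadata=metadata,
    )
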