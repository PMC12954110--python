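"""End-to-end orchestration: markers → union → AO → tree → merge, and the
multi-seed benchmark loop comparing AO against baseline cluster metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ao import AOMatrix, pairwise_ao
from .dataset import LabeledDataset
from .evaluation import (
    BASELINE_METRICS,
    average_cluster_purity,
    agreement_metrics,
    baseline_distance_matrix,
    centroid_expression_distance,
)
from .markers import rank_all_clusters, rankings_on_union, top_k_union
from .simulate import SimulationConfig, simulate, split_clusters
from .tree import ClusterTree, linkage_from_ao, linkage_from_distance, merge_to_k

__all__ = ["AOPipelineResult", "run_ao_pipeline", "run_benchmark", "derive_seeds"]


def derive_seeds(seed: int, n: int) -> list[int]:
    """Expand one global seed into ``n`` independent per-stage seeds."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


@dataclass
class AOPipelineResult:
    """Artifacts of one AO comparison run over a labeled dataset."""

    tables: dict[str, pd.DataFrame]
    union: list[str]
    rankings: dict
    ao: AOMatrix
    tree: ClusterTree
    merged_labels: np.ndarray | None = None
    merge_log: pd.DataFrame | None = None

    def marker_frame(self) -> pd.DataFrame:
        return pd.concat(self.tables.values(), ignore_index=True)


def run_ao_pipeline(
    data: LabeledDataset,
    n_markers: int = 25,
    m_shuffles: int = 1000,
    seed: int | None = 0,
    linkage: str = "average",
    k_target: int | None = None,
) -> AOPipelineResult:
    """Marker ranking → top-k union → pairwise AO → tree (→ merge).

    ``n_markers`` is the per-cluster top-k included in the global union
    (default 25); the shuffle null is built once for the union length
    with ``m_shuffles`` draws.  If ``k_target`` is given, cluster labels
    are merged along the tree until that many groups remain.
    """
    tables = rank_all_clusters(data)
    union = top_k_union(tables.values(), n_markers)
    rankings = rankings_on_union(tables.values(), union)
    ao = pairwise_ao(rankings, m_shuffles=m_shuffles, seed=seed)
    tree = linkage_from_ao(ao, method=linkage)
    result = AOPipelineResult(
        tables=tables, union=union, rankings=rankings, ao=ao, tree=tree
    )
    if k_target is not None:
        result.merged_labels, result.merge_log = merge_to_k(
            data.cluster_labels, tree, ao, k_target
        )
    return result


def _merged_labels_for_metric(
    data: LabeledDataset,
    tables: list[pd.DataFrame],
    metric: str,
    features: str,
    n_markers: int,
    k_target: int,
    linkage: str,
    m_shuffles: int,
    seed: int,
) -> np.ndarray:
    D = baseline_distance_matrix(
        data, tables, metric=metric, features=features, n_markers=n_markers
    )
    tree = linkage_from_distance(D, method=linkage)
    ao = None
    if metric == "ao":
        union = top_k_union(tables, n_markers)
        rankings = rankings_on_union(tables, union)
        ao = pairwise_ao(rankings, m_shuffles=m_shuffles, seed=seed)
    merged, _ = merge_to_k(data.cluster_labels, tree, ao, k_target)
    return merged


def run_benchmark(
    config: SimulationConfig | None = None,
    seeds=range(20),
    metrics=BASELINE_METRICS,
    features: str = "marker_expression",
    n_markers_list=(25,),
    k_target: int | None = None,
    linkage: str = "average",
    m_shuffles: int = 1000,
    with_centroids: bool = True,
) -> pd.DataFrame:
    """Repeated simulate → over-cluster → merge → score, per metric.

    For each seed a fresh dataset is drawn from ``config`` (default
    benchmark scenario), its configured populations are split into
    pseudo-clusters, and for every (metric, n_markers) combination the
    pseudo-clusters are merged back to ``k_target`` groups (default: the
    number of true populations) guided by that metric's distance matrix.
    Agreement with the planted truth is recorded per run.

    Returns a long-format frame with columns
    ``seed, metric, features, n_markers, ari, ami, fms, purity,
    centroid_distance``.
    """
    base = config or SimulationConfig()
    rows = []
    for s in seeds:
        run_seed = int(s)
        sim_cfg = SimulationConfig(
            **{**base.__dict__, "seed": run_seed}
        )
        sim = simulate(sim_cfg)
        data = split_clusters(sim)
        kt = k_target or sim_cfg.n_populations
        tables = list(rank_all_clusters(data).values())
        for n_markers in n_markers_list:
            for metric in metrics:
                merged = _merged_labels_for_metric(
                    data,
                    tables,
                    metric=metric,
                    features=features,
                    n_markers=n_markers,
                    k_target=kt,
                    linkage=linkage,
                    m_shuffles=m_shuffles,
                    seed=run_seed,
                )
                ari, ami, fms = agreement_metrics(data.truth_labels, merged)
                purity = average_cluster_purity(data.truth_labels, merged)
                centroid = (
                    centroid_expression_distance(data, merged)[1]
                    if with_centroids
                    else np.nan
                )
                rows.append(
                    {
                        "seed": run_seed,
                        "metric": metric,
                        "features": features,
                        "n_markers": n_markers,
                        "ari": ari,
                        "ami": ami,
                        "fms": fms,
                        "purity": purity,
                        "centroid_distance": centroid,
                    }
                )
    return pd.DataFrame(rows)
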