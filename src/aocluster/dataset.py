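"""In-memory container for a labeled cells x genes count matrix."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset"]


@dataclass
class LabeledDataset:
    """Counts plus per-cell cluster labels (and optional ground truth).

    Parameters
    ----------
    counts
        Dense cells x genes matrix of non-negative integer counts.
    gene_ids, cell_ids
        Distinct identifiers for columns / rows.
    cluster_labels
        Per-cell cluster assignment from any upstream community-detection
        step (Leiden, Louvain, ...).  Every cluster must contain at least
        two cells so one-vs-rest differential expression is defined.
    truth_labels
        Optional per-cell ground-truth identity used only for evaluation.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cluster_labels: np.ndarray
    truth_labels: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells x genes matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts columns")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match counts rows")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be distinct")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids must be distinct")
        self.cluster_labels = np.asarray(self.cluster_labels, dtype=object)
        if self.cluster_labels.shape != (n_cells,):
            raise ValueError("cluster_labels must have one entry per cell")
        sizes = pd.Series(self.cluster_labels).value_counts()
        small = sizes[sizes < 2]
        if len(small):
            raise ValueError(
                f"every cluster needs >= 2 cells; too small: {list(small.index)}"
            )
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels, dtype=object)
            if self.truth_labels.shape != (n_cells,):
                raise ValueError("truth_labels must have one entry per cell")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def cluster_ids(self) -> list[str]:
        """Cluster labels in deterministic (sorted) order."""
        return sorted(set(self.cluster_labels))

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(self.cluster_labels).value_counts().sort_index()

    def with_labels(self, new_labels) -> "LabeledDataset":
        """Copy of the dataset with replaced cluster labels."""
        return replace(self, cluster_labels=np.asarray(new_labels, dtype=object))

    def to_anndata(self):
        """Export as an AnnData for interoperability with scanpy workflows."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.astype(np.float32),
            obs=pd.DataFrame(
                {"cluster": pd.Categorical(self.cluster_labels)},
                index=self.cell_ids,
            ),
            var=pd.DataFrame(index=self.gene_ids),
        )
        if self.truth_labels is not None:
            adata.obs["truth"] = pd.Categorical(self.truth_labels)
        return adata

    @classmethod
    def from_anndata(cls, adata, cluster_key: str = "cluster", truth_key: str | None = None):
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        truth = (
            np.asarray(adata.obs[truth_key], dtype=object)
            if truth_key is not None
            else None
        )
        return cls(
            counts=np.asarray(X),
            gene_ids=list(adata.var_names),
            cell_ids=list(adata.obs_names),
            cluster_labels=np.asarray(adata.obs[cluster_key], dtype=object),
            truth_labels=truth,
        )
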