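"""Reading and writing the standard on-disk formats.

Counts are accepted as Matrix Market (``matrix.mtx`` with ``genes.tsv`` /
``barcodes.tsv`` companions) or dense CSV (cells x genes with a header of
gene IDs and an index of cell IDs); labels as two-column TSVs.  Result
artifacts — marker tables, AO matrices, Newick trees, merge logs — are
plain CSV/TSV/text so runs are diffable and portable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .ao import AOMatrix, RankedList
from .dataset import LabeledDataset
from .markers import MARKER_COLUMNS

__all__ = [
    "read_labels_tsv",
    "write_labels_tsv",
    "read_counts_csv",
    "read_counts_mtx",
    "write_counts_mtx",
    "write_counts_csv",
    "load_dataset",
    "write_dataset",
    "read_rankings_tsv",
    "write_rankings_tsv",
    "write_ao_matrix",
    "write_marker_tables",
    "read_marker_tables",
    "write_provenance",
]


def read_labels_tsv(path) -> pd.Series:
    """Two-column TSV (cell_id, label) → Series indexed by cell_id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"], dtype=str)
    if df["cell_id"].duplicated().any():
        raise ValueError(f"duplicate cell IDs in {path}")
    return df.set_index("cell_id")["label"]


def write_labels_tsv(labels, cell_ids, path) -> None:
    pd.DataFrame({"cell_id": cell_ids, "label": labels}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_counts_csv(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense cells x genes CSV → (counts, gene_ids, cell_ids)."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(), [str(g) for g in df.columns], [str(c) for c in df.index]


def read_counts_mtx(directory) -> tuple[np.ndarray, list[str], list[str]]:
    """Matrix Market triplet plus genes.tsv / barcodes.tsv companions.

    The matrix may be stored either cells x genes or genes x cells; the
    orientation is resolved from the companion file lengths.
    """
    directory = Path(directory)
    mat = sio.mmread(directory / "matrix.mtx")
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    if dense.shape == (len(cells), len(genes)):
        pass
    elif dense.shape == (len(genes), len(cells)):
        dense = dense.T
    else:
        raise ValueError(
            f"matrix shape {dense.shape} matches neither orientation of "
            f"{len(cells)} barcodes x {len(genes)} genes"
        )
    return dense, list(genes), list(cells)


def write_counts_mtx(data: LabeledDataset, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(directory / "matrix.mtx", sparse.coo_matrix(data.counts))
    pd.Series(data.gene_ids).to_csv(
        directory / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(data.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def write_counts_csv(data: LabeledDataset, path) -> None:
    pd.DataFrame(
        data.counts, index=data.cell_ids, columns=data.gene_ids
    ).to_csv(path)


def load_dataset(
    counts_path, labels_path, truth_path=None
) -> LabeledDataset:
    """Assemble a LabeledDataset from counts (CSV file or MTX directory)
    plus label TSVs, aligning labels to the counts' cell order."""
    counts_path = Path(counts_path)
    if counts_path.is_dir():
        counts, genes, cells = read_counts_mtx(counts_path)
    else:
        counts, genes, cells = read_counts_csv(counts_path)
    labels = read_labels_tsv(labels_path)
    missing = [c for c in cells if c not in labels.index]
    if missing:
        raise ValueError(f"cells missing from label file: {missing[:5]}")
    cluster = labels.reindex(cells).to_numpy(dtype=object)
    truth = None
    if truth_path is not None:
        tl = read_labels_tsv(truth_path)
        truth = tl.reindex(cells).to_numpy(dtype=object)
    return LabeledDataset(
        counts=counts,
        gene_ids=genes,
        cell_ids=cells,
        cluster_labels=cluster,
        truth_labels=truth,
    )


def write_dataset(data: LabeledDataset, directory, fmt: str = "mtx") -> None:
    """Write counts (+ labels) in the formats the loaders read back."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        write_counts_mtx(data, directory)
    elif fmt == "csv":
        write_counts_csv(data, directory / "counts.csv")
    else:
        raise ValueError("fmt must be 'mtx' or 'csv'")
    write_labels_tsv(data.cluster_labels, data.cell_ids, directory / "clusters.tsv")
    if data.truth_labels is not None:
        write_labels_tsv(data.truth_labels, data.cell_ids, directory / "truth.tsv")


def write_rankings_tsv(rankings: dict, path) -> None:
    """Ranked lists as TSV with columns cluster_id, rank (1-based), gene."""
    rows = [
        {"cluster_id": c, "rank": r + 1, "gene": g}
        for c, rl in rankings.items()
        for r, g in enumerate(rl)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rankings_tsv(path) -> dict[str, RankedList]:
    df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str, "gene": str})
    out = {}
    for cid, grp in df.groupby("cluster_id", sort=True):
        grp = grp.sort_values("rank")
        if list(grp["rank"]) != list(range(1, len(grp) + 1)):
            raise ValueError(f"ranks for cluster {cid!r} are not 1..n")
        out[cid] = RankedList(grp["gene"])
    return out


def write_ao_matrix(ao: AOMatrix, directory, prefix: str = "ao") -> None:
    """Similarity and z-score matrices as two CSVs with cluster-ID axes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ao.similarity_frame().to_csv(directory / f"{prefix}_similarity.csv")
    ao.zscore_frame().to_csv(directory / f"{prefix}_zscore.csv")


def write_marker_tables(tables, path) -> None:
    frames = list(tables.values()) if isinstance(tables, dict) else list(tables)
    pd.concat(frames, ignore_index=True)[MARKER_COLUMNS].to_csv(path, index=False)


def read_marker_tables(path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path, dtype={"cluster_id": str, "gene": str})
    return {
        cid: grp.reset_index(drop=True)
        for cid, grp in df.groupby("cluster_id", sort=True)
    }


def write_provenance(directory, **fields) -> None:
    """Record everything needed to re-run a command bit-identically."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "provenance.json", "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=str)
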