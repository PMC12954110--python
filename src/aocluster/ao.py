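"""Average overlap (AO) between ranked gene lists.

AO is a top-weighted similarity between two ranked lists: the mean, over
depths ``d = 1..N``, of the fraction of shared elements among each list's
top ``d``.  Differences near the top of the rankings are counted at every
depth and therefore cost more than differences near the bottom, which is
what makes AO suitable for comparing marker-gene rankings, where the most
differentially expressed genes carry the most identity information.

Significance is assessed against a shuffle null: AO computed over
uniformly random permutation pairs of an ``N``-element universe is
approximately normal with mean ``(N + 1) / (2 N)`` (≈ 0.5 for long
lists), so ``z = (AO - mu_null) / sd_null`` calibrates observed
similarities.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RankedList",
    "NullModel",
    "AOMatrix",
    "overlap_at_depth",
    "average_overlap",
    "ao_distance",
    "null_distribution",
    "ao_zscore",
    "pairwise_ao",
]

#: largest list length for which the exhaustive null enumerates all
#: relative permutations (7! = 5040)
EXHAUSTIVE_MAX_N = 7


class RankedList(Sequence):
    """An ordered list of distinct gene identifiers.

    Represents one cluster's differential-expression ranking: position 0
    is the most enriched gene.  Items must be distinct and the list
    non-empty.
    """

    __slots__ = ("items", "_index")

    def __init__(self, items: Iterable[str]):
        items = tuple(items)
        if len(items) == 0:
            raise ValueError("a RankedList must contain at least one item")
        index = {g: i for i, g in enumerate(items)}
        if len(index) != len(items):
            raise ValueError("RankedList items must be distinct")
        self.items = items
        self._index = index

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __contains__(self, g) -> bool:
        return g in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, RankedList) and self.items == other.items

    def __hash__(self) -> int:
        return hash(self.items)

    def __repr__(self) -> str:
        shown = ",".join(self.items[:4]) + ("…" if len(self) > 4 else "")
        return f"RankedList(n={len(self)}, [{shown}])"

    def position(self, gene: str) -> int:
        """0-based position of *gene* (raises ``KeyError`` if absent)."""
        return self._index[gene]


def as_ranked_list(x) -> RankedList:
    return x if isinstance(x, RankedList) else RankedList(x)


@dataclass(frozen=True)
class NullModel:
    """Shuffle-null calibration of AO for lists of a fixed length.

    ``mean`` and ``sd`` are the AO sample mean and standard deviation over
    ``n_shuffles`` independent uniformly random permutation pairs of a
    ``list_length``-element universe (or over all relative permutations in
    exhaustive mode, where ``n_shuffles`` equals ``list_length!``).
    """

    list_length: int
    n_shuffles: int
    mean: float
    sd: float
    seed: int | None
    exhaustive: bool = False

    def zscore(self, ao_value: float) -> float:
        return ao_zscore(ao_value, self)


@dataclass
class AOMatrix:
    """Pairwise AO similarities and z-scores between K clusters."""

    cluster_ids: list[str]
    similarity: np.ndarray
    zscore: np.ndarray
    null_model: NullModel = field(repr=False)

    def __post_init__(self):
        k = len(self.cluster_ids)
        self.similarity = np.asarray(self.similarity, dtype=float)
        self.zscore = np.asarray(self.zscore, dtype=float)
        if self.similarity.shape != (k, k) or self.zscore.shape != (k, k):
            raise ValueError("matrix shapes must be K x K")

    @property
    def k(self) -> int:
        return len(self.cluster_ids)

    def similarity_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.similarity, index=self.cluster_ids, columns=self.cluster_ids
        )

    def zscore_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.zscore, index=self.cluster_ids, columns=self.cluster_ids
        )

    def distance_frame(self) -> pd.DataFrame:
        """1 - AO, the distance used for hierarchical clustering."""
        return 1.0 - self.similarity_frame()


def overlap_at_depth(a, b, d: int) -> float:
    """Fraction of shared elements among the top-``d`` of both lists.

    ``|top-d(a) ∩ top-d(b)| / d`` for ``1 <= d <= min(len(a), len(b))``.
    """
    a, b = as_ranked_list(a), as_ranked_list(b)
    if not isinstance(d, (int, np.integer)):
        raise TypeError("depth must be an integer")
    if d < 1 or d > min(len(a), len(b)):
        raise ValueError(
            f"depth {d} out of range 1..{min(len(a), len(b))}"
        )
    return len(set(a.items[:d]) & set(b.items[:d])) / d


def _overlap_counts(a: RankedList, b: RankedList) -> np.ndarray:
    """Cumulative intersection sizes ``|top-d(a) ∩ top-d(b)|`` for d=1..N.

    A shared gene enters the running intersection at depth
    ``max(pos_a, pos_b) + 1``; genes absent from either list never do.
    """
    n = len(a)
    deepest = [
        max(i, b.position(g)) for i, g in enumerate(a.items) if g in b
    ]
    if not deepest:
        return np.zeros(n, dtype=np.int64)
    counts = np.bincount(np.asarray(deepest, dtype=np.intp), minlength=n)
    return np.cumsum(counts)


def average_overlap(a, b) -> float:
    """AO similarity: mean of ``overlap_at_depth`` over all depths 1..N.

    Both lists must have the same length N (rankings over a shared gene
    universe have equal length by construction).  Returns a value in
    [0, 1]; 1 iff the lists are element-wise identical, 0 iff their
    contents are disjoint.
    """
    a, b = as_ranked_list(a), as_ranked_list(b)
    if len(a) != len(b):
        raise ValueError(
            f"lists must have equal length (got {len(a)} and {len(b)})"
        )
    n = len(a)
    cum = _overlap_counts(a, b)
    return float(np.mean(cum / np.arange(1, n + 1)))


def ao_distance(a, b) -> float:
    """``1 - average_overlap(a, b)``; 0 iff identical orderings."""
    return 1.0 - average_overlap(a, b)


def _ao_null_samples(n: int, m_shuffles: int, rng: np.random.Generator) -> np.ndarray:
    """AO for ``m_shuffles`` independent random permutation pairs of size n."""
    depths = np.arange(1, n + 1)
    inv = np.empty(n, dtype=np.intp)
    out = np.empty(m_shuffles)
    idx = np.arange(n, dtype=np.intp)
    for s in range(m_shuffles):
        p = rng.permutation(n)
        q = rng.permutation(n)
        inv[q] = idx  # inv[v] = position of value v in q
        deepest = np.maximum(idx, inv[p])
        cum = np.cumsum(np.bincount(deepest, minlength=n))
        out[s] = np.mean(cum / depths)
    return out


def _ao_identity_vs(perm: Sequence[int], n: int) -> float:
    """AO of the identity ranking 0..n-1 against an integer permutation."""
    inv = np.empty(n, dtype=np.intp)
    inv[list(perm)] = np.arange(n, dtype=np.intp)
    deepest = np.maximum(np.arange(n), inv)
    cum = np.cumsum(np.bincount(deepest, minlength=n))
    return float(np.mean(cum / np.arange(1, n + 1)))


def null_distribution(
    n: int,
    m_shuffles: int = 1000,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> NullModel:
    """Calibrate the AO shuffle null for lists of length ``n``.

    Draws ``m_shuffles`` independent uniformly random permutation pairs of
    an ``n``-element universe and records the AO sample mean and standard
    deviation (ddof=1).  Deterministic given ``seed``.

    With ``exhaustive=True`` (``n`` <= 7) all ``n!`` relative permutations
    are enumerated against the identity instead — AO is invariant under
    relabelling the universe, so one fixed reference list covers every
    permutation pair — and population statistics are returned.

    The expected null mean has the closed form ``(n + 1) / (2 n)``: at
    depth d the intersection of two random top-d sets is hypergeometric
    with mean d²/n, so the expected overlap fraction is d/n and the mean
    over depths is (n + 1) / (2 n).
    """
    if n < 2:
        raise ValueError("null model needs list length >= 2 (sd undefined for n=1)")
    if exhaustive:
        if n > EXHAUSTIVE_MAX_N:
            raise ValueError(
                f"exhaustive enumeration limited to n <= {EXHAUSTIVE_MAX_N}"
            )
        samples = np.array(
            [_ao_identity_vs(p, n) for p in itertools.permutations(range(n))]
        )
        return NullModel(
            list_length=n,
            n_shuffles=len(samples),
            mean=float(samples.mean()),
            sd=float(samples.std(ddof=0)),
            seed=None,
            exhaustive=True,
        )
    if m_shuffles < 2:
        raise ValueError("m_shuffles must be >= 2")
    rng = np.random.default_rng(seed)
    samples = _ao_null_samples(n, m_shuffles, rng)
    return NullModel(
        list_length=n,
        n_shuffles=m_shuffles,
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)),
        seed=seed,
    )


def ao_zscore(ao_value: float, null: NullModel) -> float:
    """Standardize an AO value against the shuffle null."""
    if null.sd <= 0 or not math.isfinite(null.sd):
        raise ValueError("degenerate null model: sd must be positive")
    return (ao_value - null.mean) / null.sd


def pairwise_ao(
    rankings: Mapping[str, RankedList | Sequence[str]],
    null: NullModel | None = None,
    m_shuffles: int = 1000,
    seed: int | None = 0,
) -> AOMatrix:
    """Pairwise AO similarity and z-score matrices between clusters.

    All rankings must be permutations of the same gene universe (as
    produced by re-ranking the union marker set).  If ``null`` is None a
    shuffle null for the common list length is built with ``m_shuffles``
    draws and ``seed``.
    """
    ids = list(rankings)
    if not ids:
        raise ValueError("rankings must be non-empty")
    lists = [as_ranked_list(rankings[c]) for c in ids]
    n = len(lists[0])
    universe = set(lists[0].items)
    for c, rl in zip(ids, lists):
        if len(rl) != n or set(rl.items) != universe:
            raise ValueError(
                f"ranking for cluster {c!r} is not over the shared gene universe"
            )
    if null is None:
        null = null_distribution(n, m_shuffles=m_shuffles, seed=seed)
    if null.list_length != n:
        raise ValueError(
            f"null model is for length {null.list_length}, rankings have length {n}"
        )

    # integer positions per cluster: pos[c][g_code] = rank index of gene g
    order = sorted(universe)
    code = {g: i for i, g in enumerate(order)}
    pos = np.empty((len(ids), n), dtype=np.intp)
    for r, rl in enumerate(lists):
        for i, g in enumerate(rl.items):
            pos[r, code[g]] = i

    k = len(ids)
    sim = np.ones((k, k))
    depths = np.arange(1, n + 1)
    for i in range(k):
        for j in range(i + 1, k):
            deepest = np.maximum(pos[i], pos[j])
            cum = np.cumsum(np.bincount(deepest, minlength=n))
            sim[i, j] = sim[j, i] = float(np.mean(cum / depths))
    z = (sim - null.mean) / null.sd
    return AOMatrix(cluster_ids=ids, similarity=sim, zscore=z, null_model=null)
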