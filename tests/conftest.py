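import itertools
import math

import numpy as np
import pandas as pd
import pytest

from aocluster import SimulationConfig, simulate, split_clusters


# ---------------------------------------------------------------- oracles
def ao_oracle(a, b):
    """Brute-force average overlap: set intersections depth by depth."""
    a, b = list(a), list(b)
    assert len(a) == len(b)
    n = len(a)
    return sum(
        len(set(a[:d]) & set(b[:d])) / d for d in range(1, n + 1)
    ) / n


def naive_linkage_oracle(D, ids, method="average"):
    """Independent agglomeration recomputing cluster distances from the
    original matrix at every step (no Lance-Williams updates)."""
    D = np.asarray(D, dtype=float)
    k = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(k)}
    merges = []
    nxt = k
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            pairs = [(x, y) for x in clusters[i] for y in clusters[j]]
            ds = [D[x, y] for x, y in pairs]
            d = {
                "average": np.mean,
                "complete": np.max,
                "single": np.min,
            }[method](ds)
            key_i = tuple(sorted(ids[x] for x in clusters[i]))
            key_j = tuple(sorted(ids[x] for x in clusters[j]))
            cand = (d, tuple(sorted((key_i, key_j))), i, j)
            if best is None or cand < best:
                best = cand
        d, _, i, j = best
        merges.append((i, j, float(d), nxt))
        clusters[nxt] = clusters.pop(i) | clusters.pop(j)
        nxt += 1
    return merges


def pair_counting_oracle(truth, pred):
    """ARI and FMS from exhaustive enumeration of all cell pairs."""
    truth, pred = list(truth), list(pred)
    n = len(truth)
    tp = fp = fn = tn = 0
    for i, j in itertools.combinations(range(n), 2):
        same_t = truth[i] == truth[j]
        same_p = pred[i] == pred[j]
        tp += same_t and same_p
        fp += same_p and not same_t
        fn += same_t and not same_p
        tn += not same_t and not same_p
    total = math.comb(n, 2)
    # ARI via the pair-count form of the adjusted index
    sum_t = tp + fn
    sum_p = tp + fp
    expected = sum_t * sum_p / total
    max_index = (sum_t + sum_p) / 2
    ari = 1.0 if max_index == expected else (tp - expected) / (max_index - expected)
    fms = tp / math.sqrt(sum_p * sum_t) if sum_p and sum_t else 0.0
    return ari, fms


def ami_oracle(truth, pred):
    """AMI from the contingency table: MI, entropies and the exact
    hypergeometric expected MI, arithmetic-mean normalized."""
    truth, pred = list(truth), list(pred)
    n = len(truth)
    tl, pl = sorted(set(truth)), sorted(set(pred))
    a = {t: truth.count(t) for t in tl}
    b = {p: pred.count(p) for p in pl}
    mi = 0.0
    for t in tl:
        for p in pl:
            nij = sum(1 for x, y in zip(truth, pred) if x == t and y == p)
            if nij:
                mi += (nij / n) * math.log(n * nij / (a[t] * b[p]))
    h_t = -sum((a[t] / n) * math.log(a[t] / n) for t in tl)
    h_p = -sum((b[p] / n) * math.log(b[p] / n) for p in pl)
    emi = 0.0
    for t in tl:
        for p in pl:
            lo = max(1, a[t] + b[p] - n)
            hi = min(a[t], b[p])
            for nij in range(lo, hi + 1):
                prob = (
                    math.comb(a[t], nij)
                    * math.comb(n - a[t], b[p] - nij)
                    / math.comb(n, b[p])
                )
                emi += prob * (nij / n) * math.log(n * nij / (a[t] * b[p]))
    denom = (h_t + h_p) / 2 - emi
    if denom == 0:
        return 1.0
    return (mi - emi) / denom


# ---------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def small_sim():
    """Small two-population dataset with disjoint planted markers."""
    cfg = SimulationConfig(
        n_populations=2,
        cells_per_population=60,
        n_genes=300,
        markers_per_population=20,
        log_fold_change=2.0,
        sibling_pairs=(),
        split_populations=(),
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def default_split_data():
    """One draw of the standard scenario with its populations split."""
    sim = simulate(SimulationConfig(seed=5))
    return sim, split_clusters(sim)


def toy_marker_table(cluster_id, genes):
    """Minimal marker table listing ``genes`` in rank order."""
    n = len(genes)
    return pd.DataFrame(
        {
            "cluster_id": cluster_id,
            "gene": list(genes),
            "score": np.linspace(5, -5, n),
            "p_value": np.linspace(1e-6, 0.9, n),
            "p_adj": np.linspace(1e-5, 0.9, n),
            "log_fold_change": np.linspace(3, -3, n),
            "rank": np.arange(1, n + 1),
        }
    )
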