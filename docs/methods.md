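# Methods

## Average overlap

For two ranked lists `a`, `b` of equal length `N` over gene identifiers,
the overlap at depth `d` is `|top_d(a) ∩ top_d(b)| / d` and the average
overlap (AO) is the unweighted mean of the overlaps over **all** depths
`d = 1..N`.  There is no truncation depth and no geometric
rank-bias parameter: the top-weighting arises purely from the fact that
the head of each list participates in every depth while the tail
participates only in the last few.  Two consequences used as exact test
oracles:

* a single adjacent transposition at positions `(i, i+1)` of an
  otherwise identical list changes only the depth-`i` overlap, so
  `AO = 1 − 1/(N·i)`;
* if both lists are permutations of the same universe the overlap at
  depth `N` is 1, so `AO ≥ 1/N`; `AO = 0` requires disjoint contents.

Lists of unequal length are rejected rather than truncated.  In this
workflow both lists are always re-rankings of the same global marker
union, so equal length is guaranteed by construction, and silently
truncating would hide upstream errors.

Overlaps are accumulated as exact integer intersection counts and
divided once per depth; the mean is taken in double precision.
Deterministic expectations in the tests use a tolerance of 1e-12.

## Shuffle null and z-scores

AO over uniformly random permutation pairs of an `N`-universe has
expectation `(N+1)/(2N)`: at depth `d` the intersection size of two
random `d`-subsets is hypergeometric with mean `d²/N`.  The distribution
is close to normal for the list lengths that arise in practice
(N ≳ 50), centering on ≈ 0.5.  `null_distribution(n, m_shuffles, seed)`
estimates the null mean and standard deviation from `m_shuffles`
independent permutation pairs (default 1000, sample sd, ddof = 1);
`exhaustive=True` enumerates all `n!` relative permutations for `n ≤ 7`
(AO is invariant under relabelling of the universe, so enumerating one
list against the identity covers every pair) and returns population
statistics.

Each sample draws an independent permutation *pair*; shuffling one list
against a fixed reference is distributionally identical (again by
relabelling invariance), so the choice is immaterial — the pair form is
implemented.  One null is built per analysis for the global-union list
length and shared by every cluster pair; z-scores are
`(AO − mean)/sd`.  For `N = 1` AO is 0 or 1 and the null sd is
undefined, so z-scores are reported as an explicit error.

Because every pair is standardized by the same affine map, "merge the
pair with the highest z-score" and "merge the pair at the smallest
`1 − AO` distance" select the same pair; the implementation merges by
distance and reports the z for interpretation.

## Marker ranking

Expression is library-size normalized to the median cell total and
log1p-transformed.  Each cluster is tested one-vs-rest per gene with the
Wilcoxon rank-sum normal approximation including the tie correction
(midranks; variance `n1·n2/12·((n+1) − Σ(t³−t)/(n(n−1)))`).  Genes are
ordered by the signed z statistic descending — i.e. one-sided
over-expression in the cluster, the usual marker-gene convention — with
|log2 fold change| descending and then the gene identifier breaking
ties, which makes every ranking total and deterministic across
platforms.  Fold changes are computed on `expm1` of the mean
log-normalized expression with pseudocount 1e-9.  One-sided p-values and
Benjamini–Hochberg adjusted values are reported for display; the ranking
itself is invariant to any monotone p-value adjustment.

Highly-variable-gene selection and count normalization beyond the
median-library scaling are deliberately upstream concerns: callers may
pre-filter genes before constructing the dataset.

The global marker set is the union of every cluster's top-k genes
(default k = 25).  Each cluster then re-ranks the union by its own full
DE ordering, so the relative order of any two union genes matches the
cluster's marker table and all lists share one universe.

## Cluster tree and merging

Pairwise AO converts to the distance `1 − AO`.  Agglomeration uses
Lance–Williams updates with average linkage (UPGMA) by default —
complete and single are available — with ties in distance broken by the
lexicographically smallest pair of sorted member-label tuples, so merge
order is reproducible everywhere.  Average and complete linkage are
monotone, giving non-decreasing merge heights.  Trees serialize to
Newick with branch lengths equal to parent-minus-child merge heights.

`merge_to_k` relabels cells along the tree's first `K − k_target`
merges, i.e. repeatedly joins the currently most similar pair; merged
groups are named by concatenating their member labels.  This fixed-tree
merging is the default.  `merge_with_recompute` re-derives marker
tables, union and AO matrix after every single merge; it is an opt-in
because it multiplies the cost by the number of merges and, on
well-separated data, selects the same partitions (asserted in the
tests).

## Evaluation harness

Agreement between merged labels and ground truth uses adjusted Rand
index, adjusted mutual information (arithmetic normalization) and the
Fowlkes–Mallows score from scikit-learn; the test suite verifies all
three against exhaustive pair-counting / contingency-table oracles.
Average cluster purity is the fraction of a predicted cluster's cells
carrying its majority truth label, cell-weighted by default (equal to
the overall fraction of majority-assigned cells); an unweighted
per-cluster mean is available by flag since the convention is ambiguous
in the field.  Centroid expression distances standardize log-normalized
expression to zero mean and unit variance per gene (zero-variance genes
dropped with a warning), match each merged cluster to its majority truth
population (ties resolved toward the larger population, then
lexicographically), and report the Euclidean distance between matched
centroid vectors.

Baseline cluster distances for benchmarking: Pearson, Spearman and
Kendall correlations (converted as `1 − r`, so anticorrelated clusters
are maximally distant) and Euclidean distance on cluster-level feature
vectors — either mean log-normalized expression of the union marker
genes, or the cluster mean of cell scores on the first 50 principal
components of the standardized matrix — plus the un-ranked direct
overlap `1 − |top_k(a) ∩ top_k(b)|/k`.

For reference-based annotation, a marker set is scored against a genes ×
populations bulk matrix by z-scoring each gene across populations
(constant rows dropped with a warning) and combining the marker genes'
z-values per population with Stouffer's method, `Σz/√n`.

## Synthetic data

The simulator plants known structure in negative-binomial counts so
every stage has a truth-known test bed:

* baseline gene means are log-normal (σ = 1);
* each population multiplies its marker block's means by
  `exp(log_fold_change)`;
* **sibling pairs** share a configurable fraction of their marker blocks,
  and each sibling adds independent Gaussian jitter (sd
  `rank_jitter_sd`) to the shared markers' log effects — the two
  populations then rank largely the same genes in different orders,
  which is exactly the quantity AO measures;
* per-cell expected totals are log-normal with configurable mean and CV;
  counts are gamma-Poisson with dispersion φ (variance `μ + φμ²`);
* `split_clusters` randomly halves chosen populations into
  pseudo-clusters, emulating over-clustering.

Two named parameter sets are used throughout the tests:

| parameter | default scenario | sibling scenario |
|---|---|---|
| populations × cells | 5 × 200 | 5 × 60 |
| genes / markers per population | 2000 / 40 | 2000 / 40 |
| log fold change (natural) | 2.0 | 0.5 |
| NB dispersion φ | 0.5 | 1.5 |
| library mean (CV) | 5000 (0.3) | 2000 (0.3) |
| sibling sharing / jitter sd | 0.8 / 0.3 | 0.95 / 0.6 |
| split populations | pop0, pop2 | pop0–pop3 |

The default scenario represents well-separated populations with two
related pairs; AO-guided merging back to 5 groups recovers the planted
truth essentially always, which the tests assert across 20 seeds.  The
sibling scenario is deliberately homogeneous — modest ≈1.6-fold marker
effects, 95% marker sharing, small noisy clusters — so that sibling
centroids sit near the sampling noise of a split half.  In this regime
correlation- and Euclidean-based merging becomes inconsistent while the
union re-ranking remains informative, and direct set overlap collapses
when only 5 markers per cluster are used; the tests assert this ordering
of medians and interquartile ranges over 20 seeds.  These problem sizes
(≤ 1100 cells, 2000 genes, 20 seeds) were chosen as the smallest at
which the qualitative contrasts are stable.

What the generator does **not** emulate: batch effects, doublets,
ambient RNA, dropout beyond NB sampling, cell-cycle structure, and
over-clustering that splits along real expression substructure rather
than at random.  Passing the benchmark-shape tests therefore shows the
metrics behave as designed under the assumed noise model, not that AO
dominates on any particular real dataset.

## Reproducibility

All randomness flows through `numpy.random.default_rng` seeds carried in
configs and provenance; `derive_seeds` expands one global seed into
per-stage seeds via `SeedSequence`.  Identical config + seed reproduces
counts, labels, rankings and trees bit-identically, and every CLI output
directory includes a `provenance.json` recording command, version and
parameters.

## Known limitations

* The Wilcoxon normal approximation is inaccurate for clusters of only a
  few cells (the container requires ≥ 2 cells per cluster; interpret
  rankings cautiously below ~10).
* The shuffle null is content-agnostic: it conditions only on list
  length, not on the correlation structure of real DE rankings, so z
  magnitudes are calibration scores rather than frequentist p-values.
* Counts are handled densely; datasets far beyond ~10⁵ cells × 10⁴ genes
  will want sparse inputs aggregated upstream.
* `k_target` must be supplied (e.g. the number of expected identities);
  no automatic tree-cutting rule is provided.
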