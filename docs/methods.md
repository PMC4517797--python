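# Methods

## Data model

The unit of analysis is a binary co-occurrence matrix *M* (rows: drug–gene
pairs, columns: canonical dependency-path strings; `CooccurrenceMatrix`).
Rows and columns carry their total corpus occurrence counts as metadata
because the dataset presets filter on corpus counts, not on matrix margins:
the **dense** preset keeps pairs and paths that occurred ≥ 5 times, the
**sparse** preset keeps paths that occurred ≥ 2 times and every pair they
connect. Filtering order is paths first, then pairs, then a single pass
dropping rows/columns the joint filter emptied — no fixpoint iteration, so
a filtered matrix can retain a pair whose surviving paths are rare. The
sparse text format is `#rows N` / `#cols M` headers, label blocks
(`drug<TAB>gene<TAB>count`, `path<TAB>count`), then 0-based `i<TAB>j`
coordinates; round-trips are bit-identical and parse errors carry line
numbers.

### Dependency-path extraction

A sentence parse is consumed as a CoNLL-like TSV (1-based token index,
word, governor index with 0 = root, relation). Eligible sentences have 4–50
tokens inclusive. Entities are found by casefolded string matching against
single-word lexicons (multi-word entries are rejected at load; a
common-English stoplist can be supplied to drop promiscuous terms like
"CAT"). For each drug–gene mention pair the unique tree path is read off,
oriented drug → gene, with endpoint tokens dropped and edge directions
discarded; any path crossing a relation whose label starts with `conj` is
rejected (a parser artifact of list constructions). Canonical form is
pipe-delimited with relations lower-cased and interior words case-folded;
the original surface forms are available on the `DependencyPath` object if
a consumer wants them.

## Information-theoretic co-clustering

`ITCC(matrix, k, l).fit(seed)` minimises KL(p ‖ q) over row and column
cluster assignments, where p is the empirical joint (each nonzero cell
carries mass 1/ΣM) and

q(x, y) = q(x̂, ŷ) · q(x | x̂) · q(y | ŷ),  q(x|x̂) = p(x)/p(x̂),  q(y|ŷ) = p(y)/p(ŷ).

Because q preserves all row/column marginals and block masses, the
objective equals the mutual-information gap I(X;Y) − I(X̂;Ŷ); the fitting
loop evaluates it that way, while the term-by-term sum is kept as
`kl_objective` and the two are cross-asserted in the tests. All divergences
are in nats.

Numerical and algorithmic choices (the original implementation's internals
are not published; these are this package's own, exposed in the API):

* **Initialisation: random cluster centres.** Each run draws k distinct
  rows (l distinct columns) as centres and assigns every item to its most
  cosine-similar centre, with random tie-breaks so items orthogonal to all
  centres scatter instead of piling into the first cluster. Centres belong
  to their own clusters, so no cluster starts empty and k = n yields the
  singleton clustering (objective exactly 0). A random-partition
  initialisation was tried and rejected: it cannot reach the singleton
  limit (empty clusters are never re-entered) and it converges to far
  worse local optima on block-structured data.
* **Updates.** Batch row step (every row moves to the cluster ŷ minimising
  KL(p(X|y) ‖ q(X|ŷ)), computed from column-cluster aggregates), recompute
  q, batch column step, recompute q. Each half-step is non-increasing in
  the objective; the trace is recorded and asserted monotone in tests.
* **Convergence.** Stop when the relative objective decrease over a full
  sweep is < 1e-6, or after 50 sweeps; both exposed as parameters.
* **Degeneracies.** A candidate cluster with zero q-support where the item
  has mass gets +∞ divergence; if every candidate is infinite the current
  assignment is kept. Empty clusters persist (no reseeding). Argmin ties
  go to the lowest cluster index, making a run bit-reproducible given its
  seed.
* **Choosing k and l.** The published matrices used (k, l) = (30, 125)
  dense and (7, 25) sparse, exposed as `PRESET_KL`. For new data,
  `choose_kl` minimises best-of-restarts KL + λ·(k+l)/min(n, m) over a
  grid (λ = 0.1 by default) — a simple penalised substitute for the
  original, unpublished heuristic, and flagged as such.

`smoothed_matrix` returns q rescaled to the original total: the
block-approximation "fills in" plausible unobserved cells while preserving
every row and column sum.

## Ensemble and scoring

`EBC(matrix, k, l, n_runs).fit(seed)` runs ITCC with seeds
`seed + i`, i = 0..N−1, and accumulates the symmetric co-clustering count
matrix C (C_ii = N; column-axis counts are available from the same runs).
The result is order-independent and bit-reproducible. The reference
analyses used N = 2000 and observed performance stabilising around
N ≈ 1000; the scaled simulations here use N = 200.

Scoring a candidate T_i against a seed set S:

* `ebc` — rank all n rows by C(·, T_i) ascending so the most frequent
  co-clusterer takes rank n (T_i itself holds rank n through its diagonal
  count but contributes nothing since T_i ∉ S); score = Σ ranks of S. The
  score is invariant under any strictly monotone transform of the counts.
  Ties are broken by a random permutation drawn per candidate from
  (tie_seed, candidate index) — each ranking R_i gets its own independent
  tie-break, which matters: a single shared permutation correlates tie
  placements across candidates and manufactures spurious orderings.
* `avgcos` — mean cosine of T_i's binary row vector with the seed vectors.
* `ranksum` — the same rank-sum formula over cosine-similarity ranks.
* `lsa_avgcos` / `lsa_ranksum` — the cosine methods on rank-r SVD row
  embeddings U_r·diag(s_r); at r = min(n, m) they reproduce the raw
  cosines exactly.
* `random` — a seeded pure-noise scorer, used as the null baseline.

Relative certainty is min–max normalisation of the scores over the
candidate list (seeds are excluded before normalising; constant scores map
to 1.0 by convention), so the top candidate always prints 1.000. The exact
normalisation behind the published certainty columns is not stated; min–max
is this package's choice.

## Evaluation protocol

For each seed-set size (defaults 1, 2, 3, 4, 5, 10, 25, 50, 100) and
replicate, a seed set is drawn from the positives and a disjoint test set
of 50 positives + 50 negatives (configurable) is drawn without replacement;
every method scores the identical draw (the per-replicate generator derives
from (master seed, size, replicate), so comparisons are paired), ranking
quality is the ROC AUC (ties credited 0.5, via scikit-learn), and the
summary metric is the fraction of replicates with AUC strictly above 0.7.
`seed_overlap_stats` reproduces the bookkeeping arithmetic over two labeled
classes: with 3514 pairs, 290 + 410 labeled and 84 shared, 2898 pairs are
known to neither class and the class overlap is 84/616 = 13.6%.

## Landscape

Row distance is d_ij = 1 − ρ_ij with ρ the Spearman correlation of full
rows C_i· and C_j· (diagonal entries included, faithful to the definition
"correlation of C_i· and C_j·"; ties get average ranks; a constant row is
an error naming the row). Minimax linkage merges, at every step, the pair
of clusters whose union has the smallest prototype radius
r(G) = min_{p∈G} max_{q∈G} d(p, q), recording the minimising leaf as the
merge's prototype; ties go to the lowest node-id pair. Heights are
asserted non-decreasing per merge, and the implementation is checked
against an exhaustive re-evaluation oracle on small instances. Trees cut
at a height by applying every merge of height ≤ h (scipy's `fcluster`
distance criterion); enrichment tables report per-cluster size and label
percentages to one decimal; cluster-vs-cluster value comparisons use the
two-sided Mann–Whitney test (exact enumeration when both samples ≤ 8).
Newick export uses ultrametric branch lengths (height differences) with
whitespace sanitised out of leaf labels.

## Synthetic data

`planted_matrix` samples a row-block × column-block Bernoulli structure
(p_in inside an associated block, p_out outside), resamples empty margins
once, then drops whatever is still empty along with its ground-truth
entries.

`synonymy_scenario` constructs the case the ensemble exists for: one
positive relationship class whose surface forms split into two *disjoint*
path families. Defaults, frozen after pilot simulations and used by the
tests and the acceptance script:

* 40 + 40 positive rows; split A is Bernoulli(0.9) on its own 6-column
  block, split B on a second 6-column block. No positive row touches the
  other split's block, so cross-split cosines are exactly zero (verified
  at generation).
* 12 unlabeled **bridge** rows, Bernoulli(0.9) across both positive
  blocks — pairs whose sentences happen to use both phrasings. These are
  the corpus signal that makes the two column families distributionally
  similar; without them nothing links the splits and no method can.
* 4 unrelated communities of 20 rows × 18 columns each; the first two are
  the labeled negatives (40 rows), the rest unlabeled background. The
  community blocks outweigh the positive blocks, so at k = l = 3 the
  cheapest mutual-information merge is the two positive column families,
  and the background communities populate the ranks between negatives and
  seeds — with a single coherent negative block, near-tie rank bands made
  the rank-sum scores knife-edge against realisation noise.

The scaled synonymy benchmark (`evaluation.synonymy_benchmark`) runs 25
full simulation replicates — fresh matrix, fresh ensemble (k = l = 3,
N = 200), one draw of 10 seeds from split A and a 30 + 30 test set of
split-B positives versus labeled negatives — and reports per-method AUCs.
Expected behaviour, asserted by the acceptance tests: EBC median AUC
≥ 0.9 and its AUC > 0.7 fraction strictly above both cosine baselines,
while average cosine sits at exactly 0.5 (all its scores are tied at
zero). What this does and does not show: the generator plants clean block
communities and a noiseless tie structure; real literature matrices are
heterogeneous in degree, polysemous, and much sparser, so passing here
demonstrates the mechanism (path-family linkage through shared usage), not
literature-scale performance figures.

## Known limitations

* The original k, l selection heuristic and implementation internals are
  unpublished; the substitutes above are documented but not faithful.
* The published headline extraction percentages require the real
  Medline-derived matrices, curated label sets, and 2000-run ensembles at
  k = 30, l = 125; they are out of desk-reproduction scope here. The two
  dataset-statistics tests run only if the supplementary matrices are
  converted and placed under `tests/data/`.
* Spearman distances include the two self columns of C (faithful to the
  stated definition); with small n this slightly compresses distances.
* Lexicon construction and gene-name normalisation are out of scope: the
  extractor deliberately keeps synonymous gene symbols distinct.
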