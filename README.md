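# ebc — ensemble biclustering for drug–gene relationship extraction

Biomedical knowledge bases curate drug–gene relationships (which gene
product a drug targets, which gene's variants change a drug's effect) from
millions of Medline sentences, and the same relationship is phrased in
endlessly different ways: "*D*, an inhibitor of *G*", "*D* suppressed *G*
activity", "*G* is inhibited by *D*". This package implements **Ensemble
Biclustering for Classification (EBC)**, a corpus-level, distant-supervision
method that learns which phrasings mean the same thing from usage patterns
alone — no annotated sentences — and uses that to rank candidate drug–gene
pairs against a handful of known examples.

## The method

The corpus is reduced to a binary matrix *M* whose rows are drug–gene pairs
and whose columns are **dependency paths** — the sequence of grammatical
relations and interior words along the unique tree path between the drug
and the gene in a sentence's dependency parse (e.g. `appos|inhibitor|amod`
for "*D*, a *G* inhibitor"). *M<sub>ij</sub>* = 1 iff pair *i* was connected
by path *j* somewhere in the corpus.

1. **Information-theoretic co-clustering (ITCC).** Treat *M* as an
   empirical joint distribution p(x, y) over columns X and rows Y. For k
   row clusters and l column clusters, alternately reassign rows and
   columns to minimise KL(p ‖ q), where
   q(x, y) = q(x̂, ŷ) · q(x|x̂) · q(y|ŷ) is the block factorisation. The
   objective equals I(X;Y) − I(X̂;Ŷ) and never increases across a step.
2. **Ensemble.** Run ITCC N times from random cluster centres (seeds
   `base_seed + i`) and record, for every pair of rows, the number of runs
   C<sub>ij</sub> in which they shared a row cluster. C/N is a similarity
   measure that can link two pairs **even when they share no dependency
   path at all**, because their paths co-occur elsewhere in the corpus.
3. **Seeded scoring.** Given a seed set S of known relationships, each
   candidate T<sub>i</sub> ranks all n rows by C(·, T<sub>i</sub>) (ties
   broken randomly) and is scored by the rank-sum
   score(T<sub>i</sub>) = Σ<sub>j</sub> j · 1{R<sub>ij</sub> ∈ S} — rank
   normalisation removes each pair's baseline promiscuity. Cosine
   (`avgcos`), rank-sum-cosine (`ranksum`) and SVD/LSA baselines are
   included for comparison, and rankings are evaluated by the fraction of
   replicate test sets ranked with AUC > 0.7.
4. **Landscape.** Spearman correlation between rows of C gives a distance
   1 − ρ; minimax-linkage hierarchical clustering turns it into a
   dendrogram of relationship "themes" with a prototype pair at every
   internal node, exportable to Newick.

## Worked example

The synthetic synonymy scenario plants the hard case: 80 positive pairs in
two splits whose column support is *disjoint* (split A pairs are only ever
described with path family A, split B only with family B), a few unlabeled
"bridge" pairs described with both families, and unrelated background
communities. Seeds come from split A; split B must be ranked above the
negatives.

```python
import numpy as np
from ebc import EBC, synonymy_scenario
from ebc.evaluation import auc

data = synonymy_scenario(seed=7)
model = EBC(data.matrix, k=3, l=3, n_runs=200)
fitted = model.fit(seed=0)
print(fitted.summary())

seeds = data.split_a[:10]
candidates = data.split_b + data.negatives
table = fitted.score(seeds, method="ebc", tie_seed=1)
table = table[table["label"].isin(candidates)].reset_index(drop=True)
print(table.head(6).to_string(index=False))

positive = set(map(tuple, data.split_b))
labels = [int(tuple(l) in positive) for l in table["label"]]
print("EBC AUC:", auc(table["score"], labels))
```

Output:

```
Ensemble biclustering results
==================================
matrix           172 x 84
k, l             3, 3
runs (N)         200
base seed        0
mean off-diagonal co-clustering frequency  0.425
               label  score  relative_certainty method
(drug0050, gene0050)   1075            0.645206    ebc
(drug0075, gene0075)   1039            0.620014    ebc
(drug0043, gene0043)   1036            0.617915    ebc
(drug0048, gene0048)   1036            0.617915    ebc
(drug0063, gene0063)   1034            0.616515    ebc
(drug0072, gene0072)   1029            0.613016    ebc
EBC AUC: 1.0
```

Rows 40–79 are split B: every top candidate is a split-B pair even though
no split-B pair shares a single column with any seed — the ensemble linked
the two path families through the bridges. Average cosine similarity on the
same task is exactly 0.5 (chance): every cross-split cosine is 0 by
construction.

The same pipeline is exposed as a CLI (`ebc paths extract`, `ebc matrix
build`, `ebc itcc run`, `ebc ensemble`, `ebc score`, `ebc evaluate`,
`ebc landscape`, `ebc simulate …`); see `ebc --help`.

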