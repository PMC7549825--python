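# setbridge

Cross-platform comparability of transcriptomics data through per-sample
gene-set enrichment scores.

Microarrays and RNA-Seq measure the same biology through very different
physics, and their gene-level readouts agree only loosely: per-sample Spearman
correlations between paired measurements typically land in the 0.6–0.85 range,
with substantial dispersion around the best-fit line. `setbridge` implements a
transform that replaces each sample's thousands of gene values with a few
dozen-to-thousand *gene-set enrichment scores* — one scalar per a-priori gene
set (e.g. an MSigDB collection) — and the machinery to show that, and why,
this makes the two platforms far more concordant: concordance statistics, a
gene-set permutation null, a median-rank surrogate score, Procrustes alignment
of score spaces, and cross-platform subtype classification. It is aimed at
computational biologists who want to merge archival microarray studies with
modern sequencing data, or reuse classifiers across platforms.

## The score

For one sample, the expression values of all `R` measured genes are sorted
descending, giving each gene a rank `r = 1…R` (rank 1 = highest value; ties
keep input order). For a gene set `H` with `R_H` measured members, two
cumulative curves are walked down the ranking:

    P_H(r)  = Σ_{i≤r, G_i∈H} i^(−α)  /  Σ_{i≤R, G_i∈H} i^(−α)
    P_NH(r) = #{ i ≤ r : G_i ∉ H } / (R − R_H)

    ES(H)   = Σ_{r=1}^{R} ( P_H(r) − P_NH(r) )

Both curves rise from 0 to 1. Members concentrated at high ranks pull `P_H`
ahead of `P_NH` (ES > 0), members at low ranks lag it (ES < 0), and randomly
scattered members track it closely (ES ≈ 0). The stabilizing power `α`
(default 0.25) down-weights low ranks. Because only ranks enter, the score is
exactly invariant to any monotone transform (e.g. log2) of the input, and each
sample is scored independently — no cohort is needed.

The transform concentrates biologically coherent signal and averages out
platform-specific gene-level noise; a permutation null (same set sizes, random
members) shows how much of the gain is specific to the real set definitions
rather than to averaging alone.

## Worked example

The built-in generator simulates two platforms measuring the same 50 samples
(2,000 genes, 30 gene sets with coherent module structure, microarray-like
saturation + noise on one side, zero-inflated counts on the other):

```python
import numpy as np
from setbridge import *

ds = make_dual_platform(SimConfig(seed=0))
es_array = transform(ds.array_view, ds.collection)   # 30 sets x 50 samples
es_seq   = transform(ds.seq_view,  ds.collection)

gene = pairwise_report(ds.array_view.values, ds.seq_view.values)
sets = pairwise_report(es_array.scores, es_seq.scores)
print(f"gene level : mean rho = {gene.mean_rho:.3f}, mean var(E) = {gene.mean_var_e:.3f}")
print(f"set level  : mean rho = {sets.mean_rho:.3f}, mean var(E) = {sets.mean_var_e:.3f}")

rng = np.random.default_rng(1)
null = []
for _ in range(100):
    pc = permute_collection(ds.collection, rng)
    null.extend(pairwise_report(transform(ds.array_view, pc).scores,
                                transform(ds.seq_view, pc).scores).rhos)
print(f"permuted-set null: mean rho = {np.mean(null):.3f}")
```

prints

```
gene level : mean rho = 0.839, mean var(E) = 0.359
set level  : mean rho = 0.958, mean var(E) = 0.014
permuted-set null: mean rho = 0.763
```

Read: at gene level the two platforms correlate at 0.84 per sample with 36% of
paired variance off the diagonal; after the set transform correlation rises to
0.96 with 1.4% residual variance. Randomized sets of the same sizes reach only
0.76 — the real set definitions, not mere averaging, carry the improvement.

A single-sample demonstration of the walk itself:

```python
values, collection, walks = make_three_set_demo(seed=0)   # 250 genes, 3 sets
for name, walk in walks.items():
    print(f"ES({name}) = {walk.es:+.1f}")
```

```
ES(TOP) = +123.8
ES(BOTTOM) = -121.9
ES(RANDOM) = +11.6
```

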