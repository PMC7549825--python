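# Methods

This note records the modelling and design decisions behind `setbridge`: what
each statistic is, the choices that were genuinely open, and what the
synthetic experiments do and do not establish.

## Enrichment score

For a sample with `R` measured genes, ranked descending (`r = 1` is the
highest value), and a gene set `H` with `1 ≤ R_H < R` measured members:

    P_H(r)  = Σ_{i≤r, G_i∈H} i^(−α)  /  Σ_{i≤R, G_i∈H} i^(−α)
    P_NH(r) = #{ i ≤ r : G_i ∉ H } / (R − R_H)
    ES(H)   = Σ_{r=1}^{R} ( P_H(r) − P_NH(r) )

**Weight convention.** Two conventions circulate for single-sample scores of
this family: weighting each member by `i^α` (the classical ssGSEA form) or by
`i^(−α)` (the form in which the rank appears under the indicator, as printed
in the equations above). The two agree at `α = 0` and for singleton sets, and
differ mildly otherwise. `setbridge` implements the `i^(−α)` form, applying
the weight identically in the numerator terms and their normalizing sum, and
the test suite pins this reading against an independent loop-based oracle.
Users wanting the classical ssGSEA behaviour should use a dedicated ssGSEA
implementation; results are not interchangeable score-for-score, though the
qualitative behaviour (sign, ordering of extreme sets) matches.

**Ties.** Ranking uses a stable descending sort: tied values keep their input
(gene-order) positions. Fractional "average" ranks are not used because the
cumulative indicator sums require a strict permutation of 1…R. The policy is
deterministic and platform-independent, which matters for zero-inflated count
data where a large fraction of the genome ties at zero; the
`zero_inflation_experiment` quantifies exactly what this tie block does to
scores (see below).

**Set intersection.** Members absent from the measured genes are silently
intersected out and `R_H` reduced; sets that end empty, or that cover every
measured gene (leaving `P_NH` undefined), are dropped with a warning and
listed in the output's provenance. `α ≥ 0` is configurable (default 0.25;
`α = 0` is the unweighted limit in which ES is linear in member positions —
several exactness tests exploit this).

**Implementation.** The matrix transform evaluates a closed form: with
`w_i = i^(−α)` and `c_i = R − i + 1`,
`ES = Σ_m w_m c_m / Σ_m w_m − (C − Σ_m c_m)/(R − R_H)`, `C = R(R+1)/2`,
computed for all sets at once through a sparse membership matrix. This agrees
with the explicit walk to ≤ 1e−10 (tested on ~1,000 random configurations).

**A small positive bias.** For uniformly random member positions the expected
ES is exactly 0 at `α = 0` but slightly positive at `α > 0` (the normalizing
sum in `P_H` is itself random, and the ratio is convex in it). This bias is
small relative to the score of a coherently ranked set and is the same
mechanism that produces the zero-tie shift measured below.

## Median-rank score

The median of the member genes' ranks (mean of the two middle ranks for
even-size sets) is provided as a simpler, robust surrogate: low values mean
the set sits near the top of the ranking. In the synthetic experiments its
cross-platform concordance lands between raw gene values and the full
enrichment score, reproducing its published role as a sanity check that the
set definitions, not the weighting details, carry most of the signal.

## Concordance statistics

*Per-sample pair:* Spearman's ρ (average ranks for ties — here ranks feed a
correlation, not an indicator walk, so the fractional convention is correct)
and the residual variance **var(E)**: both columns of the paired sample are
mean-centered and (by default) autoscaled, and var(E) is `λ₂/(λ₁+λ₂)` of the
2×2 covariance — the variance fraction off the principal axis, 0 for
collinear platforms, 0.5 for uncorrelated ones. With autoscaling this equals
`(1 − |ρ_Pearson|)/2` exactly, which the tests use as a closed-form oracle.
Autoscaling is the default because the two platforms' scales differ by orders
of magnitude; without it var(E) measures scale imbalance, not concordance
(a flag restores centered-only behaviour).

*Whole-dataset:* the modified RV coefficient. Columns of each
samples × variables matrix are standardized, the sample configuration
matrices `XXᵀ` and `YYᵀ` get their diagonals zeroed (removing the
self-similarity term that inflates the classical RV in high dimensions), and
the coefficient is their matrix inner product over the product of their
Frobenius norms. Zero-variance columns are an error; for raw count matrices
the caller should drop uninformative (e.g. all-zero) genes first, as
`scripts/acceptance.py` does.

## Gene-set permutation null

A permuted collection keeps every set's name and size and draws members
uniformly without replacement from the pool of genes occurring anywhere in
the collection, independently across sets (a gene may land in several
permuted sets, mirroring reuse in real collections; within one set it appears
at most once). This destroys membership coherence while preserving the
structure, so the difference between real-collection and permuted-collection
cross-platform concordance isolates the contribution of the biology encoded
in the sets from the pure averaging effect of scoring groups of genes.

## Procrustes alignment

`fit_procrustes` estimates the classical three-step transform — translation,
one global scale, orthogonal rotation — from paired rows (overlapping
samples), via the SVD of the centered cross-product; the scale is the
least-squares scalar. The stored transform maps raw source coordinates into
the target frame and applies to any matrix over the same variables.
Decisions:

- **Reflections** are permitted (full orthogonal group) by default, since
  nothing in the three-step formulation excludes them; `allow_reflection=False`
  restricts to proper rotations via the usual sign correction.
- **Rank deficiency.** When fewer paired rows than variables are available
  (five class means in dozens of score variables), the rotation is only
  identified on the subspace spanned by the data; the SVD bases complete it
  deterministically but arbitrarily on the complement. Tests therefore assert
  recovery only on the spanned subspace, and the group-means tests use more
  classes than variables when they need full identification.
- **Orientation.** The convention is source = the platform to be corrected
  (sequencing side), target = the platform the model was trained on.
- `fit_procrustes_groupmeans` handles the no-overlap case: per-class mean
  vectors, paired in sorted class order, act as the rows. It reduces exactly
  to the overlap fit when every class is a singleton.

## Subtype classification

Multinomial logistic regression with a mild ridge penalty (scikit-learn,
`C = 1` by default, deterministic given the seed) — the minimal model family
matching "cross-validated logistic models". Each of `n_repeats` (default 10)
repeats draws a stratified random split (default half/half), fits on the
training part and scores the held-out part; held-out confusion counts are
pooled across repeats and accuracy is the pooled trace over the grand total.
`predict` pools every model's prediction of every sample (model-major), so a
pooled confusion table over `k` models of `n` samples totals `k·n`.
Accuracies compared against published tables are rounded to two decimals.
The published cross-platform table is itself reproduced only as printed
counts → trace/total; where a printed table and its quoted accuracy disagree,
the package reports trace/total.

## Synthetic dual-platform generator

The generator produces the minimal structure the method's claims require: two
platforms observing one latent signal in which gene sets are coherent
modules. Per `SimConfig` (defaults in parentheses — these are the package's
study conditions, used by the tests and the acceptance script):

- **Baseline** (2,000 genes): bimodal log2-scale means — ~30% silent genes
  around 2, the rest expressed around 8 (sd 2) — the characteristic shape of
  real transcriptomes.
- **Sets as coherent modules** (30 sets, 20–60 genes): each set has its own
  affinity for the silent stratum (uniform 0–0.8), so some sets are
  coherently off (strongly negative ES) and others coherently expressed.
  This composition coherence — precisely what a permutation destroys — is
  essential: with uniformly drawn sets the permuted null is nearly as
  concordant as the real collection, and the set-level gain over gene level
  all but vanishes.
- **Classes** (5, balanced over 50 samples): each set is active in exactly
  one class with a random sign, shifting its members by `set_effect`
  (1.0 log2 units, i.e. two-fold — a moderate, realistic effect). Shared
  biological noise (sd 0.5) is added to the latent signal.
- **Microarray view**: saturating monotone response (`14·tanh(x/14)`) plus
  Gaussian noise.
- **Sequencing view**: Poisson counts with log-normal overdispersion
  (`seq_noise_sd`), mean 2^latent scaled to a median of ~20 counts and
  multiplied by a per-sample depth factor; the lowest counts are then
  thresholded to zero to reach `seq_zero_fraction` (0.3).
- **Noise calibration**: `array_noise_sd = seq_noise_sd = 1.0` was chosen so
  that per-sample gene-level cross-platform Spearman lands in the 0.6–0.85
  band reported by published microarray/RNA-Seq comparisons; under these
  conditions the generator's gene-level mean ρ is ≈ 0.84.
- **Platform distortion** (`platform_offset`, default 0): per-gene log2
  gains on the count platform only, with an independent component
  (probe/length/GC-type biases) and a set-coherent component (biases
  correlated with gene families). The coherent part displaces whole set
  scores, i.e. shifts the sequencing score space relative to the microarray
  one — the situation Procrustes alignment repairs. The transfer experiment
  injects `platform_offset = 2.0` with `seq_zero_fraction = 0.5`, strong
  enough that the displacement is comparable to the within-set score spread,
  as observed in real cross-platform score scatter.

What the generator does **not** emulate: realistic transcriptome marginals or
gene–gene correlation beyond set membership, probe-level microarray physics,
read-level sequencing, gene-length/TPM effects as such, batch structure
beyond the platform dichotomy, or overlapping biological pathways. Passing
the synthetic experiments therefore shows that the implementation produces
the claimed phenomena under the stated mechanism, not that it reproduces any
particular real dataset's numbers.

## Zero-tie shift experiment

`zero_inflation_experiment` isolates what tying many low values does to the
score. A single matrix of continuous, tie-free intensities on the count
platform's log scale (latent + sequencing noise — the deep-coverage limit
before discretization) is generated once; each requested zero fraction floors
its lowest quantile to a common value, collapsing the informative bottom-end
ordering into one tie block ordered arbitrarily (by gene index, under the
stable tie policy), exactly as zero read counts do. The per-set mean score is
compared with the tie-free baseline (the zero-fraction-0 row is identically
zero by construction). Members of coherently silent sets sit at the extreme
bottom of the true ranking; the tie block relocates them toward its middle,
compressing strongly negative scores toward zero — a positive mean shift
whose size depends on each set's composition (non-uniform, positive spread
across sets). Counts are deliberately not used as the baseline: integer
counts already contain large natural tie blocks, which would contaminate the
contrast.

## Gene matching

Cross-platform gene matching takes a user-supplied many-to-many ID mapping
table. Genes with no mapping are dropped from both sides. Within each
connected component of the bipartite mapping graph that is not a plain 1:1
edge, pairs whose secondary symbols agree exactly (whitespace-trimmed,
case-sensitive — no case folding, since symbol case is meaningful) are kept
when the agreeing edges form an unambiguous matching; a component with no
agreeing pair, or with any gene claiming two agreeing partners, is removed
entirely from both datasets. Values are never merged or averaged across
duplicates — removal is always preferred to aggregation.

## Numerical and degenerate-input choices

- Ranks are exact integers; monotone-transform invariance of the transform is
  bitwise, and tests assert exact equality.
- `enrichment_score` requires `1 ≤ R_H < R`; both failure modes raise with a
  reason (empty intersection / undefined non-member curve).
- `var_e` and `spearman` reject zero-variance inputs rather than returning
  NaN; `modified_rv` likewise rejects zero-variance columns.
- Procrustes scale is clamped positive in the fully anti-correlated
  degenerate case (the rotation absorbs signs).
- All generators take integer seeds or `numpy` Generators; every simulation
  in tests and the acceptance script is seeded.

## Problem sizes

The package's own experiments run at 2,000 genes × 50 samples × 30 sets with
100 collection permutations (concordance and null), 60 samples for the
transfer experiment (5 repeats × 5 classes), and 1,000 genes × 20 samples ×
20 sets for the zero-tie experiment — sizes at which every documented
phenomenon is stable across seeds while the full suite runs in seconds.

## Known limitations

- The `i^(−α)` weight convention is not score-compatible with classical
  ssGSEA implementations (see above).
- The stable tie policy makes tied blocks deterministic but input-order
  dependent; reordering the input genes permutes tied ranks (untied data are
  unaffected).
- Group-means alignment identifies the rotation only up to the class-mean
  subspace; applying it far outside that subspace relies on an arbitrary
  (though deterministic) completion.
- The synthetic generator's class structure is balanced and clean; class
  imbalance, label noise and overlapping modules are untested territory.
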