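# Methods

This note records the model, the estimation choices, and the design
decisions behind `kptmpred`, in the package's own terms.

## Problem setting

Each lysine (K) site in a protein is a multi-label instance: its label
set is a subset of {acetylation, crotonylation, methylation,
succinylation, glutarylation}, with the empty set meaning the site
carries no known modification. The predictor decomposes the problem
into five binary one-vs-rest tasks over a shared sequence
representation and recombines the binary decisions into a label set.
This assumes label assignments are conditionally independent given the
window — co-occurrence enters only through the shared representation,
not through a joint output model.

## Peptide windows

A site is represented by the 2ζ+1 residues centred on the K, default
ζ = 24 (49-mers). When a window overruns a terminus, the missing flank
repeats the terminal residue of the protein on that side; this keeps
every window the same length without introducing a new padding symbol
that the pair and coupling encoders would have to treat specially
(the one-hot alphabet's wildcard 'Z' is reserved for genuinely
nonstandard residues: B, J, O, U, X are mapped to it on load).
Exact-duplicate windows are collapsed into one sample whose label set
is the union of the duplicates' labels: an observed modification
anywhere outweighs its absence elsewhere. Dedup is by exact string
identity; similarity-based redundancy reduction (e.g. CD-HIT-style
clustering) is deliberately out of scope.

## Feature encoders

All encoders operate over the fixed 21-letter alphabet
`ACDEFGHIKLMNPQRSTVWYZ`.

- **Amino-acid factors (AAF), 5·(2ζ+1) = 245.** Five multivariate
  physicochemical scores per residue (polarity, secondary-structure
  propensity, molecular volume, codon diversity, charge), taken from
  the Atchley et al. (2005) factor solution of the AAIndex property
  space (`aaf.py`, version `atchley-2005-v1`). 'Z' maps to the zero
  vector, the centroid of the standardized factor space.
- **Binary encoding (BE), 21·(2ζ+1) = 1029.** One-hot per residue in
  alphabet order.
- **CKSAAP, 441 per spacing, k = 0..4 → 2205.** For each spacing k the
  count of each ordered pair (a, b) with b exactly k residues
  downstream of a, divided by the number of such pairs in the window,
  N_total(k) = (2ζ+1) − k − 1; each 441-block therefore sums to 1.
- **Sequence coupling, 2ζ = 48.** Two probability models are fitted,
  one on modified and one on unmodified training windows. For offsets
  j = −ζ..−2 the model stores p(residue at j | residue at j+1), i.e.
  each flank residue is conditioned on its neighbour one step toward
  the centre; mirrored for j = +2..+ζ. Offsets ±1 adjoin the invariant
  central K and carry unconditional position-specific probabilities.
  The tables are position-specific (one table per offset), not pooled
  across positions. A feature is the positive-model probability of the
  observed residue minus the negative-model probability, so each
  component lies in [−1, 1] and the encoding is exactly antisymmetric
  under swapping the two training classes.

  *Smoothing:* a pseudocount ε = 10⁻⁴ is added to every cell before
  normalization, so an unseen (residue, context) pair gets probability
  ε/(21ε + n_context) instead of 0. The value is small enough to leave
  well-supported estimates essentially untouched (relative perturbation
  < 10⁻³ for contexts seen ≥ 2 times) while keeping every conditional
  defined.

The four blocks are concatenated serially (AAF ∥ BE ∥ CKSAAP ∥
coupling; 3527 columns at the defaults) and z-score standardized.
Zero-variance columns keep scale 1 (they standardize to exactly 0) and
are reported in a warning. The coupling tables and the standardization
parameters are fitted on training data only and applied unchanged to
validation or test windows — inside cross-validation they are refitted
per training fold, so no held-out information reaches the
representation.

## Imbalance handling

Stage one, dataset level: the modified:unmodified ratio of a curated
corpus is ≈1:16. Each sample's *instance hardness* is 1 − p(true
label | x), with the probability estimated out-of-fold (stratified
5-fold, fixed seed) by a cost-sensitive RBF-SVM wrapped in sigmoid
probability calibration, on the coupling features of the global
modified-vs-unmodified task. The highest-hardness unmodified samples —
noisy or boundary instances — are removed until the majority equals
`ratio` × minority (default 1:1). Ties in hardness break by original
sample index, so resampling is reproducible; minority samples are never
touched. The single calibrated SVM stands in for a weighted ensemble of
hardness estimators with uniform weights.

Stage two, classifier level: the residual skew inside each per-PTM
binary task (some modifications are ~20× rarer than others even after
balancing) is absorbed by different-error-cost weights. With M
training samples, M₁ positive and M₂ negative, the per-class SVM costs
are C·W⁺ and C·W⁻ with W⁺ = M/(2M₁), W⁻ = M/(2M₂); balanced counts give
unit weights, and W⁺M₁ + W⁻M₂ = M identically.

## Feature selection

Columns are scored per PTM task by the two-group one-way ANOVA F
statistic, computed directly from the between/within sums of squares.
Edge cases: zero within-group variance with equal group means gives
F = 0 (no signal); with unequal means the column separates the classes
perfectly and is ranked first (the exported score replaces +inf by
twice the largest finite F so reports stay finite). Ties in F break by
ascending column index. F is covariant under affine rescaling of a
column, so ranking before or after standardization is equivalent.

Incremental feature selection evaluates nested top-m subsets on the
grid m = 50, 100, … clamped to end exactly at the full dimension,
scoring each by cross-validated multi-label accuracy; the best m is the
accuracy maximiser, ties going to the smaller (more parsimonious) m.
Two ranking protocols are provided: `leakage-safe` (default for
`cross_validate`) re-ranks inside every training fold;
`global` ranks once on the full dataset before CV, matching
the global-ranking protocol common in this literature, and is the
default for the IFS replication sweep (`kptmpred select`). The
difference is a known source of optimism in the global protocol; both
are exposed so the comparison is a one-flag experiment.

## Classifier and validation

Each binary head is a scikit-learn `SVC` (RBF kernel) at the libSVM
defaults C = 1, γ = 1/n_features, with the DEC class weights above.
The optimizer is delegated; this package owns the cost wiring,
thresholds, fold logic and seeds. A label is assigned when its decision
score exceeds 0; sigmoid-calibrated probability thresholding at 0.5 is
available as an option. A task whose training split has fewer than two
samples of either class is disabled and predicts "not modified"
(logged); this never occurs at realistic corpus sizes but keeps
desk-scale experiments total.

Validation is repeated stratified k-fold CV, default 5 repeats × 5
folds with seeds 0..4 recorded in the report. Folds come from an
iterative multi-label stratification (greedy, rarest-label-first
assignment to the fold with the largest remaining demand, with an
explicit all-negative pseudo-label so unmodified samples stratify too).
Fold draws that would leave a PTM task untrainable (for tasks with ≥4
positives overall) are re-drawn with a shifted seed, logged. Reported
values are mean ± standard deviation over the repeats of metrics
computed on the pooled held-out predictions of each repeat.

## Multi-label metrics

Aiming, coverage, accuracy, absolute-true and absolute-false are
per-sample set-ratio means. The empty label set would leave
aiming/coverage 0/0; the default `null` convention represents it by an
explicit "non-k-ptm" label, so sets are never empty and the label
universe has L = 6 members (used in the absolute-false denominator).
The `strict` alternative keeps L = 5 and defines 0/0 := 1. Both are
exact set arithmetic; under the null convention
absolute-true ≤ accuracy ≤ min(aiming, coverage) holds sample-wise.

## Synthetic data generator

The generator emulates the statistics a curated human K-PTM corpus
presents to this pipeline: proteins drawn i.i.d. from Swiss-Prot-like
background residue frequencies (lysine ≈ 5.8%, so a 420-residue protein
carries ~24 candidate sites); a fraction 1/17 of K sites modified
(≈1:16 imbalance); label multiplicity drawn from a heavy-tailed
histogram (≈81% of modified sites carry one label, ≈17% two, the rest
3–5) and the labels themselves uniformly without replacement — the
uniform choice is deliberate so every per-PTM task keeps enough
positives to be testable at desk scale, at the cost of not reproducing
the acetylation-dominated marginals of real corpora. Each assigned PTM
stamps its planted positional preferences — four (offset, residue)
pairs at enrichment probability 0.9, offsets disjoint across PTM types
so co-occurring labels compose — into the flanks, never overwriting a
modified centre K. The manifest records every planted site and the
feature columns the motifs make informative (the coupling column at
each motif offset and the one-hot column of each (offset, residue)
pair), which closes the loop with feature selection in tests.

What the generator does *not* emulate: homology between proteins (and
hence similarity-linked train/validation windows), realistic per-PTM
sequence logos, composition biases of modified regions, or annotation
noise. Passing tests therefore demonstrate that the pipeline recovers
planted signal under honest held-out evaluation at the stated
imbalance — not field performance on real proteomes.

## Problem sizes and numerics

Library tests run on corpora of 30–40 synthetic proteins; the
end-to-end study (tests and `scripts/acceptance.py`) uses 120 proteins
→ ≈2900 candidate windows → ≈380 balanced samples, chosen so the whole
suite completes in a few minutes on one CPU while every per-PTM task
retains ≥30 positives. Determinism: all randomness flows through
explicit integer seeds (generator, hardness folds, CV repeats, SVM
internals); identical inputs give bit-identical feature matrices and
identical reports, which the tests assert. The CKSAAP/ANOVA/metric
implementations are checked against brute-force oracles at 10⁻¹²/10⁻¹⁰
absolute tolerance; SVM-level symmetry properties hold only to the
delegated optimizer's stopping tolerance (~10⁻³).

## Known limitations

- Exact-identity dedup only; homologous near-duplicate windows can
  inflate CV estimates on real data.
- The five binary heads share no joint output model; systematic label
  co-occurrence beyond what the representation captures is ignored.
- Window size ζ is a configuration knob (default 24); the model-selection
  sweep over ζ is not part of the pipeline.
- Hyperparameters C and γ are fixed at the libSVM defaults by design;
  no tuning loop is provided.
- Structural, evolutionary (PSSM) and other encoders beyond the four
  described are out of scope.
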