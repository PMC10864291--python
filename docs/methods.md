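# Methods

This note documents the models and procedures implemented in `cuckoonet`,
the parameter choices that matter, the synthetic study conditions, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and protocol

The unit of analysis is a real matrix of expression values, samples × genes,
with a two-class label per sample (tumor / normal). Labels on disk may be any
two strings; the lexicographically smaller string maps to code 0, so the
mapping needs no configuration and is stable across runs. Splitting follows
the common benchmark protocol: a stratified 70/30 train/test split (per
class, train receives `floor(0.7 · class size)` samples — for an 86/70
cohort that is 60+49 train, 26+21 test) and stratified 5-fold
cross-validation with per-class fold sizes differing by at most one. Both are
deterministic given a seed. Published descriptions of this protocol often leave stratification
unstated; we stratify because the classes are unbalanced, and record this
as an assumption.

## Z-score normalization

Per gene: v' = (v − mean)/sd, with the population standard deviation
(divisor n) by default and `ddof=1` available. The plain "standard deviation
of feature A" notation does not fix a divisor; population sd is the direct
reading. Zero-variance genes map to 0 rather than raising: constant genes
are uninformative and common in small fixtures. Inside pipelines the
statistics are always fitted on training data only and applied to the test
side, so no information leaks across the split. Normalization is per gene (feature-wise), the standard choice for
expression matrices where genes live on different scales.

## Improved cuckoo-search gene selection (ICSO)

Search space: continuous positions in [0,1]^G, thresholded at 0.5 into gene
masks — the standard binary adaptation of cuckoo search. Per generation `t`:

- every nest proposes a Lévy flight `clip(h + α_t ⊙ Lévy(λ), 0, 1)`; each
  proposal replaces a uniformly chosen nest if strictly fitter;
- the worst `ceil(p_a · N)` nests (never the current best) are abandoned and
  rebuilt by a biased random walk `clip(h_k + U(0,1) ⊙ (h_r1 − h_r2), 0, 1)`
  between two random nests;
- the global best is retained (elitism), so the best-fitness trace is
  non-decreasing. With `T = 0` the trace holds the post-initialization best
  as its single entry.

Two structural choices deserve comment. An alternative reading of the
algorithm performs a single random-cuckoo proposal per iteration and rebuilds
abandoned nests at fresh uniform positions. Implemented that way, the
population never concentrates: uniform re-initialization keeps injecting
~G/2-gene masks, and at any realistic budget the best mask found retains
roughly half its genes as noise. The full-generation sweep and the
random-walk reconstruction are the forms used in canonical cuckoo-search
implementations, and they are what make the sparsity-seeking tie-break
(below) effective.

**Step-size schedule.** α_t = a_max · (a_max/a_min)^(−t/T) · ran · 0.01 with
`ran ~ U(0,1)`: exactly `a_max`'s geometric factor at t = 0 and `a_min`'s at
t = T. The 0.01 damping is kept verbatim as the schedule is usually written;
because of it, defaults `a_max = 100, a_min = 1` are used so that early
flights move O(1) in the unit cube and late flights O(0.01). (With
`a_max = 1` the largest possible step is ~0.005 and the search cannot leave
its initialization.)

**Lévy sampler.** The heavy-tailed step uses Mantegna's construction with
stability index β = λ − 1 (default λ = 2.5, i.e. β = 1.5, the canonical
cuckoo-search choice): `u/|v|^(1/β)` with `u ~ N(0, σ_β²)`, `v ~ N(0,1)` and
the Mantegna scale σ_β. The tail exponent is verified in the tests by a Hill
estimator on 10⁵ draws.

**Fitness.** Validation accuracy of an injectable classifier trained on the
masked genes; the empty mask scores 0. The default is a Euclidean
nearest-centroid rule: deterministic, hyperparameter-free, O(samples×genes),
cheap enough to sit in the loop (the WCNN itself is far too slow for that
and can be injected for a final run). Fitness ties are broken toward fewer
genes — the point of selection is a smaller panel at equal accuracy. The
exhaustive oracle (`exhaustive_best_mask`, G ≤ 20) breaks remaining ties
toward the lexicographically smallest bit tuple.

**Variance-reduced fitness for recovery studies.**
`repeated_split_evaluator(n_splits, train_frac, seed)` pools the data it is
given and averages nearest-centroid accuracy over several stratified
re-splits with a small training fraction. Rationale: with a single frozen
validation split, each uninformative gene carries a fixed luck term of the
order of a few validation samples, which typically exceeds its small
expected cost; the accuracy argmax then genuinely contains spurious genes no
matter how good the optimizer is. Averaging over re-splits shrinks the luck
term ~1/√n_splits while leaving the expected cost untouched, making the
planted subset the strict optimum.

Defaults: N = 25 nests, p_a = 0.25, T = 100, threshold 0.5. Benchmark write-ups of this method rarely publish search
hyperparameters; these are conventional values.

## Weighted CNN

Architecture (for G genes): per-gene weights w ∈ R^G applied entrywise
(initialized at 1, so the weighted stage starts as the identity and the
model is a strict generalization of a plain CNN) → row-major embedding into
a `ceil(√G) × ceil(G/ceil(√G))` grid, zero-padded → 5×5 conv (8 filters) →
ReLU → 2×2 max-pool → 5×5 conv (16) → ReLU → 2×2 max-pool → 1×1 conv (16) →
ReLU → dense hidden (32, ReLU) → dense 2 → softmax. "Weighted" is realized as
this trainable first-stage gene weighting: the minimal construction that
behaves as a 1×1 weighted convolution of the input and addresses first-layer
information loss. Weighting filter maps or loss terms instead would be
alternative, less direct designs.

Pooling keeps a trailing partial block (ceil division), so a 13×13 grid —
169 genes — is the smallest input the two 5×5 stages accept; `train` raises
a named error below that. In pipelines, if gene selection prunes below 169
genes the mask is topped up with the highest-ranked unselected genes by the
best nest's continuous position (the search's own per-gene confidence),
keeping the run deterministic.

Training: mini-batch SGD (batch 16) on mean cross-entropy with exact
analytic gradients for every parameter group (verified against central
finite differences at 1e-5 relative). Initialization is Glorot-uniform per
layer with small uniform biases; a fixed-scale alternative
(`init_scale=0.05`) is retained but collapses activations through the
three-conv stack and will not train — that, and a default learning rate of
0.05 (0.01 does not reach loss < 0.1 on the separable micro-problem within
50 epochs), are deliberate deviations from naive defaults, chosen from the
convergence behaviour of the separable fixture. Conv layers apply ReLU after
the bias (switchable to identity); a purely linear conv stack cannot benefit
from depth. Prediction ties (p₀ = p₁) go to class 0. Softmax uses
max-subtraction stabilization; probabilities sum to 1 to 1e-12 even for
logits of ±1000.

Serialization is a single JSON document (config, gene ids, parameter arrays
as nested lists); `repr`-precision floats make the round-trip bit-exact.

## Metrics

Accuracy, precision, recall, F-measure and error rate are percentages,
computed in full precision and rounded half-up to two decimals only at
serialization. Two details follow the way such benchmarks are usually
printed rather than the formulas sometimes printed beside them:

- `accuracy_pct` defaults to overall correctness (TP+TN)/total. A
  `literal` variant computing TP/(TP+FP) — the precision formula,
  which some write-ups print under the accuracy heading — is kept behind a
  flag for transparency.
- `error_rate_pct` is 100 − accuracy. The "approximate vs. exact value"
  relative-error formula that sometimes accompanies it is not computable
  from a confusion matrix at all; published error-rate rows match
  100 − accuracy up to rounding drift.

The positive class defaults to code 1 (tumor). Undefined metrics (zero
denominators) raise a typed error and appear as NaN in reports. ROC curves
use descending unique score thresholds with an `inf` sentinel, and AUC is
the trapezoid rule — identical to the Mann–Whitney U statistic, which the
tests verify to 1e-12 against an independent pairwise implementation and
scikit-learn. Fold aggregation is the arithmetic mean per metric.

One arithmetic caveat for cross-checking against printed tables: a
harmonic-mean F cell can disagree with its own printed precision/recall pair
in the last digit (e.g. P = 93.01, R = 91.91 gives F = 92.4567, which rounds
to 92.46, not the 92.45 some tables print). The package always reports the
exact formula value.

## Synthetic data generator

`SyntheticSpec` defaults emulate the shape of the classic lung
adenocarcinoma benchmark cohort: 86 tumor vs 70 normal samples and
thousands of genes (default 2000; a 7129-gene full-scale run is one
parameter away). Non-informative genes are i.i.d. Gaussian noise, identical
across classes; a planted subset (default 20 genes, seeded random positions)
is shifted by `effect_size · noise_sd` in the tumor class and may share an
equicorrelated Gaussian factor (`block_corr`). Baseline expression is 0
pre-normalization — Z-scoring makes any constant baseline irrelevant, so
realism in the baseline level is deliberately not attempted.

What the generator does **not** emulate: probe/batch effects, missing
values, heavy-tailed or count-like intensity distributions, correlated noise
between non-planted genes, label noise. Tests passing on this generator
therefore demonstrate algorithmic correctness (recovery of location-shift
signal, calibration of the protocol), not robustness to microarray
artifacts.

## Study conditions in the acceptance script

- **Oracle equivalence:** ten G = 10 problems (3 planted genes, 1-sd shifts,
  40+40 samples); ICSO at N = 15, T = 200 must match the exhaustive optimum
  fitness in ≥ 9/10 seeds.
- **Parameter recovery:** 8 planted genes of 30 with 0.9-sd per-gene shifts
  (summed planted shift 7.2 sd over unit noise), 500 samples per class,
  repeated-split fitness (10 splits, train fraction 0.05), ICSO at N = 25,
  T = 100, a_max = 100, a_min = 1. The per-gene shift is deliberately
  moderate: with very large shifts a single planted gene saturates
  validation accuracy and the fewer-genes tie-break makes a one-gene mask
  optimal, so full recovery is only a meaningful target when the genes are
  jointly, not individually, sufficient.
- **End-to-end pipeline:** an 86/70 cohort with 1000 genes, 100 informative
  at 5-sd shifts; selection with defaults, WCNN at 40 epochs; holdout
  accuracy on the 47 test samples. Problem sizes throughout are chosen so
  the whole script completes in a few minutes on one CPU.

## Limitations

- Binary classification only; the softmax head is fixed at two classes.
- The grid embedding imposes an arbitrary 2D locality on genes; the 5×5
  kernels mix whichever genes happen to be adjacent in the grid. The
  learnable gene weights mitigate but do not remove this arbitrariness.
- Wrapper selection with a nearest-centroid surrogate targets location-shift
  signal; interaction-only genes (zero marginal shift) will not be selected.
- CPU-only, dense numpy; practical up to ~10⁴ genes and ~10³ samples.
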