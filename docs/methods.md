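# Methods

## Problem and model

`ddigrade` predicts the clinical severity grade of a drug-drug
interaction (DDI) between an antiretroviral (ARV) and a comedication
from molecular structure only. The grade is one of four ordered
categories, Green < Yellow < Amber < Red, encoded internally as 0..3
and serialized by name. The modelling premise is the similar-property
principle: structurally similar drugs tend to participate in similar
interactions, so a representation built from structural similarity
should carry grade information that extrapolates to drugs without
curated entries.

### Featurization

* **Fingerprints.** Morgan circular fingerprints, radius 2, 1024 bits
  (RDKit). Radius and width are the field's defaults for drug-like
  molecules and fix the input contract of everything downstream. A
  fixed-dose combination is one record with one SMILES per component;
  its fingerprint is the bitwise union of the component fingerprints —
  the only merge that preserves both set-bit semantics and vector
  length. Union is commutative, associative and idempotent, which the
  property tests exercise directly.
* **Similarity profiles.** A drug is represented by its Tanimoto
  coefficients against a *reference panel*: every drug of the training
  universe, ordered lexicographically by drug id and frozen at fit time
  (model weights depend on panel order, so the panel is persisted with
  the model). A training drug queried against the panel sees its own
  1.0 self-similarity — that is informative, not leakage, because
  held-out drugs are simply absent from the panel. Pair features are
  the ARV profile followed by the comedication profile (2R values);
  orientation is fixed ARV-first since the grading relation is
  asymmetric by construction.
* **Embedding stub.** A second featurizer backend maps the merged
  fingerprint through a frozen Gaussian projection (seeded by a module
  constant, not a run seed) to 768 dimensions with a tanh squash. It is
  a synthetic stand-in with the same shape contract as transformer
  molecular embedders and exists so that code paths, persistence and
  benchmarks covering a second backend are testable offline. A real
  pretrained embedder can be plugged in behind the same transformer
  interface; any such adapter must document its token-pooling choice.

### Tanimoto conventions

T(a, b) = |a∩b| / |a∪b| on equal-length bit vectors. Two all-zero
vectors are defined as similarity 0.0 with a warning; the case cannot
occur for valid molecules but must not crash on degenerate input.
Correctness is pinned to an independent set-arithmetic oracle at
1e-12 on random vectors.

### Imbalance handling

Grade frequencies are skewed roughly 72 / 7.6 / 16 / 4.4 %. Two
mechanisms are combined, and both are bookkept explicitly in logs:

* **Undersampling ensemble.** The majority grade (detected from data,
  not hard-coded) is shuffled with the master seed and split into
  k = 5 equal chunks of floor(n_maj / k); the remainder pairs are
  dropped and logged by position. Every minority pair is copied into
  all k subsets, so no example is wasted. Each subset trains one
  ensemble member.
* **Inverse-frequency class weights**, computed per member subset:
  w_c = N / (C·n_c) with C the number of *present* classes; absent
  classes get weight 0 and never contribute loss. The invariant
  n_c · w_c = N / C (identical across present classes) is property
  tested. Weights enter the loss as a per-sample multiplier w_{y_i}.

### Member networks

Feed-forward softmax classifiers implemented in NumPy (the package
deliberately has no deep-learning framework dependency; the network is
small enough that a transparent, fully seeded implementation is easier
to verify than an external engine):

* presets: `sim` = hidden {1024, 512, 256, 128}, ReLU;
  `embedding` = hidden {256, 128}, tanh — the two optimized
  architectures for the two backends; `small` = {256, 128}, ReLU with
  early-stopping patience 20, sized for the modest similarity panels of
  synthetic benchmarks;
* dropout 0.2 after every hidden layer (inverted dropout);
* loss: class-weighted sparse categorical cross-entropy;
* optimizer: Adam, lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7, batch 128;
* early stopping: 10 % stratified slice held back *from the member's
  own training subset* (never from an outer evaluation fold — that
  would leak), patience 10 epochs (20 for `small`), max 200 epochs,
  best-validation weights restored; classes too small to spare a
  sample stay entirely in training;
* initialization: He scaling for ReLU, Xavier-style for tanh, all
  draws from `default_rng(seed)`; member i uses master seed + i for
  weights, shuffling and dropout;
* a non-finite training loss aborts with diagnostics rather than
  silently producing NaN predictions.

Epochs, batch size, patience and the validation-slice construction are
package choices (flagged defaults in `NetworkSpec`); they are not
externally fixed quantities.

### Soft voting

The ensemble probability is the elementwise mean of the members'
softmax outputs (the mean preserves the simplex, which is asserted).
The predicted grade is the argmax; *exact* ties break toward the more
severe grade — clinically conservative and configurable
(`tie_break="first"` restores plain argmax). With k = 1, undersampling
off and weights off, the estimator reduces to the plain single softmax
classifier used as the non-ensemble baseline.

### Evaluation

All metrics are one-vs-rest reductions of the 4x4 confusion matrix
(rows = truth). Per class: accuracy, precision, sensitivity,
specificity, F1, balanced accuracy = (sensitivity + specificity)/2.
0/0 conventions: precision, sensitivity and F1 are 0 when their
denominator is 0. Aggregates: plain macro mean over the four classes
and frequency-weighted macro with weights n_i / N (weights sum to 1 by
construction). ROC-AUC is computed per class on the *voted*
probabilities by pairwise concordance with ties counting one half
(equivalently the Mann-Whitney statistic); the test suite pins it to
independent trapezoidal curve integration and to the reference library
implementation. Confusion matrices are row-normalized, matching how
per-grade correct-prediction rates are usually quoted.

Alongside the weighted one-vs-rest balanced accuracy, reports carry
`macro_recall` — the mean per-class sensitivity, i.e. multiclass
balanced accuracy in the scikit-learn sense. The distinction matters:
for any label-independent classifier the one-vs-rest quantity sits at
0.5, while macro recall sits at 1/C = 0.25. Signal-recovery statements
against a no-signal baseline therefore use macro recall.

Cross-validation is stratified k-fold with per-class seeded shuffling
and round-robin assignment with a rotating global start, which keeps
per-fold class counts within one pair of perfect proportionality and
fold sizes within one of each other. The independent test is
*drug-anchored*: entire ARVs are held out, so every test pair involves
an unseen drug — the realistic deployment scenario, and the split CV
cannot emulate.

### Baselines

GaussianNB, decision tree and random forest (scikit-learn engines)
tuned by exhaustive `GridSearchCV` over their published grids
(NB: two prior vectors x three var_smoothing values; DT: 144
combinations; RF: 432) with stratified, seeded 5-fold internal CV, and
scored through the same metric code path as the ensemble so
conventions cannot drift. The prior vector (0.1, 0.1, 0.3, 0.5) maps
positionally to (Green, Yellow, Amber, Red). A one-off test validates
the engine's Gaussian class likelihood against the closed-form normal
density on a four-point dataset.

## Synthetic data generator

The generator produces download-free datasets carrying the statistical
structure the method assumes; it is first-class, tested code.

* **Molecules.** SMILES come from an enumeration grammar: ten small
  scaffolds (benzene, pyridine, thiophene, furan, benzofuran,
  cyclohexane, ester/amide cores) crossed with twenty substituents,
  plus four large amide scaffolds whose first slot extends a
  peripheral alkoxy tail — their chain homologs are near-identical
  analogs (pairwise Tanimoto > 0.9, often 1.0), giving the universe
  the analog-series structure real drug lists have. All candidates
  are RDKit-validated and canonicalized; capacity is ~3,900 unique
  molecules and exceeding it is an explicit error. Universes are
  seeded permutations of the pool; a configurable fraction of ARVs
  (default 0.2, round-half-up) become 2-3 component combinations.
  Synthetic ARV classes cycle through five tokens, and hold-out ARVs
  are drawn round-robin across classes so the unseen-drug test spans
  all of them.
* **Latent pharmacology.** Each drug gets a latent vector of length
  L = 16: `signal` x a standardized seeded random projection of its
  fingerprint + (1 − signal) x per-drug Gaussian noise. The projection
  rows are L2-normalized fingerprints of L seeded probe drugs from the
  universe, so each structural coordinate is a cosine-style similarity
  to a probe — deliberately the same geometry a Tanimoto profile
  measures. A dense Gaussian projection would encode the signal in a
  basis that similarity profiles can barely express, making recovery
  fail for reasons unrelated to the method.
* **Interaction scores and grades.** A pair's score is a dense seeded
  bilinear form of the two latents, standardized within each
  comedication column. The calibration makes grade ranks comparable
  across comedications and guarantees that at signal 0 an unseen ARV's
  grades are exchangeable — i.e. exactly chance-level, so the
  no-signal control is meaningful. Grades are assigned by exact
  quantile quotas (largest-remainder rounding), so realized class
  counts match the target proportions exactly rather than
  multinomially. When a hold-out is defined, the training stratum is
  quota-graded and its empirical thresholds grade the held-out
  stratum: one shared score→grade map, no count coupling between
  strata, and column calibration uses training rows only (using all
  rows measurably anti-correlates training priors with test truth).
* **Presets.** The default geometry is 125 ARVs x 40 comedications =
  5,000 pairs with the 72/7.6/16/4.4 skew and 8 held-out ARVs:
  unseen-drug generalization at this size needs many distinct anchor
  drugs, and this geometry is the package's standard recovery-surface
  condition. The `database_shape_config` preset instead mirrors a
  realistic database shape (44 ARVs x 700 comedications, strata
  trimmed to 25,039 training and exactly 5,103 held-out pairs graded
  3221/358/1146/378 — real databases are not full cross-products, so
  surplus candidate pairs are dropped at random, seeded).

**What the generator does not emulate:** pharmacological mechanisms
(the latent model is a statistical stand-in), real ARV chemical space,
curation noise and inter-database grading disagreement, or
non-structural determinants of DDIs (transporters, PK/PD context).
Passing recovery tests therefore demonstrates that the pipeline
extracts structure-encoded grade signal under its own premise — not
clinical performance on real data.

## Determinism

Every stochastic step — universe permutation, probes, noise, bilinear
matrix, stratum trimming, undersampling shuffle, fold assignment,
weight init, dropout, batch order — derives from explicit seeds
(`SeedSequence([seed, tag])` streams inside the generator; master seed
+ member index inside the ensemble; master seed + 1000·(fold+1) in
CV). Two runs with the same configuration and seed produce
byte-identical prediction tables, which is asserted at file level.

## Known limitations

* The ensemble trains one member per subset with a fixed preset; the
  published-scale hyperparameter sweeps (layer-count/width grids,
  dropout options) are out of scope — presets only.
* Fingerprint radius/length sweeps, 3-D descriptors and similarity-map
  rendering are out of scope.
* The embedding backend ships only as the deterministic stub; results
  with a real pretrained embedder will differ.
* Grid-searching the full random-forest grid on large feature matrices
  is expensive; the benchmark harness accepts reduced grids for smoke
  runs (the full grids remain the defaults and their contents are
  tested).
* Multi-component comedications are accepted (components for any drug),
  although marketed combinations are typically ARVs.
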