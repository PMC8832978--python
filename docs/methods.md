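# Methods

## Problem setting

`snarekit` treats SNARE-protein identification as binary sequence
classification under a roughly 1:10 class imbalance. The pipeline is
descriptor extraction → hybrid balancing of the training data →
gradient-boosted tree classification → imbalance-aware evaluation. Each
stage is an independent module; this note records the models, the
parameter choices that matter, and what the synthetic benchmarks do and
do not establish.

## Sequence handling

FASTA input is parsed with Biopython; sequences are upper-cased, joined
across wrapped lines and validated against the 20-letter canonical
alphabet. Non-canonical symbols (B, J, O, U, X, Z, gaps) make composition
descriptors ill-defined, so affected records are either dropped
(`reject`, the default) or have the symbols removed (`strip`); either way
a warning is logged. Records shorter than 3 residues are always dropped —
skip-pair encoders need at least one gap-2 pair. Duplicate ids get a
numeric suffix so downstream matrices keep unique row keys.

Train/independent splitting is stratified per class with
`floor(test_fraction × class_size)` test records, so the per-class test
proportion is within one record of the requested fraction. At the
benchmark scale (697 positives, 9:1 split) this leaves 628 positives in
the training pool. Splits are deterministic per seed.

## Descriptors

All pair-based encoders index ordered dipeptides as
`20·index(first) + index(second)` over the fixed alphabet
`ACDEFGHIKLMNPQRSTVWY`.

* **AAC** (20): residue frequencies.
* **GDC** (400): ordered-pair frequencies at one gap g, divided by the
  L−g available pairs so each gap level is a proper distribution.
* **ASDC** (400): pair counts accumulated over all gaps g = 1..L−1 and
  normalised jointly. The identity Σ counts = L(L−1)/2 (every position
  pair counted once) is asserted inside the encoder. Implemented with a
  prefix-histogram matrix product (O(20L)); tests cross-check it against
  a brute-force double loop.
* **CKSAAP** (400·(kmax+1), default kmax 3 → 1,600): per-spacing blocks,
  each normalised by its own pair count; the k-block equals GDC at
  g = k+1, and tests enforce that equivalence.
* **DDE** (400): adjacent-pair frequency standardised against the
  theoretical mean Tm = (C₁/61)(C₂/61) from synonymous-codon counts of
  the standard genetic code and variance Tv = Tm(1−Tm)/(L−1).
* **QSOrder** (40+2·nlag, default nlag 2 → 44, weight w = 0.1): for each
  of two residue distance matrices, coupling numbers
  τ_d = Σ_i d(R_i, R_{i+d})² and the normalisation group
  [f₁..f₂₀, w·τ₁..w·τ_nlag] / (Σf + wΣτ). nlag = 2 is the default because
  it matches the 44-dimension convention this toolkit follows (the common
  nlag = 30 would give 100).

### Distance-matrix data

Two 20×20 matrices ship as versioned JSON package data:

* `grantham.json` — Grantham's distance, recomputed from his
  composition/polarity/volume formula with the scale constant set so the
  mean over the 190 residue pairs is 100. Spot checks against the
  published integers: R–L 102.0, L–I 4.9, S–R 109.4, C–W 214.6.
* `physchem_distance_synthetic.json` — a synthetic physicochemical
  distance built here from three classical scales (hydrophobicity,
  hydrophilicity, side-chain mass; standardised, root-mean-square
  difference). It stands in for the Schneider–Wrede distance commonly
  paired with Grantham's in quasi-sequence-order encoders, which is not
  redistributable from any dependency of this package; it is **not** the
  Schneider–Wrede matrix, and QSOrder values are therefore not
  numerically comparable with encoders that use it, though the
  descriptor's structure and normalisation are identical.

## Hybrid balancing

Negatives are reduced to the target n by taking the first n entries of a
single seed-determined permutation. This "prefix of one permutation"
design makes retained subsets nested — S(n) ⊂ S(m) for n < m under one
seed — so a sweep over n varies only the amount of data, not which
samples happen to be drawn.

Positives are raised to n by SMOTE. Seed samples are assigned round-robin
over the positives (a remainder beyond whole rounds is assigned by the
seeded RNG without replacement), the neighbour is uniform among the K = 5
Euclidean nearest minority neighbours (K follows the original SMOTE
default; neighbour ties resolve to the lowest row index), and the default
interpolation is the canonical

    x_new = x + u · (x_n − x),  u ~ Uniform(0,1), one u per row.

A second variant, `paper-literal`, implements the absolute-value form
`x_new = x + u·|x − x_n|` componentwise, as the formula is sometimes
printed; it only moves coordinates upward and is kept for fidelity and
comparison, not as the default. The absolute-value form is almost
certainly a typesetting artifact of its sources, which is why the
canonical interpolation is the default.

Balancing runs on extracted features, and only ever on training
partitions: inside cross-validation it is applied per fold to the
training part (the sweep-level n is scaled by (folds−1)/folds and clamped
to the fold's feasible range), and the independent set is never touched.
This is the leakage-safe reading; balancing before splitting would
inflate CV metrics.

Boundary semantics: n = (positive count) is pure downsampling (zero
synthetic rows); n = (negative count) is pure oversampling (no negatives
dropped). The feasible range is [positive count, negative count].

## Classification

The primary learner is a histogram gradient-boosted decision tree
(LightGBM) with defaults num_leaves = 31, max_depth = 10,
learning_rate = 0.08 — the tuned optimum for this task — and
n_estimators = 100 (the estimator count is otherwise unreported;
100 with no early stopping favours reproducibility over tuning).
A leaf-wise tree with k leaves requires depth ≥ ⌈log₂(k+1)⌉; bounded
configurations below that floor are rejected before fitting (31 leaves
need depth ≥ 5). Random-forest and XGBoost backends sit behind the same
interface for the descriptor × classifier benchmark; backend-specific
extra parameters are filtered to what each backend accepts.

Determinism is part of the contract: fixed seed plus single-threaded
execution give bit-identical scores. Multi-threading is available
explicitly and waives the contract. Hard labels use a fixed 0.5
threshold — AUROC is reported precisely because thresholds are arbitrary.

## Evaluation

Sens = TP/(TP+FN), Spec = TN/(TN+FP), Acc = (TP+TN)/total and MCC are
computed from pooled confusion counts. Conventions: a vanishing MCC
denominator yields 0 (standard practice, keeps sweeps total); an empty
sensitivity/specificity denominator yields 0; all-zero counts are an
error. Metrics are stored as proportions and rendered as percentages.

AUROC uses the rank (Mann–Whitney) formulation with midranks for ties,
which equals the trapezoidal area under the empirical ROC; tests verify
it against brute-force pair counting (n ≤ 50) and scikit-learn.

Cross-validation is stratified k-fold (default 5 folds, configurable)
with held-out predictions pooled before computing metrics once — well
defined even when folds contain few positives, though it can differ
slightly from averaging per-fold metrics, which is one plausible source
of discrepancy when comparing against externally reported numbers.

## Synthetic data

Sequences are first-order Markov chains. The negative class uses uniform
transitions. The positive class depends on the mode:

* `composition-shift`: all transition rows equal one tilted residue
  distribution `softmax(separation · z)`, z standard normal — the classes
  differ in composition, and every descriptor can see it.
* `order-shift`: the transition matrix is `exp(separation · G)` balanced
  to doubly stochastic by Sinkhorn iteration, so the stationary residue
  distribution stays exactly uniform — class mean compositions coincide
  and the signal lives in residue order.

Default sizes are 200 positives / 2,000 negatives (the 1:10 ratio of
curated SNARE collections) with lengths uniform on [50, 200];
separation 0.5 in composition-shift mode gives a cross-validated AUROC
near 0.97, and separation 0 is an exact null (both classes share one
generator). Order-shift runs use shorter sequences (lengths 15–40) and
separation 1.5: ASDC's mass at gap g scales like (L−g), so only ~2/L of
it sits at gap 1 and long sequences dilute a one-step transition
perturbation below detectability. Shorter chains concentrate the order
signal, and there ASDC's CV AUROC exceeds AAC's by ~0.12.

Two caveats on what these fixtures show. First, AAC is not at chance in
order-shift mode (~0.7 AUROC): double stochasticity fixes the *mean*
composition, but residue clumping inflates the variance of each
sequence's realised composition, which a tree ensemble detects — the
meaningful claim is the ranking ASDC > AAC, not AAC ≈ 0.5. Second,
Markov fixtures carry none of the real biology (SNARE motifs, heptad
repeats, homology structure), so passing these benchmarks shows the
pipeline recovers the statistical structure it is pointed at, not that
it attains any particular accuracy on real proteins.

`generate_clusters` provides seeded spherical Gaussian clouds for the
SMOTE geometry property tests.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale:
pipeline checks use 2,200 sequences × 400 ASDC features with 5-fold CV,
property suites use 100-sequence oracle sweeps, 1,000 SMOTE points and
50 downsampling seeds. Composition distributions are validated to 1e-9;
SMOTE collinearity to 1e-9; Sinkhorn balancing runs 200 iterations
(residual far below sampling noise). Seeds derived from a master seed use
`numpy.random.SeedSequence` and stay below 2³¹.

## Known limitations

* No evolutionary-profile (PSSM) features and no neural-network backends;
  the 2D-CNN comparison lives only as a published-cells delta report.
* No feature selection; descriptor concatenation is provided
  (`concat_features`) but mixing value ranges across descriptors is known
  to help little or hurt.
* SMOTE variants (Borderline-SMOTE, ADASYN) and cost-sensitive learning
  are out of scope; undersampling is uniform-permutation prefix only.
* The QSOrder physicochemical matrix is a documented synthetic stand-in
  (see above).
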