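# Methods

## Scope and data model

The package classifies subjects described by per-region mean tracer
intensities from spatially normalized FDG-PET volumes. Spatial
normalization, smoothing and partial-volume correction are upstream
concerns: the extraction step only requires a volume and an integer atlas
label map on the same grid (shape and affine are checked; no resampling is
performed). Per-subject intensity normalization divides each regional mean
by the grand mean over regions (SUVR-style, reference = whole parcellation).
This choice — per-subject rather than cohort-level scaling — makes the
feature vector invariant to global uptake differences between subjects and
scanners, which is the property the downstream model actually needs; it is
also idempotent and preserves regional contrast.

## Network

Input is a length-R region vector treated as a 1-channel 1-D sequence — the
only layout under which "convolution over regional features" is
well-defined. Two convolution blocks `σ(BN(conv(·)))` with "same" padding
(default channels 16 and 32, kernel 3) yield a feature map that is
flattened (channels × positions) into the d-vector `Y` fed to the
interaction stage.

The interaction stage is factorized bilinear pooling
`B = Pᵀ(UᵀY ∘ VᵀY)` with dictionary rank r (default 32) and output length
o (default 64). Algebraically `B` with unit projection equals the quadratic
form `YᵀUVᵀY`; the implementation's identity with an explicit double-loop
quadratic form, and its exact second-order homogeneity (`Y → αY` scales the
output by `α²`), are both under test. An average-pooling stage (window 2)
then halves the output, and the head is two fully connected layers:
embedding (default width 32, ReLU) and a 1-unit output with sigmoid. With
`use_bp=false` the bilinear stage is replaced by a single fully connected
layer of matched output size, leaving every other stage identical — the
Baseline ablation. This head depth resolves an ambiguity in the
architecture's published descriptions ("two fully connected layers" after
the bilinear stage vs "three fully connected layers" in the Baseline): the
Baseline's replacement FC is exactly the third layer. A deeper head is
available via `fc_dims`; note that extra ReLU layers can themselves learn
multiplicative feature interactions, which blurs the Baseline/bilinear
contrast in ablation studies.

The network, including backpropagation through the bilinear stage and batch
normalization, is implemented directly in NumPy. The backward pass is
verified against central finite differences end to end (all parameter
groups, with and without metric losses). Initialization is Kaiming-uniform
with seeded generators; batch norm uses momentum 0.1, eps 1e-5, batch
statistics during training and running statistics at inference (the
standard convention; the source material does not state one).

## Losses

* Cross-entropy `L_C`: mean binary cross-entropy on probabilities clamped
  to [1e-7, 1−1e-7]; the clamp is invisible at reported precision. The
  gradient is taken through the logit (`p − y`), which is exact and stable.
* Contrastive loss: `mean[s·d² + (1−s)·max(0, m−d)²]` with `d` the
  Euclidean distance and `s` the same-class indicator. The printed symbol
  convention in the source material (distance defined as a squared norm
  that is then squared again, and an inverted pair label) is internally
  inconsistent; the implemented form matches the described behaviour
  (same-class pairs contract, different-class pairs repel up to the
  margin). The literal-symbol variant remains available
  (`contrastive_loss(..., literal=True)`) for comparison, without gradient
  support.
* Triplet loss: `mean[max(0, m + d_ap − d_an)]` with squared Euclidean
  distances, as printed (unambiguous there).
* Joint loss: `λ·L_M + L_C`, λ = 0.05 by default, margin m = 1.0.

Metric losses are computed on L2-normalized embeddings (the classifier path
sees the unnormalized embedding). Without normalization the same-class `d²`
term dominates whenever the embedding scale exceeds the margin and collapses
the representation, measurably degrading AUC; on the unit sphere m = 1 is a
scale-free quantity. The normalization is differentiated exactly.

Pair/triplet construction: every sample anchors one pair (or one triplet,
when a same-class partner exists). `random` mining samples partners
uniformly; `semi_hard` prefers different-class partners inside the margin
(pairs) or negatives with `d_ap < d_an < d_ap + m` (triplets), falling back
to uniform sampling when none exist. Batches are stratified so both classes
appear in every batch and mining never fails mid-training; the metric loss
is computed on every batch. Random mining rarely selects informative pairs
once the classes are roughly separated, so benchmark and ablation work uses
`semi_hard`.

## Optimization

SGD with momentum 0.9 and weight decay 0.001 (published defaults), learning
rate 0.01, batch size 32, 100 epochs by default (the published account does
not state these three; the defaults converge on desk-scale cohorts in
seconds to minutes). Gradients are clipped to a global L2 norm of 5.0
before the momentum update: the quadratic bilinear path occasionally
produces gradient spikes that otherwise drive the run to overflow, and
clipping bounds the step without changing the function class or the
comparison between variants (`grad_clip: null` disables it). A non-finite
loss or activation raises a training error naming the epoch. All randomness
(initialization, batch order, mining) derives from the config seed via
explicit NumPy generators; execution is single-threaded NumPy, so any run
is bit-reproducible from (config, seed). Per-fold models in
cross-validation derive distinct seeds deterministically from the base seed.

## Evaluation protocol

Stratified k-fold cross-validation (default k = 5) keeps per-fold class
counts within one subject of exact proportionality (a 290/147 cohort at
k = 5 gives class-0 folds of 58 and class-1 folds 30/30/29/29/29); the
80/10/10 stratified holdout is available for the independent-test-set
protocol. Metrics: ACC, PPV, NPV, SEN, SPE, F1 at probability threshold 0.5
(a Youden-optimal threshold is deliberately not the default), plus
Mann–Whitney AUC with ties counted 1/2. A metric whose denominator is zero
is reported as undefined and flagged, never as 0. Fold summaries use the
sample standard deviation (ddof = 1). ACC ≡ (SEN·P + SPE·N)/(P+N) and the
agreement of the AUC with both exhaustive pair enumeration and
scikit-learn's implementation are enforced by tests.

Variant comparisons: a two-sided paired t-test on per-fold AUCs (all
variants share fold assignments and per-fold seeds, so pairing is exact)
and the DeLong test on pooled out-of-fold scores (every subject is scored
exactly once out of fold, giving paired score vectors on identical
subjects). Zero-variance degenerate cases return defined results (p = 1 for
identical inputs) with a flag. The DeLong variance is validated against a
10,000-replicate bootstrap on a fixed 40-subject set (they agree within a
few percent).

The six-variant ablation grid — Baseline, Baseline+BP, Tri-loss,
Tri-loss+BP, Con-loss, Con-loss+BP — runs on shared folds, and the λ-sweep
evaluates λ ∈ {0, 0.03, 0.05, 0.08, 0.1} (the published grid) on shared
folds with one cross-validated AUC per value.

## Synthetic cohorts

Cohorts are drawn from class-conditional multivariate Gaussians — the
simplest model with independently controllable first-order (mean) and
second-order (covariance) structure, a reasonable stand-in for
ROI-averaged, normalized PET features. `mean_shift` sets per-region mean
differences in units of within-class sd; `interaction_pairs` adds
covariance deltas to class 1 only; a `hard_fraction` of each class is
redrawn from the midpoint distribution (averaged means and covariances) and
flagged — boundary subjects without label noise. Class covariances are
checked for positive semidefiniteness, and draws use a fixed Cholesky
factorization for determinism. The default spec mirrors the motivating
cohort: 290 vs 147 subjects, 90 regions, unit variance.

Two canonical benchmark conditions are frozen in `bmnet.benchmarks`:

* **Interaction-only** (`interaction_only_spec`): 500/class, 30 regions,
  zero mean shift, covariance delta 0.8 on six *distant* pairs
  (i, i + 15). Distance matters: a covariance difference between regions
  inside one convolutional receptive field (5 positions for two kernel-3
  layers) leaks into first-order channel statistics through the ReLU
  nonlinearity, and any variant can read it; distant pairs keep the signal
  genuinely second-order. Under these conditions a linear read-out of the
  raw features stays at chance (cross-validated AUC ≤ 0.58) while explicit
  pair products reach ≈ 0.89 — the regime that isolates what bilinear
  pooling is for. The bilinear-vs-FC comparison uses rank 64, learning
  rate 0.03, 40 epochs, 3-fold CV, three seeds.
* **Hard-sample** (`hard_sample_spec`): 290/147, 90 regions, 0.8-sd shift
  on 12 regions, 30% midpoint draws. The loss comparison (none vs triplet
  vs contrastive, λ = 0.05, m = 1) uses the Baseline architecture for all
  arms — one factor at a time — with semi-hard mining, learning rate 0.01,
  40 epochs, 3-fold CV, three seeds.

The 3-fold/40-epoch sizes are the package's desk-scale choice: effects are
stable at that size and a full benchmark takes minutes. Both effects are
stochastic; across base seeds the bilinear AUC gain is typically +0.04 to
+0.07 and the metric-loss specificity gain +0.01 to +0.03, always with the
expected sign in our runs but varying in magnitude, which is why the
benchmarks average over three seeds.

What the simulator does **not** emulate: voxel-level image structure,
scanner/site effects, non-Gaussian tails, age/sex covariates, label noise,
and realistic inter-region covariance beyond the planted pairs. Passing
benchmarks therefore demonstrate that the implementation recovers the
specific signal types it claims to exploit — not clinical performance.
Published accuracies on clinical ADNI cohorts depend on controlled-access
data and are out of scope here.

## Numerical choices and degenerate inputs

* PSD tolerance for class covariances: smallest eigenvalue ≥ −1e-9, with a
  1e-10 jitter fallback in the Cholesky.
* Probability clamp in cross-entropy: 1e-7.
* Batch norm eps 1e-5; contrastive gradient at exactly zero distance uses
  the zero subgradient.
* Empty atlas regions, NaN voxels inside regions, NaN table cells,
  non-binary labels, single-class batches and non-finite losses all raise
  descriptive errors rather than degrading silently.
* Checkpoints are single `.npz` files embedding the architecture config and
  all arrays (including BN running statistics), versioned.

## Known limitations

* Training stalls (constant-prior predictions from a dead embedding layer)
  can occur for unlucky seeds on large flattened dimensions; they are
  benign but depress a fold's AUC. Gradient clipping removes the
  divergence failure mode but not stalls.
* The Gaussian simulator cannot say anything about 3-D image-level models;
  extending the encoder to whole volumes is out of scope.
* The contrastive loss's literal printed form is preserved only as a
  value-level comparison mode.
* `extract` without a label file writes a placeholder all-zero label
  column; such tables are for scoring, not training.
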