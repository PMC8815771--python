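# Methods

## Problem setting

`dfsvm` targets binary classification with skewed class sizes, the regime of
disease-diagnosis and other biomedical screening tables where the condition
of interest is rare.  The minority (rarer) class is always labeled +1 and
the majority −1; loaders relabel by count so the convention holds regardless
of what the source file calls its classes.  The imbalance ratio
IR = n_maj / n_min drives both the oversampler's target and the classifier's
cost weighting.

The method is a three-stage pipeline: (1) a metric-learning embedding,
(2) minority oversampling in embedding space, (3) a cost-sensitive fuzzy
SVM.  Each stage is usable on its own.

## Embedding network

A feed-forward network maps the p standardized input features through three
hidden layers of widths (4d, 2d, d); the d-dimensional output of the third
layer is the embedding.  Only d is chosen (default 8; grid
{2, 4, 6, 8, 10, 12}); the earlier widths follow the halving rule.  The
activation is the Gumbel CDF σ(x) = exp(−exp(−x)): smooth, strictly
increasing, bounded in (0, 1), asymmetric, and free of the dying-ReLU
effect.  By default the third layer is also activated, so embeddings live in
(0, 1)^d — which conveniently bounds the oversampler's feature pools — but a
`last_layer_activated=False` switch exposes a linear embedding layer, since
either reading of the architecture is defensible.

Training minimizes the hinge triplet loss
max(0, D(a, min) − D(a, maj) + m) with Euclidean D, anchors and positives
drawn uniformly from the minority class and negatives from the majority
class.  Euclidean (not squared) distance keeps the loss on the same unit
scale as the margin grid m ∈ {0.1, …, 0.9} (default m = 0.2).  The optimizer
is plain minibatch gradient descent (hand-written numpy backpropagation):
learning rate 1e-2, 200 epochs, 128 freshly mined triplets per epoch in
batches of 32.  These loop sizes are the package's defaults for the small
(hundreds-of-rows) tables the method is aimed at; on such data the loss
curve flattens well before 200 epochs.  All randomness — weight
initialization (Glorot-scaled uniform) and triplet mining — derives from one
integer seed, so traces are bit-reproducible.  A non-finite loss aborts with
a diagnostic rather than training through NaNs.

## Oversampling with the center-distance filter

After embedding, the minority class is topped up to exact balance.  Each
candidate is assembled per dimension: coordinate j is drawn uniformly from
the multiset F_j of minority values observed on dimension j.  Candidates
must then satisfy the strict chain

    d(x, C_maj) > d(x, C_all) > d(x, C_min)

where the three centers are the majority, overall, and minority means of the
embedded training data (C_all is the mean of all rows, not the midpoint of
the class centers) and d is Euclidean.  Ties reject.  Candidates are drawn
by rejection sampling capped at 200 × deficit attempts; if the acceptance
region is empty (e.g. minority clusters straddling the majority so all
three centers coincide), the remaining deficit is filled by jittered
duplication of minority rows (Gaussian noise, σ = 1% of the per-dimension
minority range) and flagged `fallback_used` in the synthesis report, so
balance is always reached and the caller can see how.

Candidates may coincide with an existing minority row (all coordinates from
one donor); they are counted as ordinary accepts.  Oversampling is applied
to training folds only — validation and test folds never contain synthetic
rows.

## Fuzzy SVM

The classifier is a soft-margin SVM whose per-sample penalty is s_i·C; the
dual box constraint becomes 0 ≤ α_i ≤ s_i·C and nothing else changes, so
s ≡ 1 recovers a standard C-SVM exactly (a property the tests exploit
against an independent solver).  The membership scheme sets s_i = IR for
minority samples and 1 for majority samples.  Because the classifier is
trained *after* balancing — where the raw ratio is 1 — IR is measured on the
pre-oversampling training fold and applied to all minority rows including
synthetic ones; computing it after balancing would silently disable the
fuzzy weighting and make the FSVM-vs-SVM ablation vacuous.

The kernel is Gaussian, k(x, x′) = exp(−‖x−x′‖²/(2σ²)); the 1/(2σ²)
convention is fixed and recorded here since "width σ" alone is ambiguous.
Grids: C ∈ {10⁻³, …, 10⁴}, σ ∈ {2⁻⁵, …, 2⁴}.

The dual QP is solved by an SMO-type algorithm: at each step the maximal
violating pair under the equality constraint y'α = 0 is selected and updated
in closed form with clipping to the per-sample box.  The KKT residual is the
violating-pair gap; the solver stops at tol = 1e-6 (cap 10⁵ pair updates,
with a convergence error carrying the residual on exhaustion).  The bias b
averages y_i − Σ_j α_j y_j K_ij over margin support vectors
(tol·s_iC < α_i < s_iC(1 − tol)); when every α sits at a bound, b falls back
to the midpoint of the interval implied by the bound KKT inequalities, and
the estimate records which branch produced it.  A decision value of exactly
zero predicts the minority class, consistent with the cost-sensitive intent.

Derivation misprint policy: the stationarity condition is implemented as
s_iC − α_i − β_i = 0 and the weight expansion as w = Σ α_i y_i φ(x_i); the
dual box confirms both readings.

## Evaluation

Metrics treat minority as positive: precision, sensitivity, specificity,
F-measure (harmonic mean of precision and sensitivity), and
G-mean = √(Sen·Spe) — the radical is the universal definition even where the
name is sometimes printed without it.  Conventions: Pre = 0 when tp+fp = 0,
F = 0 when Pre+Sen = 0.  AUC is the Mann–Whitney pair statistic on the
continuous decision values (ties ½), which equals the trapezoidal ROC area;
the equality is asserted to 1e-12 against an independent implementation.

Cross-validation is stratified k-fold (default 5 folds × 5 independent
runs).  Standardization statistics, the embedding network, and the
oversampler are all fit inside the training fold only; anything else would
leak synthetic or test information.  Grid search scores each point by mean
CV G-mean (ties → first point in deterministic grid order).  Selection
re-uses the reporting CV rather than nesting, which is optimistically
biased for the selected point's reported score; the bias is accepted and
flagged here because the package's comparisons are within-CV and paired.

"5 independent runs" is read as five repetitions of the full 5-fold split
with different fold seeds (not five training restarts within one split).

## Comparison statistics

For k methods on N datasets, scores are ranked within each dataset (rank 1
best, ties averaged — the standard convention, which preserves row rank
sums).  The Friedman statistic χ²_F = 12N/(k(k+1))·[ΣR_j² − k(k+1)²/4] is
refined to F_F = (N−1)χ²_F/(N(k−1) − χ²_F), compared against the exact F
quantile with (k−1, (k−1)(N−1)) degrees of freedom.  The Nemenyi critical
difference is CD = q_α√(k(k+1)/(6N)); q_α is computed as the studentized
range quantile at infinite degrees of freedom divided by √2
(scipy's `studentized_range`), rather than from a hard-coded table — for
k = 10, α = 0.05 this gives 3.1637, matching the conventional 3.163.

The shipped benchmark tables hold published mean scores rounded to three
decimals; ranking them reproduces the published mean ranks (best method
1.33, runner-up 3.33) while F_F comes out ≈ 8.18 versus the published 8.055,
because rounding introduces ties the original unrounded scores lack.  The
null calibration of the F_F test at α = 0.05 (1,000 simulated iid score
tables at N = 12, k = 10) rejects at ≈ 5%.

## Synthetic data generator

`make_synthetic` draws each class from a mixture of isotropic Gaussians:
majority centroid at the origin, minority centroid at distance
`class_separation` along a random direction, per-cluster standard deviation
`within_class_spread`, optional sub-clusters (centers scattered at
1.5 × spread) to mimic irregular class shapes, and optional uniform label
flips.  Class counts are exact (n_min = round(n_maj/ir)) before noise.
Defaults (p = 5, n_maj = 200, IR = 10, separation 3.0, spread 1.0) describe
a moderately overlapping screening-table regime: far enough apart that the
classes are learnable, close enough that an unweighted classifier collapses
onto the majority.  The generator emulates numeric tabular data only — no
categorical attributes, feature correlations, heteroscedastic noise, or
covariate shift — so passing tests demonstrate correct mechanics and the
expected qualitative behavior under imbalance, not performance on any
particular real dataset.

The end-to-end check runs the full pipeline and an unweighted RBF-SVM
baseline (no embedding, no oversampling, s ≡ 1) on identical folds over
10 generator seeds at p = 5, n_maj = 200, IR = 10, separation 2.5, with
5-fold CV per seed and shared defaults C = 10, σ = 1; the pipeline's mean
G-mean exceeds the baseline's by a wide margin (≈ 0.88 vs ≈ 0.55 on these
conditions).

## Numerical choices and limitations

- Standardization: z-scores with training-fold statistics; constant columns
  are centered with scale 1.
- Strictness everywhere the filter or ranking needs a tie-break is
  documented at the call site (filter ties reject; grid ties take the first
  point; zero decision scores predict minority).
- The SMO solver materializes the full Gram matrix (O(n²) memory); intended
  for the small-to-medium tables this method targets, not for n ≫ 10⁴.
- Binary problems only; multi-class membership schemes, probability
  calibration, and alternative membership definitions (class-center decay,
  density-based) are out of scope, though `fit` accepts any explicit
  membership vector.
- Embedding training is full-batch-free SGD with a fixed rate; there is no
  early stopping, so `epochs` is the only budget control.
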