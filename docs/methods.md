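# Methods

## Scope and model

`nirmtl` implements a multi-task calibration-transfer-free workflow for
beer NIR transmission spectra on a shared wavelength grid (by default the
228-point uniform grid over 900–1700 nm). Three tasks are modelled from the
same absorbance matrix: two regressions (alcohol, % vol, range 3–12; original
wort concentration, °P, range 8–24) and a three-class authentication
(craft / industrial / non-fermented imitation). The central claim the
package operationalizes is that a *shared* deep feature extractor, trained
under a task-weighted joint loss whose weights are optimized together with
the architecture, yields features that serve all three tasks at once.

## Synthetic data: what it emulates and what it does not

The generator produces absorbance spectra under a Beer–Lambert mixing
model: each constituent contributes Gaussian absorption bands placed inside
the C–H/O–H overtone windows (1120–1220, 1360–1440, 1463–1530,
1620–1700 nm), scaled by its concentration, on top of a broad dominant
water band at 1450 nm. Instrument artefacts are a random quadratic baseline
(coefficient half-ranges 0.02/0.01/0.005 absorbance over a normalized
wavelength axis), a multiplicative scatter factor uniform in [0.95, 1.05],
and additive Gaussian noise (sd 0.002 absorbance). Class structure: craft
beer carries a full fermentation protein/secondary-metabolite band at
1500 nm (0.008 absorbance per °P), industrial beer 30% of it, and the
non-fermented imitation none — but the imitation carries a fixed flavoring/
citric-acid additive band at 1245 nm that fermented beers lack. This makes
the three classes linearly separable, mirroring the finding that
authentication is the easy task, and makes the middle (industrial) class
identifiable rather than masked between the other two.

The study design is fixed: 138 craft and 78 industrial samples with
(alcohol, wort) drawn from truncated correlated bivariate normals
(ρ = 0.8 — multi-task learning presupposes inter-target correlation; the
true commercial correlation is unknown and ρ is configurable), plus the
full-factorial non-fermented block of 4 alcohol × 5 wort levels × 6
replicates (120 samples, 20 unique formulations), 336 samples total.

Not emulated: radiative-transfer physics, temperature effects, instrument
drift between sessions, heteroscedastic detector noise, and the composition
diversity of real commercial beers. Passing tests on this generator
demonstrate that the machinery (selection scores, partitioning, optimization,
feature extraction, metrics) behaves correctly and that the pipeline can
recover near-linear composition signals; they say nothing about accuracy on
real beer spectra.

## Preprocessing and MCPS

Operators: Savitzky–Golay (window 11, polyorder 2, edges refit on the
truncated window), MSC against a reference spectrum (the calibration mean,
frozen at fit time when applied out-of-sample; within the pipeline,
preprocessing precedes partitioning — as in the study protocol — so the
reference is the full-data mean), SNV (sample sd), wavelet denoising
(Daubechies-4, level 3, soft universal threshold σ√(2 ln N) with σ from the
MAD of the finest detail scale; a zero threshold bypasses shrinkage so
noiseless signals pass unchanged), and Fourier low-pass denoising (default
cutoff 0.2 × Nyquist). The candidate set for selection is the five singles
plus {WD+FTD, SG+SNV, SG+MSC}; chains apply left to right.

Benchmarks are fixed-complexity on purpose: 10-LV PLSR RMSECV for the
regressions and 10-LV PLS-DA CVER for classification under seeded 10-fold
CV (stratified for classification). MCPS then scores each method by the
weighted sum of its per-task error divided by the per-task minimum over all
candidates (weights 1/3 each); the argmin is selected. MCPS ≥ 1 by
construction, with equality only for a method that is simultaneously best
everywhere. Zero classification errors are floored at 1e-12 before the
ratio so the score stays defined without affecting the ranking.

## Partitioning

The test set is a uniformly random holdout (numpy PCG64, recorded seed).
SPXY then selects calibration samples from the remainder by deterministic
max–min selection on d(i,j) = d_X/max d_X + d_Y/max d_Y with Euclidean
distances; Y is the column-standardized (alcohol, wort) pair (class labels
are excluded from the distance; with no Y the procedure reduces to
Kennard–Stone). Ties break to the lowest sample index. On 336 samples the
2:1:1 protocol yields 168/84/84.

## VIP selection

VIP scores come from a mean-centered NIPALS PLS fit (scikit-learn);
per-component explained Y-variance is s_a = (tᵃ'tᵃ)(qᵃ'qᵃ), summed over
one-hot columns for classification. The LV count is chosen once per task by
MCCV/PRESS on the full spectrum and held fixed across the threshold sweep
(0.1–1.2 in steps of 0.1), which isolates the effect of wavelength
selection from model complexity. Thresholds retaining zero wavelengths are
recorded as invalid; criterion ties resolve to the larger threshold
(parsimony).

## Deep feature extractors

All three architectures end in the same block: linear projection of the
sequence to 20 dimensions, scaled dot-product self-attention with 2 heads
of 10 dimensions and a residual connection around the attention output
(no layer normalization — the narrow 20-dim channel trains stably without
it), flattening, and a fully connected *feature layer* of configurable
width whose activations are the exported features. Heads are linear
(regression, MSE on min-max-scaled targets) and 3-way softmax
(cross-entropy).

Sequence construction per architecture: `cnn_mha` concatenates three
parallel same-padded 1-D convolution branches (small/medium/large kernels,
shared filter count, ReLU); `lstm_mha` feeds the raw spectrum as a
228-step scalar sequence to an LSTM returning full sequences;
`cnn_lstm_mha` feeds the concatenated convolution feature maps as a
228-step sequence of (3 × filters)-dimensional vectors, preserving
wavelength order.

Optimization: Adam (β = 0.9/0.999), coupled L2 from the
`l2_regularization` hyperparameter, global gradient-norm clipping at 1.0,
mini-batches (default 32; 16 in the reduced pipeline, where the small
calibration set otherwise yields too few updates per epoch), and for
LSTM-bearing architectures a piecewise learning-rate schedule dropping by
`learn_rate_drop_factor` every 50 epochs plus dropout on the LSTM output
sequence. The plain convolutional network uses a constant rate and no
dropout. Inputs are standardized per wavelength on calibration statistics
(the informative band variation is a few percent of the water background;
without this the networks collapse to majority-class behavior), and
regression targets are min-max scaled to [0, 1]; both scalers are stored in
the trained extractor and inverted for reporting.

Initialization is Glorot-uniform from per-module seeded streams, so the
shared trunk draws identical weights whether one or three heads exist.
Together with the rule that tasks with weight exactly zero drop out of the
loss, multi-task training at a simplex vertex reproduces the corresponding
single-task run bit for bit — a structural identity the tests assert.

The networks run on a small in-package reverse-mode autodiff engine
(float32) with fused LSTM and attention nodes whose backward passes are
closed-form; a finite-difference gradient check in the test suite validates
every operator.

## Bayesian joint optimization

Fitness is cross-validated: pooled RMSECV on scaled targets or pooled CVER
(stratified folds for classification and MTL), and for MTL the weighted
joint error with normalization factors from single-task benchmarks. In the
pipeline the norms default to the single-task cross-validated fitness of
the default configuration (a full per-task hyperparameter search is
supported but triples the cost); classification norms are floored at one
CV miss (1/n) because CVER can legitimately reach zero on separable
classes. A diverged fold returns an infinite sentinel; such points enter
the surrogate with a penalty of 10 × the worst finite observation.

The optimizer is a Matern-5/2 Gaussian process (scikit-learn) over a unit
cube: integers round after acquisition, learning rate and L2 are
log-scaled, and the task-weight simplex is one categorical dimension over
the 36 grid points with 0.1 resolution and a 0.1 floor (observed optima lie
on this grid; a continuous simplex inside a GP is fragile). Initialization
uses scrambled Sobol points (default 8; 5 in the reduced pipeline),
acquisition is expected improvement maximized over 1024 random candidates.
Search ranges: kernels 2–5/6–12/15–25, filters 8–32, hidden units 32–160,
feature width 20–200, learning rate 1e-3–0.1 (log), L2 1e-10–1e-4 (log),
drop factor 0.2–0.9, dropout 0.1–0.3. The reduced space used by the default
pipeline narrows the capacity ranges (filters ≤ 16, hidden units 16–48,
feature width ≤ 80) and the learning rate to 1e-3–0.03 so that 15-epoch
fitness evaluations remain informative.

## Downstream models

PLSR is mean-centered NIPALS; the LV count is selected by Monte Carlo CV
(default 100 splits, 25% holdout; fewer in the pipeline) under minimum mean
PRESS with ties toward fewer LVs, computing all truncated-LV coefficient
matrices from a single fit per split. PLS-DA regresses the one-hot class
matrix and predicts the argmax column (ties to the lowest class index);
constant feature columns are tolerated and the LV count is capped at the
effective rank. SVR is RBF with features and target standardized on
calibration statistics, ε = 0.01 on the scaled target, and an exhaustive
C × γ grid (C ∈ {0.1…1000}, γ ∈ {1e-3…10}) under seeded k-fold RMSECV,
ties to smallest C then γ.

After cross-validated model selection the chosen extractor is refit on the
full calibration set with twice the CV epoch budget: CV folds train on
two-thirds of the data and exist to rank configurations, while the final
model serves prediction.

## Metrics and inference

R² = 1 − SSres/SStot; RMSE in target units; rRMSE = 100·RMSE/mean of the
evaluated subset; RPD = sample sd of the subset's references divided by
RMSE (reported as +∞ when RMSE is exactly 0), so RPD = CV%/rRMSE% holds as
an internal identity. Classification reports accuracy, macro precision and
recall (the macro average pairs with macro F1), macro and count-weighted
F1, all in percent, with the 0-convention for empty denominators and a
flag for classes absent from the references. The consistency test is a
two-sided paired t-test of measured versus predicted values (critical
value: Student-t quantile at α = 0.05 with n−1 df, e.g. 1.989 at n = 84);
residual summaries report the extreme residuals and the percentage within
a ± threshold, with no distributional band fitted.

## Problem sizes and determinism

The default pipeline (and the acceptance script) runs the reduced-scale
configuration: 336 simulated samples, 10 Bayesian-optimization iterations
with 3-fold fitness and 15 training epochs, SVR grid at 5-fold CV and
MCCV with 30 splits — a few minutes on one CPU; full-scale settings
(50 iterations, 10-fold, 150 epochs) are plain configuration changes. All
randomness flows from one global seed expanded per stage by a fixed affine
scheme recorded in the run manifest; every fold, initialization and shuffle
derives its own stream from it, so reruns are bit-identical.

## Known limitations

* The generator's band library is stylized; absolute absorbance levels and
  band shapes are only qualitatively beer-like, and no claim transfers to
  real spectra without revalidation.
* The Table-like wort rRMSE/RPD identities from the original study's data
  are not internally consistent with its printed subset statistics; the
  package asserts only the self-consistent alcohol block.
* CVER-based fitness saturates at zero on cleanly separable synthetic
  classes, so under MTL the classification term mostly constrains the
  search away from degenerate configurations rather than discriminating
  among good ones.
* The attention block's residual placement and the learning-rate drop
  period are design choices; alternatives (pre-norm attention, cosine
  schedules) were not explored.
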