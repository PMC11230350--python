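# Methods

## Model

Let `x_{1:T} ∈ R^{N×T}` be one subject's multivariate component timecourses
(e.g. N = 53 NeuroMark ICA components).  The timeseries is cut into
overlapping windows `x_wj` of W = 30 timesteps (stride 1 by default).  Two
encoders act on each window:

* a **context encoder** `φ_context(x_wj) → q(z_c)` mapping the whole window
  to the posterior of a single *context* latent (the slow timescale), and
* a **local encoder** `φ_local(·) → q(z_t)` mapping each timestep to the
  posterior of a per-timestep *local* latent (the fast timescale).

In the **DSVAE** the local encoder input is the timestep concatenated with
the window's context vector `[x_t ; z_c]`; in the **IDSVAE** (independent /
factorized variant) it is `x_t` alone — this is the only difference between
the two.  An MLP decoder `ψ(z_c, z_t)` reconstructs each timestep from the
pair of latents.  Training minimises the negative evidence lower bound per
window

```
L = (1/W) Σ_t ½‖x_t − ψ(z_c, z_t)‖²           (Gaussian likelihood, unit variance)
  + β (1/W) Σ_t KL(q(z_t) ‖ N(0, I))
  + γ        KL(q(z_c) ‖ N(0, I))
```

averaged over the window batch.  The fixed-unit-variance Gaussian likelihood
makes the reconstruction term ½·MSE (additive constants dropped), so model
selection by validation MSE is consistent with the training objective.

Baselines: **LVAE** removes the context pathway entirely (decoder sees `z_t`
only) and defines a window's context embedding as the time-average of its
local posterior means — an exact identity in the implementation, not an
approximation.  **CO** is a deterministic context-only convolutional
autoencoder (two strided 1-D convolutions over time, a dense bottleneck of
size CS, mirrored transposed-convolution decoder), trained on plain MSE.
**wFNC** is the windowed functional-network-connectivity baseline: the
vectorized upper triangle of each window's Pearson correlation matrix,
embedded by PCA (fit on train+val only) to the size matched with the latent
model being compared.

### Architectural choices

The encoders' internal architecture is a design choice of this package: the
context encoder is an MLP on the flattened `N·W` window, the local encoder a
per-timestep MLP, the decoder an MLP on `[z_c ; z_t]`; default widths
(128, 128).  Networks are implemented directly in numpy with explicit
forward/backward passes (Adam optimiser, lr 1e-3); every layer's analytic
gradient is validated against central finite differences in the test suite,
as is the full model loss including the reparameterization path.  Log
variances are clamped to [−8, 8] as a numerical guard.  During training the
local encoder of the DSVAE receives a reparameterized *sample* of `z_c`; at
inference all embeddings are posterior means, so encoding is deterministic —
a requirement for the reliability analysis.  Training keeps the weights of
the best-validation-MSE epoch.  All randomness (initialisation, shuffling,
sampling) flows from the single model seed; training is bit-reproducible for
a fixed seed.  The study's seed set is {42, 1337, 1212, 9999}.  A small
built-in random search (`random_search`) samples hyperparameters uniformly /
log-uniformly and selects by validation MSE.

## Evaluation suite

* **Window classification.** A linear SVM (C = 1, features standardized on
  train+val) separates patient from control *windows* using context
  embeddings; accuracy is computed on windows of held-out subjects.  Splits
  are always at the subject level (60/20/20, stratified by diagnosis) —
  window-level leakage is structurally impossible and asserted.
* **Cross-seed reliability.** For each ordered pair of training seeds, an
  ordinary least-squares map (with intercept) predicts one seed's context
  embeddings from another's on the same train+val windows; R² is averaged
  uniformly over output dimensions, then over all ordered pairs.  R² = 1
  exactly for affinely equivalent spaces.
* **Manifold comparison.** Euclidean distances between sampled window pairs
  (default 10⁵ pairs, seeded, sampled without replacement — the full distance
  matrix is infeasible at stride 1) are computed in the latent space and in
  the wFNC space, each standardized, and a simple linear regression predicts
  latent distances from wFNC distances.  Low R² means the latent geometry is
  not reducible to connectivity geometry.
* **Step distances.** Per subject, local embeddings are taken along
  *non-overlapping* windows (stride = W) so each timestep appears exactly
  once; the statistic is the mean Euclidean distance between consecutive
  timesteps.  The SZ−HC difference in subject means is tested by permuting
  subject labels (default 10 000 permutations, or exhaustively for tiny
  cohorts) and reporting `z = (observed − null mean)/null sd`.
* **Cluster analysis.** Patient windows' context embeddings are clustered
  with seeded k-means (k = 3, k-means++ init, 10 restarts).  Per-subject
  dwell counts (windows per cluster) proxy time in each state.  Cluster
  membership ("has any window in the cluster", i.e. dwell > 0) is tested
  against age and cognition score with Welch's two-sided t-test; dwell counts
  are correlated (Pearson) with the same covariates.  Each cluster is
  visualized as its mean wFNC minus the overall patient mean; the
  size-weighted average of cluster means reconstructs the overall mean
  exactly (tested).

Statistical choices: Welch's t-test rather than Student's (robustness to
unequal variances); reliability regressions include an intercept; multi-
output R² is the uniform average over dimensions.

## Synthetic cohort generator

Real cohorts of this kind are access-controlled, so the package ships a
generator with the two-timescale structure the model assumes and known
ground truth:

* **Context:** time is segmented into consecutive length-W blocks; each block
  draws one true context vector.  Controls draw from a single Gaussian mode
  at the origin (sd 0.5).  Patients draw from a mixture of 3 modes placed on
  *one side* of the control mode at graded distances — the most separated
  mode at distance `context_mode_separation` (default 3.0), later modes
  progressively closer, fanned at ±40° — forming a gradient from control-like
  to fully separated states.  The most separated mode is the *designated*
  mode: its mixture logit increases with the subject's age and decreases with
  the cognition score, so older / lower-scoring patients occupy it more.
* **Local:** a stationary AR(1) process `z_{t+1} = √(1−s²) z_t + s ε` with
  unit marginal variance and group-specific innovation scale `s`
  (controls 1.0, patients 0.6).  This is a standardized random walk in the
  small-step limit; its mean consecutive step distance is strictly monotone
  in `s`, so the patient group's reduced dynamic range holds by construction.
  A literal random walk divided by its empirical segment sd would cancel `s`
  from the step sizes entirely, which is why the stationary form is used.
* **Observation:** `x_t = tanh(A u_t) + B u_t + ε`, `u_t = [c ; z_t]`, with
  mixing matrices drawn once from `mixing_seed` and observation noise
  sd 0.1.  The tanh term guarantees the linear wFNC baseline cannot capture
  everything.  Separate mixing and cohort seeds let one "brain" generate
  independent cohorts.
* **Demographics:** ages uniform on 18–65; cognition scores Gaussian with
  group means/sds −1.6 ± 1.2 (patients) and 0.0 ± 0.9 (controls), matching
  the demographic profile the generator emulates.

Context changes per non-overlapping block while analysis windows overlap, so
windows near block boundaries see context mixtures — deliberate temporal
blur.  What the generator does **not** emulate: hemodynamic-response
convolution, physiological noise spectra, site effects, motion artefacts,
or realistic spatial covariance of ICA components.  Passing recovery tests
therefore demonstrate that the estimation machinery recovers planted
two-timescale structure at realistic sample sizes, not that equivalent
effects exist in any particular real cohort.

## Recovery experiment (tests and `scripts/acceptance.py`)

Problem sizes are chosen for a single CPU: 20 subjects per group, N = 20
channels, T = 150 timesteps, W = 30 (5 context blocks/subject, 121 windows
per subject at stride 1), 50 training epochs, seeds {42, 1337, 1212}.
Windows enter the models at the generator's native scale: the synthetic
channels are standardized by construction (unit-variance latents, bounded
tanh, fixed mixing), and per-subject z-scoring — the default for loaded real
cohorts, whose export scale is arbitrary — would remove the subject-level
component of the planted context signal that the recovery experiment is
designed to detect.

The null calibration of the permutation statistic uses cohorts with fully
*exchangeable* groups: equal local step scales **and** zero context-mode
separation.  Equalizing the step scales alone is not a null here — the
patient context modes sit away from the origin, and the tanh observation
converts that offset into a genuine group difference in observed local
dynamics, which the statistic correctly detects (every such run produced
|z| ≥ 2).  One model is trained on a null cohort and then encodes 20
independently drawn null cohorts, computing the permutation z for each;
retraining 20 separate models would test the same null at ~20× the cost.

## Degenerate inputs and numerical conventions

Zero-variance channels are rejected by name in z-scoring and wFNC (the
statistics are undefined); non-finite values are rejected at load time with
their position; a non-finite training loss raises a divergence error naming
the epoch; the upper-triangle vectorization order is row-major `i < j` with
an exact devectorization inverse; windows are half-open `[start, start+W)`
with 0-based timesteps; subject splits are deterministic given `split_seed`.

## Known limitations

* Full-gradient numpy training is practical at desk scale but slow for
  cohorts of hundreds of subjects at stride 1; no GPU path is provided.
* The CO baseline follows the convolutional encoder/decoder design loosely
  (3-layer stride-2 stack); it is not a reimplementation of any specific
  published architecture's hyperparameters.
* k = 3 is fixed by design, mirroring the visual choice in the analysis the
  package implements; no formal model selection for k is provided.
* The default experiment grid (DSVAE/IDSVAE over LS, CS ∈ {2,4,8}, plus
  LVAE/CO) at 4 seeds and 200 epochs is the full study configuration and is
  expensive on one CPU; the recovery experiment above uses the reduced sizes
  stated there.
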