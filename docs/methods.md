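# Methods

## Data model and notation

The package operates on trial-resolved firing-rate tensors
`x[n, s, d, t, k]` (spikes/s) for `N` neurons, `S` stimuli, `Q` decisions,
`T` time bins and up to `K` trials per condition, with unequal trial counts
`K_nsd >= 1` stored alongside (missing slots are NaN-padded). Every
combination of stimulus and decision must be present for every neuron; this
is a hard requirement of the non-parametric marginalization and is validated
at construction. Trial averaging yields the PSTH tensor `x̄[n, s, d, t]`,
centered per neuron (the removed means are kept so single trials can be
centered consistently).

All four datasets the method is designed around are *sequentially* recorded:
no two neurons share a trial, so single-trial population vectors are
"pseudo-trials" assembled by drawing one trial per neuron per condition, and
the noise covariance across neurons is not estimable — a diagonal noise
covariance (per-neuron variances) is the default throughout.

## Preprocessing

Spike trains are converted to instantaneous rates by convolution with a
Gaussian kernel (default SD 50 ms) sampled on a regular grid (default
100 Hz, bin centers, t = 0 at the first alignment event). The kernel is
truncated at ±4σ with the tail mass ignored, and edge bins are *not*
renormalized — the simple, deterministic choice; a trace of k spikes away
from the window edges integrates to k.

For self-paced tasks the trials are aligned by piecewise-linear time
warping: reference event times are the medians of the per-trial event times
(the reward event's median over correct trials only; error trials lacking a
reward event get a synthetic one at `t_prev + ΔT`, with ΔT the task's
minimal reward waiting time), and each trial's rate trace is resampled so
that its events land on the reference events. Smoothing is applied before
warping — warping is defined on the instantaneous rate.

## Marginalization

For the parameter set Ψ (here {s, d, t}; the implementation is generic in
Ψ), every non-empty subset ψ ⊆ Ψ has a term

    x̄_ψ = <x>_{Ψ∖ψ} − Σ_{τ⊂ψ} x̄_τ ,

computed iteratively over subsets in order of size (equivalent to the
alternating-sign closed form, which the test suite uses as an independent
oracle). These terms average to zero over any of their own parameters and
are pairwise uncorrelated, so both the data and the covariance split
additively. Terms are then grouped: each purely-conditional term is folded
into its condition × time interaction (`st = s + st`, etc.), because every
neural component is expected to vary in time. The grouping is a
user-suppliable partition of the non-empty subsets, validated to cover each
exactly once; for more than three parameters no canonical grouping is
imposed.

All covariances use the common denominator (the total number of sample
points), not per-term degrees of freedom — otherwise the additive split
would not hold.

Unbalanced trial counts break the per-trial decomposition (the package's
2×2 toy generator demonstrates the induced spurious pooled correlation), so
unbalanced data are routed through the PSTH formulation with a *re-balanced*
noise covariance: the unweighted average over conditions (and time) of the
per-condition covariance of trial residuals, with population denominator
`K_nsd`. This estimate is exactly invariant to replicating any condition's
trials.

## Core fit

Per marginalization φ the loss is a regularized reduced-rank regression

    L_φ = ||X_φ − F D X||² + SQT·||F D C_noise^{1/2}||² + μ||F D||²,

solved in three steps: the full-rank ridge solution
`A = X_φ Xᵀ (X Xᵀ + SQT·C_noise + μI)⁻¹`, PCA of `A X` to get the leading
left singular vectors `U_q`, then `F = U_q`, `D = U_qᵀ A`. The inverse is
computed by symmetric eigen-decomposition with a relative eigenvalue cutoff
of 1e-12 (a pseudo-inverse), since `X Xᵀ` is rank-deficient whenever
N > SQT. The ridge is parametrized as `μ = (λ||X||)²` so λ is comparable
across datasets.

Conventions chosen where the mathematics leaves freedom:

* **Sign**: each (f, d) pair is flipped so the encoder coefficient of
  largest magnitude is positive, making fits reproducible.
* **Ordering**: components are ordered globally by the variance of their
  decoder projection `||d X||²`, but keep their marginalization label.
* **Nestedness** holds by construction: pair *i* is `(u_i, u_iᵀ A)`
  regardless of q.
* **Degenerate spectra**: tied singular values make individual axes
  non-unique; only subspaces are then well-defined (and only subspaces are
  asserted in such tests). A rank-deficient solution with q above the rank
  yields zero-variance trailing components with a warning; the zero-variance
  threshold is 1e-12 relative.

## Regularization selection

λ is selected by repeated hold-one-trial-per-condition cross-validation:
one random trial per neuron per condition forms S·Q test pseudo-trials, the
rest give the training PSTHs and a freshly estimated training noise
covariance (re-estimated per split to avoid leakage). The criterion

    L_CV(λ) = Σ_φ ||X_train,φ − F_φ D_φ X_test||² / ||X_train||²

applies training decoders to *test* data against *training* targets; the
direction is deliberately asymmetric. Defaults: 10 components per
marginalization, 10 repetitions, 30 log-spaced λ between 1e-7 and 1e-3 (the
range is standard; the density is a package choice). Ties in the argmin are
broken toward smaller λ (the weaker prior). As λ → ∞ the map shrinks to
zero and L_CV → 1 by norm additivity. With diagonal noise covariances
regularization typically has little influence, so no particular optimum is
asserted for realistic data.

## Evaluation

* **Explained variance**: `R² = 1 − ||X − FDX||²/||X||²` per component,
  cumulatively for stacked components, and split additively across
  marginalizations (the split is exact because the marginalizations are
  uncorrelated). Arbitrary component matrices Z are scored by regressing the
  data onto them (`B = X Zᵀ(Z Zᵀ)⁻¹`).
* **Signal variance**: finite trials leave residual noise in the PSTHs;
  its total sum of squares is estimated as `Θ = SQT·Σ_n C_nn/K̄_n` and split
  over marginalizations proportionally to their degrees of freedom
  (T−1, ST−T, QT−T, SQT−ST−QT+T; summing to SQT−1). The per-marginalization
  signal pie `(||X_φ||² − Θ_φ)/(||X||² − Θ)` is displayed as integer
  percentages via largest-remainder rounding. A negative estimated signal
  fraction (tiny-data pathology) is clipped to 0 with a warning.
* **Demixing index**: `max_φ ||d X_φ||²/||d X||²`, ranging from 1/L to 1
  for L marginalizations.
* **Axis angles**: two encoder axes are flagged significantly
  non-orthogonal when `|f₁·f₂| > 3.3/√N` (the p < 0.001 bound for random
  directions on the N-sphere) *and* the Kendall correlation between their
  coordinates is significant at p < 0.001 (guarding against a few outlying
  neurons); the Kendall p-value uses the exact distribution for small N and
  the normal approximation otherwise (scipy's default switch at n = 50).
  Below N ≈ 12 the threshold exceeds 0.95 and a warning marks the test as
  near-vacuous.
* **Classification significance**: stratified Monte Carlo leave-group-out
  CV; each iteration refits the model on the training split and classifies
  each of the S·Q test pseudo-trials at every time bin by the nearest class
  mean along each of the first three stimulus/decision/interaction decoder
  axes. The null distribution comes from within-neuron trial shuffles that
  preserve per-condition counts, each evaluated with the same CV procedure.
  A bin is significant when the actual accuracy *strictly exceeds every*
  shuffle accuracy for at least 10 consecutive bins of the analysis grid.
  The standard setting of 100 CV iterations × 100 shuffles is expensive
  (each shuffle runs the full CV); both are configurable downward with a
  warning.
* **Encoder-weight diagnostics**: neurons as points in the space of the
  leading 15 encoder weights; density-peaks statistics with a Gaussian
  kernel of variance 0.01 (density = kernel sum over other points; delta =
  distance to the nearest denser point, the global mode taking the distance
  to the furthest point, density ties broken by index). One joint
  (density, delta) outlier indicates a single cluster, i.e. no discrete
  sub-populations.

## Baselines

PCA; per-marginalization PCA with pseudo-inverse decoders (stacked top-k
axes, default k = 10; k too small leaves leakage from unmodelled latents,
k too large overfits); targeted dimensionality reduction (per-neuron
per-time regression on stimulus, decision and their product, beta vectors
denoised by a 20-PC projector, per-parameter axis at the time of maximal
norm — first maximum on ties — stacked in a required, dataset-specific
order with the condition-independent axis always last, then
QR-orthogonalized); factorial LDA (per-marginalization generalized
eigenproblem `C_{-φ}⁻¹C_φ`; the dPCA decoders correspond instead to
eigenvectors of `C⁻¹C_φ²`, which is verified as a cross-check of the core
solver); difference-of-covariances axes (eigenvectors of `C_φ1 − C_φ2`);
and classical per-neuron two-way ANOVA with signed partial-ω² effect sizes
and sign-flipped population averages. Balanced ANOVA designs use the direct
sums-of-squares decomposition; unbalanced designs use Type-II sums of
squares from nested effect-coded regressions.

## Synthetic data

The generator emulates the structure of sequentially recorded prefrontal
datasets: rates are sums of label-specific latents times unit-norm random
encoding vectors plus i.i.d. Gaussian noise,
`x_n(t,s,d,k) = Σ_j w_nj z_j(t,s,d) + ε`. Latent time courses default to
Gaussian bumps and ramps; stimulus and decision modulations are linear
across levels, interactions random. Each raw latent is projected exactly
onto its marginalization subspace, so at zero noise the decomposition
recovers the latents to machine precision. SNR is defined as total latent
variance over expected PSTH noise variance after K-trial averaging, and
the default conditions (N = 100, S = 4, Q = 2, T = 50, K = 10, SNR 1)
represent a realistically sized sequential recording at moderate noise.

What the generator deliberately does *not* emulate: Poisson spiking
statistics (the loss is squared-error, so Gaussian additive noise matches
the model's own assumptions), noise correlations between neurons (absent in
sequential recordings by construction), non-stationary baselines, and the
specific task structure of any experiment. Tests passing on this generator
therefore validate the algebra and the statistical machinery, not
robustness to non-Gaussian firing statistics.

Two focused generators reproduce known failure modes: a 2×2 additive toy
where unbalanced trial counts (10 vs 100) induce a strong spurious pooled
correlation between two per-condition-uncorrelated neurons (the exact value
depends on the chosen effect sizes; the defaults give ≈ 0.8), and a
temporally jittered population `y_n(t) = a_n z(t + τ_n)` whose second
principal component approximates the waveform's derivative — the
derivative-artifact mechanism of pooling non-simultaneous recordings.

## Problem sizes used in tests

The test suite and the acceptance script run at desk scale: populations of
10–100 neurons, 2–4 stimuli, 2–3 decisions, 10–50 time bins, and reduced
Monte-Carlo settings for the classification null (20 CV iterations × 20
shuffles over 20 seeds, versus the standard 100 × 100). These sizes were
chosen so the full ground-truth recovery sweep and the family-wise
false-positive check remain cheap to rerun while still exercising the
N ≫ conditions and N < conditions regimes.

## Known limitations

Only discrete task parameters; every parameter combination must be present
(no missing-condition imputation). Components within a marginalization are
mutually orthogonal, which can make higher components hard to interpret.
Non-demixable data — overlapping high-variance subspaces of different
marginalizations — yield components with low demixing indices rather than
an error. The full (non-diagonal) noise covariance is only available for
simultaneously recorded data with shared trial counts.
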