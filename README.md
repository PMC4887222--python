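# dpca

Demixed principal component analysis (dPCA) for multi-condition neural
population recordings, with preprocessing, model selection, evaluation,
comparison baselines, a synthetic-population generator, and a command-line
interface.

## The problem

Neurons in higher cortical areas show *mixed selectivity*: a single cell's
firing rate depends simultaneously on several task parameters (the stimulus,
the animal's decision, and time within the trial). Classical PCA summarizes
such recordings compactly but returns components that mix all parameters;
per-parameter methods (ANOVA cell counting, targeted regression axes, LDA)
demix but discard most of the population variance. dPCA does both: it finds
linear readouts of the population that each carry variance from a *single*
task parameter while still reconstructing the data almost as well as PCA.

## The method

Let `X` be the `N x SQT` matrix of trial-averaged, per-neuron-centered
firing rates (PSTHs) of `N` neurons over `S` stimuli, `Q` decisions and `T`
time bins. An ANOVA-style marginalization splits `X` additively into
pairwise-uncorrelated parts

    X = X_t + X_st + X_dt + X_sdt        (+ X_noise for single trials),

the condition-independent, stimulus, decision and interaction terms, and the
covariance splits accordingly: `C = Σ_φ C_φ (+ C_noise)`. For each
marginalization φ, dPCA finds a decoder `D_φ` (q x N) and an encoder `F_φ`
(N x q, orthonormal columns) minimizing the regularized reduced-rank loss

    L_φ = ||X_φ − F_φ D_φ X||² + SQT·||F_φ D_φ C_noise^{1/2}||² + μ||F_φ D_φ||²

with `μ = (λ||X||)²`. The solution is analytic: the full-rank ridge solution
is `A = X_φ Xᵀ (X Xᵀ + SQT·C_noise + μI)⁻¹`, and with `U_q` the leading left
singular vectors of `A X`, `F = U_q` and `D = U_qᵀ A`. Decoder/encoder pairs
are nested (pair *i* does not depend on how many pairs are extracted).
λ is chosen by cross-validation that holds out one trial per neuron per
condition as pseudo-trials. Components are scored by explained variance,
by the *demixing index* `max_φ ||d X_φ||² / ||d X||²` (1 = perfectly
demixed), and by time-resolved decoder classification with a
trial-shuffle null.

## Worked example

```python
import numpy as np
import dpca

# synthetic population: 100 neurons, 4 stimuli x 2 decisions, 50 time
# bins, 10 trials per condition, SNR 1, one latent per marginalization
data, truth = dpca.generate_population(N=100, S=4, Q=2, T=50, K=10,
                                       snr=1.0, seed=1)

psth = dpca.compute_psths(data, center=True)
noise = dpca.estimate_noise_covariance(data)      # diagonal, re-balanced
mset = dpca.decompose(psth)                       # {t, st, dt, sdt}
model = dpca.fit(psth, mset, noise=noise, q_per_label=3)

report = dpca.explained_variance(model, psth, mset)
sig = dpca.signal_variance(noise, psth, mset)
F, D, order = model.stacked()

print(f"total R^2 of {model.n_components} components: {report.total_r2:.3f}")
print(f"signal fraction of PSTH variance: {sig.signal_fraction:.3f}")
print(f"variance pie over marginalizations: {sig.pie_percent}")
for rank in range(4):
    lab, i = order[rank]
    dmx = dpca.demixing_index(D[rank], mset)
    print(f"component #{rank+1}: label={lab:3s}  "
          f"R^2={report.component_r2[rank]:.3f}  demixing index={dmx:.3f}")
```

prints

```
total R^2 of 12 components: 0.493
signal fraction of PSTH variance: 0.551
variance pie over marginalizations: {'t': 15, 'st': 34, 'dt': 41, 'sdt': 10}
component #1: label=dt   R^2=0.215  demixing index=0.983
component #2: label=st   R^2=0.168  demixing index=0.983
component #3: label=t    R^2=0.070  demixing index=0.946
component #4: label=sdt  R^2=0.031  demixing index=0.922
```

The 12 components capture 49% of the PSTH variance — about all of it that is
signal rather than finite-trial noise (signal fraction 0.55) — and every
leading component is demixed (index > 0.9), one per marginalization. The pie
gives the integer percentages of signal variance per marginalization
(largest-remainder rounding, summing to 100). Matching fitted components to
the generator's ground-truth latents gives |r| ≈ 0.93–0.99 per
marginalization at this noise level.

The same workflow is available from the shell:

```
dpca simulate --preset basic --seed 1 --out data.h5
dpca crossval data.h5 --grid 1e-7:1e-3:30 --reps 10 --seed 1 --out cv.csv
dpca fit data.h5 --q 10 --lam 1e-5 --out model.h5
dpca evaluate data.h5 model.h5 --out reports/
dpca report --input simulate:basic --out run/ --seed 1
```

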