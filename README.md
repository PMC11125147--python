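# begp

Personalized diurnal heart-rate baselines from noisy wearable data, with
Bayesian calibration.

Wrist-worn PPG sensors make continuous heart-rate monitoring cheap and
unobtrusive, but the data they produce are rough: motion artifacts inject
large transient errors, and whole stretches of the day go missing when the
device is charging or not worn. `begp` is for analysts of such longitudinal
wearable data — e.g. remote monitoring of older adults — who need a clean,
personalized estimate of a subject's diurnal HR pattern, with honest
uncertainty, from a couple of weeks of messy history.

## The model

A day's HR trace is a smooth latent curve observed with noise:

    y_ij = x_i(t_ij) + eps_ij,        eps_ij ~ iid N(0, sigma^2)
    x_i(t) = Phi(t)' C_i,             Phi(t) = (phi_1(t), ..., phi_P(t))'

where the `phi_p` are P cubic B-splines on [0, 24] hours (default P = 13),
and the day's coefficient vector varies around a subject-level mean,
`C_i ~ N(C, Sigma_C)`. This is a Gaussian process whose mean and covariance
functions come from the basis expansion:

    x(t) ~ GP(mu, k),   mu(t) = Phi(t)' C,   k(t, tau) = Phi(t)' Sigma_C Phi(tau)

From M days of history the package estimates, in closed form: per-day
coefficients `C_i^ = (Phi Phi')^{-1} Phi Y_i` (ordinary least squares — the
smoothing itself is what suppresses artifacts), the pooled mean `C-bar`,
the noise variance `sigma^2^` from residuals and the hat-matrix trace, and
the debiased coefficient covariance

    Sigma_C^ = S_C - (sigma^2^ / M) * sum_i (Phi_i Phi_i')^{-1}

which subtracts the average least-squares estimation noise so that
`E[Sigma_C^] = Sigma_C`. That triple — mean curve, covariance function,
noise level — is the subject's **HR baseline**; its mean ± 3·sd band is the
subject's plausible HR range at each time of day.

Given a new day of measurements `Y*`, the baseline acts as a Gaussian prior
and the standard conjugate update gives calibrated coefficients and a
contracted covariance:

    C*      = C + Sigma_C Phi [Phi' Sigma_C Phi + sigma^2 I]^{-1} (Y* - Phi' C)
    Sigma*  = Sigma_C - Sigma_C Phi [Phi' Sigma_C Phi + sigma^2 I]^{-1} Phi' Sigma_C

The posterior GP `x*(t) ~ GP(Phi' C*, Phi' Sigma* Phi)` is a denoised,
gap-imputed version of the day — missing stretches are filled by the curve,
with a band that widens where the data ran out.

## Worked example

```python
import numpy as np
from begp import (SimConfig, build_basis, simulate_dataset, estimate_baseline,
                  calibrate, baseline_band, impute)

basis = build_basis(13, 4)                      # 13 cubic B-splines on [0, 24] h
sim = simulate_dataset(SimConfig(seed=7), basis)  # 15 days, gaps + artifacts

history, new_day = sim.days[:-1], sim.days[-1]
baseline = estimate_baseline(history, basis)
print(f"days used: {baseline.n_days}, noise sd: {np.sqrt(baseline.noise_var):.1f} bpm")

band = baseline_band(baseline, np.array([3.0, 14.0]))
print(f"baseline at 03:00  {band.mean[0]:.1f} bpm  (3-sigma {band.lower3[0]:.1f}-{band.upper3[0]:.1f})")
print(f"baseline at 14:00  {band.mean[1]:.1f} bpm  (3-sigma {band.lower3[1]:.1f}-{band.upper3[1]:.1f})")

post = calibrate(baseline, new_day)
grid = np.linspace(0.0, 24.0, 289)
curve = impute(post, grid)
truth = sim.truth(new_day.day_index, grid)
print(f"calibrated-curve RMSE vs truth: {np.sqrt(np.mean((curve.mean - truth)**2)):.2f} bpm")
```

prints

```
days used: 14, noise sd: 6.5 bpm
baseline at 03:00  58.8 bpm  (3-sigma 50.3-67.4)
baseline at 14:00  84.0 bpm  (3-sigma 79.5-88.5)
calibrated-curve RMSE vs truth: 0.59 bpm
```

The baseline shows the subject's diurnal swing (nocturnal trough near
59 bpm, afternoon peak near 84 bpm) with its regular-variation band. The
estimated noise sd (6.5 bpm) exceeds the generator's 3 bpm sensor noise
because motion-artifact shocks inflate the residuals — the homoscedastic
noise model absorbs them into `sigma^2^`. Calibrating with one day of
noisy, gappy data recovers that day's true curve to well under 1 bpm RMSE,
and the posterior band contracts relative to the baseline band wherever the
day supplied data.

The same pipeline is available from the shell:

```
begp simulate --out-dir data/ --seed 7 --subjects 3
begp fit-baseline --input data/S1/ppg.csv --subject S1 --out baseline.json
begp calibrate --baseline baseline.json --new-day newday.csv --out calibrated.csv
begp evaluate --data-dir data/ --out table.csv
```

`begp evaluate` scores five estimators of a held-out day against a paired
ground-truth sensor, leave-one-day-out: (A) the raw noisy sensor, (B) the
population mean across subjects, (C) the subject's scalar mean, (D) the
baseline functional mean, and (E) the calibrated functional mean. The
output table reports MSE (error SD) per subject and pooled.

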