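# kinrates

Reconstruction of dynamic microbial growth rates and gene-expression
(fluorescent-protein synthesis) rates from noisy plate-reader kinetics.

## Who this is for

Anyone characterizing promoters, transcription units or growth phenotypes
from 96-well kinetic assays: time series of optical density (biomass proxy)
and up to three fluorescence channels, sampled every 10–15 minutes over
~24 h, with media-blank and no-reporter control wells on the plate. The
quantities of interest are the specific growth rate μ(t) = d log B/dt and
the per-biomass protein synthesis rate φ(t) — *not* dy/dt or d(y/B)/dt,
which confound synthesis with dilution and degradation.

## The method

Measurements follow

    dB/dt = μ(t)·B,        dy/dt = B(t)·φ(t) − γ·y,

with γ the reporter degradation rate (0 for stable fluorescent proteins).
Rather than differentiating noisy data, the rate profile is expanded on a
Gaussian basis with spacing Δ (default 1 h, the timescale of protein
synthesis),

    f(t) = Σ_k w_k · exp(−(t − kΔ)² / (2Δ)),    w_k ≥ 0,

and the *forward* model is fitted to the raw background-corrected data by
bound-constrained trust-region least squares with a Tikhonov penalty:

    min_Θ ‖data − F(Θ)‖₂² + λ‖Θ‖₂²,    Θ = [B₀, ŵ] ≥ 0.

The biomass solution B₀·exp(∫μ) is closed-form through the error function;
the fluorescence model is driven by the measured biomass and is linear in
(y₀, ŵ). λ comes from an error-minimizing grid scan when the truth is known
(simulations) or from the L-curve corner on experimental data.

The two standard alternatives are implemented as baselines, weaknesses
intact: **direct** regularized linear inversion in the log domain
(hyperparameter: the "insignificant value" ε_L) and **indirect**
smooth-then-differentiate (Savitzky–Golay, or an anti-causal zero-phase
Butterworth filter at cutoff 4/33), which divides by smoothed biomass that
is small and possibly negative early in growth. A fully specified simulator
(Gompertz growth, smoothed lognormal random-walk expression profiles,
forward-Euler integration, multiplicative noise, background, control wells)
provides ground truth for benchmarking, and a plate pipeline handles I/O,
background correction, per-well fitting, growth-peak synchronization
(τ = t − t₀), z-normalization and ratiometric comparison against an in-vivo
reference transcription unit.

## Worked example

Simulate one well with a Gompertz growth truth (μ* = 0.8/h, 2 h lag,
B₀ = 0.01, 5% multiplicative measurement noise, background 0.1 OD),
background-correct it and reconstruct the growth rate:

```python
import numpy as np
import kinrates as kr

gp = kr.GompertzParams(mu_star=0.8, lag=2.0)
noise = kr.NoiseSpec(sigma=0.05)
well = kr.simulate_well(
    lambda t: kr.gompertz_growth_rate(gp, t),
    lambda t: np.zeros_like(np.asarray(t, float)),
    noise=noise, b0=float(kr.gompertz_biomass(gp, 0.0)), seed=7,
)
biomass, _ = well.corrected(noise)
result = kr.GrowthRateModel(biomass, delta=1.0).fit(lambda_reg=1e-3)
print(result.summary())
t_peak, mu_peak = result.peak()
```

prints

```
GrowthRate fit (inverse method, trust-region reflective)
========================================================
  observations      : 101
  basis functions   : 25  (Δ = 1 h)
  Tikhonov λ        : 0.001
  B0                : 0.00905511
  residual 2-norm   : 0.354013
  ‖Θ‖2              : 0.713871
  rate peak         : 0.8431 at t = 4.57 h
  converged         : True  (`ftol` termination condition is satisfied.)
```

The reconstructed initial biomass (0.0091 OD) and rate peak (0.84/h at
4.6 h) sit close to the truth: B₀ = 0.01, peak μ* = 0.8/h at
t = lag + A/(μ*·e) = 4.12 h. `result.rate(t)` evaluates μ(t) anywhere in the
window; `result.predict()` returns the fitted biomass curve.

Expression rates work the same way through `kr.ExpressionRateModel(fluor,
biomass, gamma=0.0).fit(...)`; plates go through `kr.read_plate_csv`,
`kr.subtract_background` and `kr.characterize_sample`, which returns
synchronized, z-normalized profiles ready for `kr.compare_to_reference`.

A CLI wraps the same functions:

```sh
kinrates simulate --n 10 --seed 1 --out plates/
kinrates fit --input od.csv --method inverse --lambda lcurve --out mu.csv
kinrates benchmark --task growth --n 100 --seed 1 --out bench/
kinrates characterize --input plate.csv --sample s1 --channel RFP --out prof.csv
kinrates compare --profile prof.csv --reference ref.csv
```

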