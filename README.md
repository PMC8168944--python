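# adcascade

Latent disease-progression modelling for Alzheimer's disease, and in-silico
simulation of amyloid-lowering intervention trials.

`adcascade` is aimed at researchers who study how multimodal biomarkers —
regional amyloid-PET load, FDG-PET glucose metabolism, MRI grey-matter
atrophy and neuropsychological scores — evolve jointly over the decades-long
history of the disease, and who want to ask *what-if* questions: if amyloid
accumulation were blocked (fully or partially) at a given number of years
before dementia diagnosis, how large would the clinical benefit be, and what
sample size would a trial need to detect it?

## The model

Each subject-visit provides blocks of measurements
`X(t) = [x_amy, x_met, x_atr, x_cli]`. Every block is mapped to a single
interpretable z-score, giving a 4-dimensional latent state
`z = (z_amy, z_met, z_atr, z_cli)` whose joint evolution follows a system of
coupled logistic ODEs:

    dz_m/dt = k_m z_m (1 - z_m) + Σ_{j≠m} α_{m,j} z_j
            ⇔  dz/dt = W z − V z²          (z² elementwise)

where `k_m` (1/year) is the progression rate of modality *m* and `α_{m,j}`
couples modality *j* into modality *m* — e.g. a positive `α_{met,amy}`
expresses amyloid driving metabolic decline (the amyloid-cascade
hypothesis). Observations are generated from the latent state through
per-modality monotone decoders with Gaussian noise:

    x_m | z ~ N(μ_m(z_m), σ_m² I)

All parameters — modality-wise encoders `f_m`, decoders `μ_m`, noise `σ_m²`
and the dynamics `W` — are estimated jointly from short, irregular,
partially missing longitudinal follow-up by stochastic variational
inference: encode each subject's baseline, integrate the ODE to every
follow-up time, score the reconstructions, and regularize the posterior.

On top of the fitted model the package provides:

- **Long-term trajectory** (`adcascade.longterm`): a Gaussian mixture
  (AIC-selected) over the AD subjects' latent states is extended backward
  and forward along the model's disease course, giving the mean ± sd
  reference trajectory anchored at conversion (t = 0).
- **Disease staging** (`adcascade.staging`): an individual's severity is the
  time-shift `τ = argmin_t Σ_m |f_m(x_m) − z̄_m(t)|`, computable from any
  subset of modalities; groups are compared with two-sided
  Wilcoxon–Mann–Whitney tests.
- **Trial simulation** (`adcascade.trials`): two-arm trials where the
  treated arm's vector field is damped by `Γ = diag(γ)` from the
  intervention time on (`γ_amy = 0` is 100% amyloid lowering, `0.5` is
  50%); endpoints are decoded clinical scores at conversion, compared by
  two-sided t-tests; power is estimated over Monte-Carlo trial replicates
  and mapped over intervention time × sample size × lowering rate.
- **Synthetic cohorts** (`adcascade.synthetic`): an ADNI-schema-like
  generator with known ground truth (time-shifts, latents, stage labels),
  so the whole pipeline is testable without access to controlled data.

## Worked example

```sh
adcascade simulate-data --seed 0 --n-subjects 300 --out work/data
adcascade fit        --cohort work/data/cohort.csv --out work/fit
adcascade trajectory --model work/fit/model.json --cohort work/data/cohort.csv --out work/traj
adcascade stage      --model work/fit/model.json --reference work/traj/reference.csv \
                     --cohort work/data/cohort.csv --out work/stage
adcascade power      --model work/fit/model.json --cohort work/data/cohort.csv \
                     --times -16,-12,-8,-4 --sizes 50,200 --gammas 0.0,0.5 --out work/power
```

The same pipeline through the Python API:

```python
import numpy as np
from adcascade import (canonical_config, generate, fit, TrainingConfig,
                       fit_mixture, sample_ensemble, build_reference, stage)

cohort, truth = generate(canonical_config(seed=0))
model = fit(cohort, TrainingConfig(epochs=2000, seed=0, encoder_squash="softplus"))

ad = [s for s in cohort if s.visits[0].diagnosis == "AD"]
mix = fit_mixture(model.baseline_latents(ad), rng=np.random.default_rng(0))
grid = np.arange(-30.0, 10.0, 0.1)
ref = build_reference(sample_ensemble(mix, 1000, model.dynamics, grid, rng=0),
                      ("threshold", "cli", 0.5), schema=model.schema)
tau = stage(cohort[0].visits[0].blocks, model, ref)
print(round(tau.tau, 1))
```

On the canonical synthetic cohort this prints a time-shift of `15.5` years
for the first subject — an AD-stage individual staged about 15 years past
the reference conversion point (the generating time-shift was 15.9 years).
Across the whole cohort the estimated time-shifts rank-correlate with the
generating ones at Spearman ρ ≈ 0.96–0.97, and the five clinical groups
(NL stable → NL converter → MCI stable → MCI converter → AD) have strictly
increasing median severity, every adjacent pair separated at P < 0.01
(rank-sum). Trial simulation on the same model shows the structure that
motivates early intervention: with 100 subjects per arm and the first
clinical endpoint at conversion, full amyloid blockage 16 years before
conversion is detected with power 1.0 (mean endpoint improvement 0.148),
50% blockage at the same time drops to power 0.49 (improvement 0.041), and
full blockage only 8 years before conversion is no longer detectable at
this sample size (power ≈ 0.01) — later intervention and weaker lowering
both erode the detectable benefit.

## Limitations

The rate/coupling decomposition of the dynamics is only weakly identified
from short follow-up windows: different (k, α) combinations explain such
data almost equally well, so point estimates of individual dynamics
parameters scatter across seeds even though the fitted trajectories,
staging and trial simulations are stable. See `docs/methods.md` for the
full analysis and for every numerical design choice.
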