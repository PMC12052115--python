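# covhawkes

Covariate-adjusted self-exciting (Hawkes) point process for recurrent
clinical events, built for recurrent opioid-overdose modeling: each person's
events both reflect their fixed risk profile and raise their own short-term
risk of further events.

## The model

For recipient *i* with static covariates *xᵢ* and past events
*tᵢ₁ < tᵢ₂ < …*, the conditional intensity (instantaneous event rate) is

```
λᵢ(t | Hᵢ(t)) = θ·t^(θ−1)·exp(αᵀxᵢ)  +  Σ_{j: tᵢⱼ < t} β·γ·exp(−γ·(t − tᵢⱼ))
```

* **Baseline** — a power-law time trend `θ·t^(θ−1)` (constant for θ = 1,
  decreasing for θ < 1, increasing for θ > 1) scaled log-linearly by
  dummy-encoded covariates, as in Cox-type regression.
* **Triggering** — every past event adds an excitation of total mass β
  (the branching ratio: expected directly-triggered events per event) that
  decays exponentially at rate γ per day.

The compensator Λᵢ(t) = ∫₀ᵗ λᵢ(u) du is available in closed form, so the
log-likelihood

```
ℓ(Θ) = Σᵢ [ Σⱼ log λᵢ(tᵢⱼ) − Λᵢ(Tᵢ) ],   Θ = {θ, α, β, γ}
```

is exact; it is maximized by L-BFGS-B under box constraints (θ, γ > 0,
β ≥ 0). The event risk by time *t* is 1 − exp(−Λᵢ(t)). Expected event
counts over a horizon decompose exactly into a baseline part and a
triggering part, which quantifies the share of events attributable to
event-to-event triggering. Homogeneous (HPP) and non-homogeneous (NHPP)
Poisson benchmarks — the model without triggering — share the same
fit/predict interface, and a replicated 80/20 train/test protocol compares
them by MAE and MAPE of predicted counts.

All estimators follow scikit-learn conventions (`fit`, `predict`,
`get_params`; fitted attributes end in `_`) and operate on a `Cohort` of
per-recipient event streams with administrative censoring.

## Worked example

```python
import numpy as np
from covhawkes import (TriggeringPointProcess, run_replications,
                       triggering_significance)
from covhawkes.simulate import SimConfig, simulate_cohort

cohort = simulate_cohort(SimConfig(n_recipients=500, obs_length=365.0,
                                   seed=42))
model = TriggeringPointProcess().fit(cohort)
p = model.params_
print(f"theta={p.theta:.3f}  beta={p.beta:.3f}  gamma={p.gamma:.3f}")
print(f"log-lik={model.log_lik_:.1f}  AIC={model.aic_:.1f}  "
      f"BIC={model.bic_:.1f}")

base, trig = model.predict_decomposed(cohort, 90.0)
total = base.sum() + trig.sum()
print(f"expected events in 90 d: {total:.1f} "
      f"(baseline {base.sum():.1f}, triggered {trig.sum():.1f}, "
      f"share {100*trig.sum()/total:.1f}%)")

report = run_replications(cohort, [30.0, 90.0, 180.0], n_reps=20, seed=0)
t, pval = triggering_significance(report.beta_hats)
print(f"beta t-test: t={t:.1f}, p={pval:.2e}")
```

Output:

```
theta=0.300  beta=0.506  gamma=0.101
log-lik=-24771.0  AIC=49570.1  BIC=49667.3
expected events in 90 d: 4833.9 (baseline 2488.0, triggered 2345.9, share 48.5%)
beta t-test: t=432.6, p=1.04e-39
```

The cohort was generated at θ = 0.3, β = 0.5, γ = 0.1; the fit recovers all
three. The 48.5% triggered share says roughly half of the expected events
are attributable to excitation by earlier events rather than to the
recipients' baseline risk, and the t-test across replicated refits shows
that the triggering magnitude is decisively nonzero.

The same workflows are available from the shell:

```
covhawkes simulate --n 500 --seed 42 --out cohort.csv
covhawkes fit --input cohort.csv --out fit.json
covhawkes evaluate --input cohort.csv --windows 30,60,90,120,150,180 \
    --n-reps 100 --out-dir eval/
covhawkes build-cohort --input raw_events.csv --study-start 2016-01-01 \
    --study-end 2018-12-31 --out cohort.csv
```

`build-cohort` applies the study's inclusion rules to raw dated event
records: the index date is set 90 days after the earliest event that
follows a 90-day observed-event-free run-in, people without a later event
are excluded (with a logged reason), and follow-up is censored at the study
end.

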