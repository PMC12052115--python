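# Methods

## Model

Each recipient *i* is observed over `[0, Tᵢ)` days from their index date
(t = 0), with administrative censoring at Tᵢ. The conditional intensity is

    λᵢ(t) = θ t^(θ−1) exp(αᵀxᵢ) + Σ_{tᵢⱼ<t} β γ e^(−γ(t−tᵢⱼ)).

Assumptions worth stating explicitly:

* **Static covariates.** xᵢ is fixed over follow-up. Treatment-type flags
  (e.g. withdrawal, medications for opioid use disorder) that in reality
  switch on and off are modeled as static indicators; a piecewise-constant
  covariate extension would change only the baseline compensator
  (a sum of power-law segments) but is not implemented.
* **Power-law baseline.** `λ₀(t) = θ t^(θ−1)` has no free scale parameter:
  the overall level is carried by θ (through `t^(θ−1)`) and by the
  covariate term. θ < 1 captures risk that is highest shortly after the
  index date and declines thereafter.
* **Exponential triggering kernel.** Each event contributes excitation of
  total mass β decaying at rate γ. β is the branching ratio: in the
  stationary regime a fraction β of events is triggered and 1 − β
  immigrant. β < 1 is required only for simulation (subcriticality);
  fitting does not impose it.
* **Events at the censoring boundary.** Events lie in `[0, Tᵢ)`
  (half-open). An event recorded exactly at t = 0 is shifted to 10⁻⁶ days
  with a warning, because the baseline is singular at 0 for θ < 1. Events
  exactly at t do not contribute to λ(t) (strict `tᵢⱼ < t`).

## Estimation

The compensator is closed-form,
`Λᵢ(t) = t^θ exp(αᵀxᵢ) + β Σ_{tᵢⱼ<t}(1 − e^(−γ(t−tᵢⱼ)))`,
so the log-likelihood needs no quadrature. The triggering sums
`Sⱼ = Σ_{k<j} e^(−γ(tⱼ−tₖ))` are computed from a precomputed
within-recipient pair table (vectorized; used when the cohort has at most
4×10⁶ pairs) or a per-recipient log-space prefix scan
(`logaddexp.accumulate`; O(n) per recipient, overflow-safe for γ·t up to
thousands). Both paths are algebraically identical and tested against each
other.

Optimization is L-BFGS-B on the natural scale with box constraints
θ ∈ [10⁻⁴, 10], β ∈ [0, 10], γ ∈ [10⁻⁴, 10] day⁻¹, α free; default start
θ = 1, α = 0, β = 0.1, γ = 0.1. The analytic score is the default gradient:
it is exact and roughly an order of magnitude faster than finite
differences, which matters for the 100-replication protocol; a numeric
gradient remains available (`gradient="numeric"`) and the two are tested to
agree. Optional seeded multi-starts guard against the likelihood's
non-convexity. A fit that fails to improve on its start is reported with
`converged=False`, never silently.

AIC = 2k − 2ℓ and BIC = k·ln(nₑ) − 2ℓ with k = 3 + p parameters and nₑ the
total event count across the cohort (each event contributes one likelihood
factor; recipients would be an equally defensible but different convention,
so the choice is documented here).

The NHPP benchmark is the same model with β pinned at 0 (γ then drops out
of the likelihood); the HPP rate is the closed-form events-per-person-time
estimate.

## Simulation

`simulate_recipient` draws from the exact law via the cluster
representation: immigrants from the inhomogeneous Poisson baseline by
inversion on the compensator scale, then each event spawns
Poisson(β(1 − e^(−γ(T−t)))) children with truncated-Exponential(γ) delays,
recursively. Offspring falling beyond T are discarded (right truncation,
matching censored observation). Every event keeps a generation label
(0 = immigrant), giving a ground truth for the triggered share that the
fitted decomposition is checked against. An independent Ogata thinning
sampler provides a distributional cross-check (it requires a bounded
baseline: θ ≥ 1 or an explicit bound).

Reproducibility: recipient *i*'s covariates and event stream come from
`SeedSequence(seed, spawn_key=(i,))`, so they are invariant to cohort size.

### Default synthetic study cohort

The default `SimConfig` emulates a state-Medicaid opioid-overdose cohort:
1,000 recipients followed 365 days; covariates sex (2 levels), age group
(4), race (4), rural/urban/mixed geography (3), and two binary treatment
flags, dummy-encoded against alphabetical reference levels with plausible
prevalences; generating parameters θ = 0.3, β = 0.5, γ = 0.1 day⁻¹ and
dummy effects |α| ≤ 0.3. Rationale: θ = 0.3 puts baseline risk highest just
after the index date with a few baseline events per follow-up year; β = 0.5
makes about half of events triggered, matching the triggered share this
kind of cohort exhibits; γ = 0.1 gives a 10-day mean excitation memory, so
most triggered recurrences arrive within a month. Under these conditions
the cohort averages ~14 events per recipient-year and ~85% of consecutive
inter-event gaps fall within 30 days — denser than a real claims cohort,
where coverage churn, unrecorded events and fatal overdoses thin the
streams. The simulator models none of those mechanisms (no absorbing
states, no missingness), so passing tests demonstrate correctness of the
method under its own assumptions, not robustness to real-data artifacts.

## Evaluation protocol

Replicated recipient-level 80/20 splits (train size = round(0.8·N); for
1,186 recipients that is 949/237), each fitting on the training recipients
and predicting expected counts on test recipients over windows
L ∈ {30, …, 180} days from each recipient's own t = 0. The predictor is the
plug-in conditional expectation: the test recipients' realized events
inside `[0, L)` feed the triggering term, so the prediction decomposes
exactly (bitwise) into baseline + triggering parts — the only reading under
which the triggered-share decomposition is closed-form. The alternative
(branching-expectation) predictor that integrates over unobserved future
offspring is deliberately not the default. Actual counts are events in
`[0, L) ∩ [0, Tᵢ)`. MAE and MAPE aggregate |m̂ʳ − mʳ| over replications;
replication r's split uses `SeedSequence(seed, spawn_key=(r,))`. Fit
failures are logged and excluded with a count, never silently dropped.

The significance of triggering is a one-sample, one-sided t-test of the
replication estimates β̂ʳ against 0 at α = 0.05, with a documented
degenerate branch when all β̂ʳ coincide.

## Numerical choices and edge cases

* Likelihood evaluations guard nothing hidden: λ at an event is strictly
  positive for θ > 0 and t > 0, so the log never sees 0.
* MAPE raises on a zero actual count rather than silently skipping;
  `run_replications` converts that case to NaN with a warning.
* Cohort CSVs are read with round-trip float parsing so write→read is
  bit-exact; XLSX round-trips to machine precision only.
* Cohort construction uses whole-day calendar arithmetic. The required
  90-day event-free run-in is evaluated against *observed* events only
  (history before the study window is unknowable), so the first recorded
  event always qualifies as the anchor. Follow-up ends at the end of the
  study-end day, i.e. `obs_length = (study_end − index) + 1` days, so an
  event on the final day lies inside `[0, T)`. Same-day duplicate records
  collapse to one event by default (switchable).

## Known limitations

* **The β̂ t-test is anti-conservative under the null.** β is a boundary
  parameter (β ≥ 0): with no true triggering its MLE is a mixture of a
  point mass at 0 and positive values, so replicate means are positive,
  and the replicates are correlated through overlapping splits of one
  cohort. The empirical type-I error at nominal 5% is measured at roughly
  40% (200 null cohorts) rather than 5%. The test is therefore evidence
  *for* triggering when the effect is large (its power at β = 0.5 is
  overwhelming, p < 10⁻³⁰), but a rejection near the threshold should not
  be read at face value; a likelihood-ratio test with a boundary-corrected
  (½χ²₀ + ½χ²₁) null would be the principled replacement.
* Near the null the pair (β, γ) is weakly identified: as γ → 0 only the
  product βγ matters, so on small cohorts β̂ alone can drift along that
  ridge. At the study scale (N = 1000, T = 365) the MLE pins β̂ ≈ 0 on
  null data.
* Time-rescaling diagnostics (Exp(1) gaps after mapping through Λ) are
  exact only up to an end-of-window truncation bias of order 1/(events per
  window); tests use long windows where the bias is negligible.
* Single-event recipients are excluded by the cohort rules, which biases
  who enters the cohort; the model makes no correction for that selection.
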