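# ttcjoint

Joint longitudinal–survival modelling of drug exposure and progression-free
survival, built for therapeutic drug monitoring (TDM) of oral targeted
anticancer agents such as the ALK inhibitor alectinib.

## The problem

In routine oncology care, plasma drug concentrations are sampled at clinic
visits over months of treatment.  Conventional exposure–response analyses
collapse this longitudinal record into a single number (e.g. each patient's
median trough concentration) and feed it to a Cox model — discarding dose
reductions, within-patient drift and measurement error.  Time-dependent Cox
models with last-value-carried-forward (LVCF) covariates help, but are known
to attenuate true associations when the covariate is measured with noise.

`ttcjoint` implements the joint-model alternative end to end:

1. **Trough extrapolation.**  Samples drawn mid-interval are decayed
   log-linearly to the next scheduled trough:
   `C_trough = C_obs · 2^(−Δ/t½)` with Δ the time remaining to the next
   intake (t½ = 32 h, 12 h dosing interval by default).
2. **Sigmoid (Emax) normalization.**  Troughs are mapped to a bounded
   0–100 scale, the *transformed trough concentration* (TTC):
   `TTC(C) = 100 · C^γ / (EC50^γ + C^γ)` with EC50 = 600 ng/mL and γ
   calibrated so the TTC sample is approximately Gaussian.
3. **Joint model.**  A linear mixed model for the TTC trajectory,
   `m_i(t) = β₀ + β₁ t + β_dose[level_i(t)] + b₀ᵢ + b₁ᵢ t`,
   shares its subject effects with a proportional-hazards event model

   `h_i(t) = h₀(t) · exp( φ′wᵢ + α_curr · m_i(t) + α_avg · (1/t)∫₀ᵗ m_i(s) ds )`

   where the association structure uses the current value, the running
   average, or both.  Estimation is by adaptive Metropolis-within-Gibbs with
   a piecewise-constant baseline hazard; structures are compared by WAIC and
   LPML.
4. **Baselines.**  Kaplan–Meier (with reverse-KM follow-up), standard Cox on
   median exposure (continuous TTC, or dichotomized at the 435 ng/mL trough
   target), and time-dependent Cox on LVCF counting-process rows — with an
   in-package Efron partial-likelihood Newton solver shared bitwise between
   the standard and time-dependent fits.
5. **Synthetic cohorts.**  A generator emulating the TDM study design
   (100 patients, ~5 samples each over 1–17, ~46% progression events,
   dose reductions, administrative censoring) with known ground truth, so
   recovery of every parameter is testable without patient data.

## Worked example

```python
from ttcjoint import pk

gamma = pk.gamma_from_unit_pair(600, 617, ec50=600)   # 1.4319
params = pk.SigmoidParams(ec50=600, gamma=gamma)
pk.ttc(600, params)                                   # 50.0  (curve centre)
round(pk.unit_increase_equivalent(350, params))       # 361
```

i.e. one TTC unit corresponds to the step from 350 to 361 ng/mL — the scale
on which the association hazard ratios are read.  A hazard ratio of 0.891
per TTC unit is an 11% reduction in progression risk per unit.

The numbered drivers under `analysis/` run the full study on a simulated
cohort (`python analysis/01_simulate.py` … `05_sensitivity.py`), writing
tables under `results/`.  On the default seed the chain prints, among
others:

```
cohort: 100 patients, 485 samples (median 4/patient, range 1-17)
events: 51 progressions; median follow-up (reverse KM) 40.8 months
calibrated gamma = 1.5 (EC50 600 ng/mL)
one TTC unit: 350 -> 361 ng/mL, 600 -> 616 ng/mL
=== association: average exposure (WAIC 3722.8, LPML -1904.9) ===
average exposure (TTC) 0.9158  (0.8770-0.9505)
```

— the generating truth for this cohort is HR(average) = 0.891 per TTC unit,
inside the reported interval.  The equivalent one-shot pipeline is

```bash
ttcjoint run --config run.yaml --out results/run
```

with subcommands `simulate`, `transform`, `fit-km`, `fit-cox`, `fit-tdcox`
and `fit-joint` for the individual stages.

## Scope

Population-PK trough estimation, adherence modelling, slope association
structures, and multivariate longitudinal outcomes are intentionally out of
scope; see `docs/methods.md` for the modelling assumptions and their limits.
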