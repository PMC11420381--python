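# Methods

This note documents the models implemented in `ttcjoint`, the synthetic
cohort that exercises them, and the numerical and design choices that were
genuinely open.

## Exposure metric

Plasma samples from routine visits are rarely troughs.  Because the drug's
elimination half-life (32 h) is long relative to the 12 h dosing interval,
the concentration immediately before the next intake is recovered by
log-linear decay over the remaining fraction of the interval:

    Δ = (τ − (t_since_dose mod τ)) mod τ,      C_trough = C_obs · 2^(−Δ/t½).

Two conventions are deliberate: a sample at a scheduled trough (Δ = 0) is
returned unchanged, and times since dose beyond one interval are reduced
modulo the interval — late intakes are treated as a shifted schedule rather
than modelled as non-adherence (no adherence data exist in this design).
Absorption-phase kinetics are ignored; with a 32 h half-life the
peak-to-trough ratio is small and the error is second-order.

Troughs are normalized by a Hill sigmoid to the **transformed trough
concentration** `TTC(C) = 100·C^γ/(EC50^γ + C^γ)`.  The transformation has
two jobs: it makes the right-skewed concentration distribution approximately
Gaussian (a working assumption of the linear mixed sub-model), and it
encodes saturation — above the curve centre additional exposure buys less
effect.  EC50 is fixed at 600 ng/mL, just above the 435 ng/mL efficacy
target used in TDM practice, so the informative part of the curve brackets
the target.  The steepness γ is calibrated by maximizing the Shapiro–Wilk W
statistic of the transformed sample over the grid {0.5, 0.75, …, 4.0}, ties
toward the smaller γ.  The package default γ = 1.5 reproduces the
interpretation pairs (one TTC unit ≈ 350→361 ng/mL ≈ 600→617 ng/mL) to
three significant figures; sensitivity presets EC50 ∈ {500, 700} ng/mL with
γ = 2 are provided.  The transformation is a normalization device, not an
estimate of the true concentration–effect curve.

All times are months (1 month = 30.4375 days).

## Longitudinal sub-model

TTC follows a linear mixed model with fixed intercept, time slope and an
unordered categorical dose-level effect (reference = standard dose; the dose
actually recorded at sampling), plus a subject-level random intercept and
slope with unstructured 2×2 covariance D and i.i.d. Gaussian residuals.
Fitting is by maximum likelihood through statsmodels' `MixedLM`; because its
default L-BFGS path can stall on near-flat variance profiles, the fit is
retried with Powell and the best converged likelihood kept (deterministic).
A singular D triggers a flagged random-intercept-only refit.  Patients with
a single observation are retained — their empirical-Bayes effects simply
shrink to the population mean.  Per-subject trajectories are piecewise
linear with left-continuous steps at dose changes.

## Survival baselines

Kaplan–Meier estimation (Greenwood variance, log-log intervals — lifelines'
defaults) with the median follow-up from reverse KM.  Cox models use an
in-package Newton–Raphson maximizer of the Efron-ties partial likelihood on
counting-process rows; the standard Cox fit is the single-interval special
case of the same code path, which makes the reduction property exact.
Breslow ties are available as an option.  Separation is detected both by
coefficient blow-up during iteration and by an absurd converged magnitude
(|log HR| > 10); constant covariates are pinned at zero with no inference
rather than rejected, since they cancel from the partial likelihood.

Time-dependent Cox models use LVCF: a measurement at t_j supplies the
covariate on [t_j, t_{j+1}).  The interval before a patient's first
measurement carries the first value backward by default (configurable to
excluded/delayed entry instead); measurements at or after the event time are
dropped with a warning.  Exposure dichotomization uses the per-patient
median extrapolated trough against the 435 ng/mL target, the boundary
counting as adequate; the continuous exposure is the per-patient median TTC.
Backward elimination removes the worst block-Wald-p candidate ≥ 0.05 until
all remaining covariates are significant, never touching the exposure terms
or the prior-ALK-inhibitor adjustment.

## Joint model

The hazard is

    h_i(t) = h0(t) · exp( φ′w_i + α_curr·(m_i(t) − ȳ) + α_avg·(avg m_i(t) − ȳ) )

with m_i the LMM trajectory, avg m_i its running average (closed form per
linear/stepped segment; equal to m_i(0) at t = 0 by continuity), and w_i
baseline covariates (prior ALK-inhibitor use by default).  Centring the
association terms at the mean observed TTC ȳ is a pure reparameterization of
the baseline that decorrelates α from the baseline log-rates; reported
hazard ratios are unaffected.  The slope association structure is
intentionally not implemented: for a cytostatic exposure metric the current
level and cumulative history, not the local rate of change, carry the
mechanism.

*Baseline hazard*: piecewise-constant on five intervals with knots at the
observed event-time quintiles.  This choice (over splines) admits closed
per-piece integration and an exact trapezoid oracle for the cumulative
hazard; within each smooth segment (split further at dose-change points)
7-node Gauss–Legendre quadrature integrates the association terms.

*Priors*: N(0, 100²) on the longitudinal fixed effects (TTC scale),
N(0, 10²) on φ and α (log-hazard scale), half-t(3, 25) on the random
intercept SD and residual SD, half-t(3, 2.5) on the slope SD (TTC/month),
uniform on the random-effects correlation, and N(log crude rate, 5²) on the
baseline log-rates.  All weakly informative at the scale of the data.

*Sampler*: Metropolis-within-Gibbs with five block types — fixed effects
(proposal scaled by the LMM standard errors), per-subject random effects
(vectorized parallel 2-d walks), variance components, translation moves
shifting mass between β₀/β₁ and the random-effect columns (these leave every
trajectory invariant and cost only the random-effects density), and a
survival block (baseline log-rates, φ, active α's).  The survival block is
the cheapest and the worst conditioned — the current-value and
average-exposure functionals are nearly collinear — so it is updated ten
times per sweep, with its initial proposal covariance taken from a
finite-difference Hessian of its conditional log-posterior and empirically
re-estimated during warmup (Robbins–Monro scale adaptation targeting ~0.3
acceptance throughout).  Defaults: 3 chains × (1000 warmup + 2000 draws);
split-R̂ above 1.05 on any association coefficient raises a warning.  Chains
are seeded from a single `SeedSequence`, so every fit is reproducible.

*Model comparison*: WAIC = −2(lppd − p_waic) and LPML = Σ log CPO (harmonic
mean, via stabilized log-sum-exp), both with the **subject** as the
pointwise unit and the **conditional** (given b_i) joint density of that
subject's longitudinal and survival data.  The conditional convention is
documented because WAIC magnitudes are not comparable across conventions;
the marginal (b-integrated) variant is out of scope.

## Synthetic cohort

The generator draws, per patient: baseline covariates at the study's
reported frequencies (prior ALK-inhibitor 40%, male 47%, ECOG 41/49/7/3%,
prior lines 57/27/10/6%); a dose history starting at the standard dose with
a 0.1 probability of stepping down one level at each 3-monthly visit; random
effects from D; an event time by inverse-transform sampling (bisection on
the quadrature cumulative hazard, matching an independent dense-grid
inversion to 1e−4 months); administrative censoring uniform on 18–54 months;
and a clipped negative-binomial number of sampling times (mean 5.69, size 3,
clipped to [1, 17] — median 5).  Observed concentrations are produced by
adding Gaussian noise to the latent TTC, inverting the sigmoid, and
projecting the trough *backward* by a uniform 0–12 h sampling offset, so
trough extrapolation is exact in the noise-free limit.

Default truth: β₀ = 45, β₁ = 0.05 TTC/month, −8 TTC per dose-level step,
SD(b₀) = 12, SD(b₁) = 0.3, corr −0.2, residual SD 6 — spreading TTC across
the image of the 435 ng/mL target — with α_avg = ln 0.891 per TTC unit,
α_curr = 0, and φ = ln 2.2 for prior ALK-inhibitor use.  The constant
baseline log-rate 0.39 was calibrated once, by large-n simulation under
these defaults, to yield ≈46 progression events per 100 patients; the
per-patient sample-count parameters were tuned once to the reported
median-5 / 569-total structure.  Brain-metastasis prevalence (35%) and the
weight distribution (N(75, 15²) kg, clipped) are plausible placeholders —
the emulated study reports neither — as are the dose-reduction probability
and visit spacing.

What the generator does *not* emulate: non-adherence, assay error beyond
additive Gaussian TTC noise, informative sampling or censoring, drug–drug
interactions, and any misspecification of the trajectory (the generating
trajectory is exactly the fitted family).  Passing recovery tests therefore
demonstrates internal consistency of the estimation machinery, not
robustness to the ways real TDM data violate the model.

## Verification design

Every numerical component has an independent oracle in the test suite:
partial likelihoods vs brute-force risk-set enumeration (n ≤ 6, exact to
1e−6), cumulative hazards vs dense trapezoid grids (1e−6), the
average-exposure closed form vs 64-node Gauss–Legendre (1e−8), empirical
Bayes modes vs the analytic conditional-mean formula, lifelines as an
independent cross-check of the Cox engine, and the event-time sampler vs
closed-form exponential and dense Riemann inversion.  Simulation-based
checks fit the joint model on seeded cohorts: 95% intervals for the
average-exposure HR cover the generating 0.891 in ≥8/10 cohorts at n = 100
(reduced chains: 2 × 1500 after 600 warmup); with both associations active
(opposing HRs 1.094 and 0.891, the pattern a combined structure is needed
for) the combined model attains the smallest WAIC in the majority of 10
replicates at n = 60; with null associations the interval covers HR 1 in
≥17/20 replicates; and the LVCF time-dependent Cox coefficient is attenuated
toward zero relative to the joint posterior mean under a true current-value
effect.  Replicate counts, cohort sizes and chain lengths for these suites
were chosen to keep the full test run comfortably on a single CPU while
leaving the checks well-powered.

## Known limitations

- The combined association structure is weakly identified when trajectories
  are near-linear: m(t) and its running average are then nearly collinear,
  so the two α's trade off along a ridge.  The sampler handles the ridge
  (covariance-adapted block updates), but marginal intervals are wide and
  single-coefficient coverage in the combined model runs slightly below
  nominal — visible in the recovery suite.
- WAIC/LPML values depend on the conditional-pointwise convention and are
  not comparable to implementations using marginal densities.
- The piecewise-constant baseline is a modelling choice; a spline baseline
  would change absolute WAIC values but not the association contrasts the
  package is built to estimate.
- Backward elimination inherits the usual caveats of stepwise selection; it
  is provided as the conventional comparator, not as a recommendation.
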