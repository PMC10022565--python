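# Methods

## Model structure

The simulator reproduces the life course of a general-population cohort
from birth to a 30-year horizon.  Eight diagnostic clusters of mental
disorders are modelled as *parallel* onset processes per individual:
substance use, anxiety, mood disorders (accepting "depression" as an input
alias), psychosis and personality disorders, conduct disorders, ADHD,
eating disorders, and self-harm.  Onset of one cluster does not alter the
hazard of another; the per-cluster counts the model reports are marginal,
not mutually exclusive, and once a disorder begins its consequences are
permanent (no remission).

Each individual carries gender, binary SES (low vs medium-to-high, the
pharmacy co-payment proxy used in the source registry) and nine uniform
deviates: one per cluster and one for death.  The population is cloned
into a base-case and an intervention copy sharing those deviates, so the
only source of between-scenario differences is the pair of incidence
tables — the common-random-number design that makes null effects produce
*exactly* zero differences and protective effects produce per-individual
monotone ones (onset delayed or prevented, never hastened).

Onset times are drawn by inverse transform on the cumulative incidence
curve F of the individual's cluster × gender × SES cell: an individual
with deviate u experiences onset iff `u < F(30)`, at the age where the
step-linear curve crosses u (linear interpolation inside the year, so
event times are continuous).  The age grid is integer years 1–30 with
F(0) = 0; flat years (zero incidence) are legal.

Death competes with onset.  Mortality is Gompertz,
`h(t) = rate·e^{shape·t}`, stratified by gender and by binary disorder
status ("any disorder yet") — not by cluster, because deaths before 30 are
rare.  The status switch happens at the first onset: the cumulative hazard
is `H0(t)` before the switch age s and `H0(s) + H1(t) − H1(s)` after, so
the survivor function is continuous at the switch.  Death times solve
`H(t) = −log(1−u)` in closed form (the shape→0 exponential limit is
handled via `expm1`/`log1p`).  Since a delayed onset moves s later and the
with-disorder hazard is higher, preventing disorders also defers death —
deaths averted are non-negative by construction.  Onsets that would occur
after death are censored; deaths beyond the horizon count as survival.

## Incidence estimation

Input curves are estimated from individual event records by the
Aalen–Johansen estimator with competing risks death and file closure
(censoring): `CIF_k(t) = Σ Ŝ(t_j⁻)·d_kj/n_j`, all same-time events sharing
one risk set.  With no censoring and no competing events this reduces
exactly to the empirical CDF.  Grid read-off is right-continuous; beyond
the last observed risk time the value is carried forward flat and flagged
as extrapolated.  An Aalen-type pointwise variance is reported but not
consumed downstream.  No covariate regression (e.g. Fine–Gray) is
attempted: strata are estimated separately, as in the source design.

## Effect translation

Trial effects are odds ratios on the probability of worsening (anxiety
OR 0.71, mood OR 0.66); the meta-analytic sensitivity path uses
standardized mean differences (−0.18 anxiety, −0.13 mood).  Conversion and
application:

1. SMD → OR by the logistic-distribution identity `OR = exp(SMD·π/√3)`,
   exact when the latent score is logistic in both arms.  The source text
   does not state its SMD→incidence mapping; this standard conversion is a
   package choice.
2. OR → RR by `RR = OR/(1 − p₀ + p₀·OR)` with baseline risk p₀ taken as
   the *conditional annual incidence* q(t) of the affected cell, year by
   year.  Annual risks are ≤ a few percent, so RR ≈ OR and the p₀
   convention is second-order.
3. `q(t)` is multiplied by RR for ages in `[start, start+duration)`
   (default start 14; durations 2, 5 or 1 year) and the curve recomposed
   via `F(t) = 1 − Π(1−q(j))`.  Scaling even a short window moves the
   whole cumulative curve from the window start to the horizon.

Whether the original analysis scaled annual incidence or the cumulative
increment over the window is not determined by its text; annual scaling is
the default and a "cumulative" mode is selectable for sensitivity.  Both
preserve curve dominance (RR ≤ 1 ⇒ F′ ≤ F, equality before the window).

## Economics

QALYs and costs accrue continuously over ages 14–30 (the programme runs at
ages 12–14; accrual starts when it ends), truncated at death.  Utility is
binary in disorder status within each gender × SES cell (decrements do not
stack across clusters), whereas per-cluster annual costs — healthcare,
direct non-medical, indirect — are additive across co-occurring clusters,
accruing from max(onset, 14).  Premature-mortality production losses,
intangible costs and crime costs are excluded.

Discounting is continuous, `e^{−r(t−14)}` at r = 0.03, because it composes
with continuous event times; an annual-step mode `(1+r)^{−⌊t−14⌋}` is
available and differs by under 2 % over the full window.  The programme
cost (€135.70/student) is charged once, undiscounted, to every simulated
individual — the choice that reproduces the printed total of €82.69
million exactly at the registry population size.

The healthcare perspective counts healthcare plus programme costs; the
societal perspective adds direct non-medical and indirect costs.  For each
subgroup ΔC and ΔQ give an ICUR only when both are positive; lower cost
with higher QALYs is *dominant*, higher cost with lower QALYs *dominated*;
the south-west quadrant is labelled rather than expressed as a ratio.

## Synthetic data

The source registry (609,381 individuals) is not deposited.  The
generator therefore emulates:

* **Population** — gender ~ Bernoulli(0.487 female), SES ~ Bernoulli(0.078
  low), independent, matching the published composition; nine uniforms per
  individual from counter-based Philox streams spawned off one master
  seed, drawn as single blocks so results are independent of iteration
  order.
* **Incidence** — logistic-in-age curves (steepness 0.15–0.35/yr, midpoint
  10–20 yr, drawn from a shape seed) scaled per stratum so the
  population-weighted F(30) equals each cluster's published base-case
  proportion (e.g. anxiety 141,397/609,381) to 1e-6.  Low-SES strata get a
  risk multiplier of 1.6 (the registry showed higher prevalence in low
  SES; the true per-stratum split is unpublished, so the multiplier is a
  package choice, not an estimate).
* **Mortality** — Gompertz shape 0.075/yr for all groups; rates 5.6e-6
  (female) and 9.0e-6 (male) without disorder, four-fold higher with
  (2.25e-5 / 3.6e-5), calibrated once so a full-size base-case run yields
  deaths on the scale of the published aggregate (~1,045; about 1.7 per
  1,000 by age 30).
* **Utilities** — 0.879–0.895 without disorder (male above female,
  medium/high SES above low, the ordering of Spanish EQ-5D population
  norms for young adults), decrement 0.12 with any disorder.
* **Costs** — €700–3,200/patient-year healthcare and larger indirect
  costs, ordered as in Spanish cost-of-brain-disorders studies (psychosis
  and self-harm dearest, anxiety cheapest).
* **Event records** — one competing-risks observation per (individual,
  cluster): first of that cluster's onset, death (no status feedback in
  the fixture), exponential censoring, or the 30-year horizon.

What the synthetic data does **not** emulate: cross-cluster correlation
(real comorbidity makes the same individuals appear in several clusters,
so the synthetic "any disorder" fraction exceeds the registry's 15.9 %),
visit-level microstructure, prescriptions, and the true per-stratum
incidence split.  Passing tests therefore demonstrate the *mechanics* —
estimator consistency, clone exactness, monotone effect propagation,
accounting identities — under controlled conditions, not agreement with
the confidential registry.  The published subgroup-level figures are only
reproducible with the original parameter tables loaded through
`mhsim.parameters.load_parameters`.

## Validation

Operational validation compares simulated age-specific cumulative
incidence (base case) with the input curves per cluster × stratum using
Pearson r, NMSE, fractional bias, fractional variance and FAC2 (factor-of-
two fraction, boundaries inclusive).  The source's exact pass criteria are
unpublished; defaults are the conventional model-evaluation bounds
|FB| ≤ 0.3, NMSE ≤ 1.5, FAC2 ≥ 0.8, r ≥ 0.9, |FV| ≤ 0.5, configurable.
FAC2 ratios are evaluated only at ages where the input curve implies at
least 10 expected onsets in the stratum — below that, a factor-of-two
check is pure noise.  Runs under 10,000 individuals carry a warning that
sampling error dominates.  Statistics over constant series report an
undefined correlation; cells with no simulated events report undefined
statistics and fail.

## Numerical choices and problem sizes

* Inverse-CDF lookup uses `searchsorted` on the F grid; ties on flat
  segments resolve to the left edge and cannot produce interior ages.
* Gompertz MLE: Nelder–Mead polish then BFGS on (shape, log rate);
  standard errors from the finite-difference observed information;
  exponential and Weibull share the framework for AIC comparability
  (AIC = 2k − 2lnL; ties broken toward fewer parameters).
* The engine is vectorised; a full-size run (609,381 individuals, paired
  scenarios) takes a few seconds, so tests exercise the calibration
  contract at full size while most fixtures use 2,000–100,000 individuals,
  enough to separate the tested signal from Monte-Carlo noise.
* AIC family-selection replicates use an adult-lifespan design (n = 3,000,
  censoring at 80, ~70 % events, shape 0.09, rate 5e-5): with 30-year
  censoring and ~1.5 % events the three families are nearly
  indistinguishable, which tests the data, not the selector.

## Known limitations

* No probabilistic sensitivity analysis or CEAC; confidence intervals on
  the ORs are not propagated.
* No remission, no cluster-specific mortality, no within-trial cluster-
  randomisation structure.
* Whether onsets should be recorded independently of death is unknowable
  from the source text; censoring at death is assumed.
* The societal perspective is partial (no social-services, education or
  justice spillovers), inherited from the source cost study.
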