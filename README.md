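# mhsim

Discrete-event microsimulation of the natural history of mental disorders
from birth to age 30, with cost-utility analysis of universal school-based
resilience interventions.

## The problem

School programmes that strengthen adolescents' resilience aim to prevent
mental disorders whose costs and quality-of-life losses appear years after
the trial ends.  Evaluating such a programme therefore requires projecting
a short-term effect — measured as odds ratios on questionnaire worsening,
or standardized mean differences from meta-analyses — onto the long-term
natural history of mental illness in the general population.

`mhsim` implements that projection as an individual-level discrete-event
simulation.  Disorder onset is described by cumulative incidence functions
(CIFs) for eight diagnostic clusters — substance use, anxiety, mood
disorders, psychosis and personality disorders, conduct disorders, ADHD,
eating disorders, and self-harm — estimated under competing risks (death,
file closure) with the Aalen–Johansen estimator and disaggregated by
gender and socioeconomic status (SES):

```
CIF_k(t) = Σ_{t_j ≤ t}  Ŝ(t_j⁻) · d_kj / n_j
```

Every simulated individual receives gender, SES and nine uniform deviates,
and is then **cloned**: the base-case and intervention copies share the
same random numbers (common random numbers), so any difference between
their life courses is caused solely by the difference between the two
incidence tables.  Onset times come from inverse-transform sampling of the
empirical CIFs; death from a Gompertz hazard `h(t) = rate·e^{shape·t}`
(fitted by maximum likelihood with AIC family selection) that switches
from the no-disorder to the with-disorder parameters at the first onset.

The intervention effect enters through the conditional annual incidence
`q(t) = (F(t) − F(t−1))/(1 − F(t−1))`: odds ratios are converted to
relative risks with `RR = OR/(1 − p₀ + p₀·OR)`, standardized mean
differences to odds ratios with `OR = exp(SMD·π/√3)`, and `q` is scaled by
RR inside the effect window (2 years, 5 years, or 1 year for the
meta-analytic path) before the curve is recomposed — which shifts the
whole cumulative curve from the window start to the 30-year horizon.

Costs (healthcare, direct non-medical, indirect; €/patient-year per
cluster) and utilities (by gender, SES and disorder status) accrue in
continuous time from age 14 to 30, discounted at 3 %/year; the programme
cost (€135.70 per student) is charged once to every individual.  Results
are incremental cost-utility ratios (ICUR = ΔC/ΔQ, €/QALY) or dominance
labels, for the whole cohort and the four gender × SES subgroups, from
healthcare and societal perspectives.

Because the registry that parameterised the original analysis is not
public, `mhsim.synthetic_data` generates complete parameter bundles whose
population-weighted incidence at age 30 is calibrated (to 1e-6) to the
published per-cluster base-case counts, so the entire pipeline runs
self-contained.

## Worked example

```bash
cat > example.yaml <<'YAML'
seed: 7
population: {n: 50000}
parameters: {synthetic: {shape_seed: 0}}
effect: {presets: [trial-2y, trial-5y, meta-1y]}
economics: {discount_rate: 0.03, perspectives: [healthcare, societal]}
output_dir: example_out
YAML
mhsim run -c example.yaml
```

prints the epidemiological impact of the three effect presets (trial odds
ratios 0.71/0.66 for anxiety/mood with 2- or 5-year waning; meta-analytic
SMDs −0.18/−0.13 with 1-year waning) on a 50,000-person cohort:

```
  substance_use: base 6689, trial-2y +0, trial-5y +0, meta-1y +0
  anxiety: base 11531, trial-2y -374, trial-5y -784, meta-1y -183
  mood: base 2776, trial-2y -140, trial-5y -313, meta-1y -33
  ...
  deaths: base 93, trial-2y +0, trial-5y -2, meta-1y +0
```

Only the two affected clusters change (the zero rows are exact, a
consequence of the cloned-population design), the 5-year effect averts
more cases than the 2-year effect, and fewer disorders also means fewer
deaths.  `example_out/table4.csv` holds the cost-utility analysis; the
discounted totals from this run:

```
  effect perspective  delta_cost  delta_qaly     icur    label
trial-2y  healthcare     18.9336    0.010943  1730.18     icur
trial-2y    societal   -226.0683    0.010943      NaN dominant
trial-5y  healthcare    -91.2990    0.021336      NaN dominant
trial-5y    societal   -567.5000    0.021336      NaN dominant
 meta-1y  healthcare     86.4700    0.005030 17189.35     icur
 meta-1y    societal    -15.6604    0.005030      NaN dominant
```

Per person, the 2-year trial effect costs €18.93 more from the healthcare
perspective (the €135.70 programme charge minus €117 of averted healthcare
costs) and gains 0.011 QALYs — an ICUR of €1,730/QALY, far below usual
willingness-to-pay thresholds.  From the societal perspective (adding
direct non-medical and indirect costs) every preset is *dominant*: the
intervention saves money and gains QALYs.

## Layout

| module | role |
| --- | --- |
| `mhsim.parameters` | domain types, CSV readers/writers, structural validation |
| `mhsim.synthetic_data` | calibrated parameter bundles, populations, event records |
| `mhsim.incidence` | Aalen–Johansen CIF estimation under competing risks |
| `mhsim.survival` | parametric mortality (MLE, AIC selection, piecewise sampling) |
| `mhsim.effect_translation` | OR/SMD → RR conversion and intervention-arm curves |
| `mhsim.des_engine` | cloned-population simulation under common random numbers |
| `mhsim.economics` | discounted QALY/cost accrual, ICUR and dominance |
| `mhsim.validation` | goodness-of-fit battery (r, NMSE, FB, FV, FAC2) |
| `mhsim.cli` | `mhsim run/synth/simulate/economics/validate/report` |

See `docs/methods.md` for the model's assumptions, parameter defaults and
known limitations.
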