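# Methods

## Model overview

`lungscreen` evaluates LDCT lung-cancer screening policies for heavy smokers
with a deterministic cohort state-transition (Markov) model run in annual
cycles over a 30-year horizon.  The state space couples:

* **Natural history** — Healthy; undetected lung cancer stages I–IV;
  lung-cancer death; other-cause death.  Healthy individuals develop stage-I
  disease at the cycle's incidence; undetected disease may progress to any
  higher stage, be detected clinically (symptomatic presentation) or by
  screening, or kill.
* **Post-diagnosis** — aftercare stages I–IV, each split into a *first-year*
  and a *subsequent-year* tunnel so that first-year and continuing care costs
  can differ.  Diagnosed patients are assumed treated immediately; recurrence
  is not modelled.  Sub-stages (IA/IB, IIIA/IIIB) are not modelled.

Within a cycle, events compose **sequentially and conditionally** in this
order: (1) screening, (2) clinical detection, (3) other-cause death,
(4) incidence and undetected progression/lung-cancer death, (5) aftercare
lung-cancer death.  Sequential composition is forced by the inputs: stage-IV
clinical detection (0.658) plus stage-IV death (0.588) would exceed 1 if
composed additively.  The exact intra-cycle order used by the original
implementation is unpublished; ours is a documented choice, and any
parameter set whose progression rows sum above 1 is renormalized with a
logged warning.  Newly diagnosed patients spend the diagnosis cycle in the
first-year tunnel and face aftercare mortality from the following cycle.
Patients in every alive state face age/sex-specific other-cause mortality.

The cohort is heterogeneous in age, sex and risk group, while a single cohort
matrix cannot carry age-varying rates, so the engine runs one state vector
per (risk group × entry age × sex) stratum (about 107 strata for the default
cohort) and aggregates with stratum weights.  Tuberculosis and emphysema
prevalences enter as stratum-level utility decrements.

## Absolute risk and stratification

Individual risk uses a Gail-type projection: multiplicative relative risk
`r` from per-factor hazard ratios; baseline hazard `h1j` = registry
lung-cancer incidence × (1 − PAR), with the population-attributable risk from
Bruzzi's formula (`PAR = 1 − Σ ρ_c/RR_c`); competing hazard `h2j` = all-cause
mortality × smoker RR (1.33 male / 1.44 female) − lung-cancer mortality.  The
smoker adjustment is applied to all-cause mortality *before* subtracting
lung-cancer mortality (configurable, `adjust_allcause_first`).  Case-category
weights `ρ_c` default to a simulation from the cohort's observed group
incidence densities (each member contributes expected cases proportional to
their group's density); an explicit weight table is accepted.

Quartile stratification ranks by risk with a stable tie-break and splits into
four groups as equal as possible; fixed-threshold mode uses ≥-semantics
(boundary values go to the higher-risk group).  Default fixed thresholds are
1.70% / 1.03% / 0.49%.

## Incidence over time

Per-cycle incidence is `I_i = I_b × HR_i`.  `I_b` per stratum is the risk
group's observed incidence density (262 / 220 / 154 / 81 per 100,000
person-years).  `HR_i` is the stratum-mean ratio of each member's relative
risk at cycle *i* to its baseline value, with the age-band hazard ratio
clamped at the top 70–74 band (the relative-risk model is fitted on ages
50–74, so extrapolating its age effect beyond that range is unsupported).
In the base case pack-years accumulate at 1/year (≈1 pack/day), which can
move members across the ≥50 pack-year band; the quit-smoking scenario freezes
pack-years so incidence varies with age only.  Radiation exposure inflates
incidence by `(1 + 0.001 × cumulative screens)`; the attributable fraction
`0.001·n/(1 + 0.001·n)` of incident cases accrues to a radiation counter.

## Screening, harms and adherence

A screen reaches Healthy and undetected-cancer occupants with probability
`adherence` (base 1.0, range 0.5–1.0).  Undetected stage *s* is diagnosed
with probability `adherence × sensitivity` (0.937); a screen detects the
current underlying stage — no separate stage-shift is imposed, the benefit
emerges from earlier transfer to aftercare mortality and treatment costs.
Healthy participants incur a false positive with probability
`adherence × (1 − specificity)` (specificity 0.765), paying the biopsy
work-up cost (CNY 1202.9) and a 0.063 utility decrement for 3 months, then
return to Healthy; repeat false positives are possible.  Overdiagnosis is
counted as 0.031 × screen-detected stage-I cases (configurable to all
screen-detected); overdiagnosed cases accrue diagnosis and care costs but no
death-averted credit.  Screens are offered at cycles 1, 1+k, 1+2k, … per
group interval (one-off: baseline only) while attained age ≤ 74.

## Economics

Costs (2022 CNY, health-system perspective): risk scoring/questionnaire
613.3 once at baseline for every screening strategy including annual-for-all
(the original study is silent on this; configurable); LDCT 239.97 per screen;
biopsy 1202.9 per false positive; stage-specific care split first-year vs
subsequent (e.g. stage II: 97,435.6 then 15,888.82); background medical
treatment 5348.1/year for undetected symptomatic disease only.  Utilities:
age/sex baseline for smokers without cancer (e.g. male 51–60: 0.984) minus
tuberculosis (0.01) and emphysema (0.052) decrements, floored at 0; stage
utilities 0.85/0.75/0.69/0.69 after diagnosis.  Undetected (undiagnosed)
cases carry the *baseline* utility — they are unaware of their disease —
configurable to stage utility.

Costs and QALYs discount at 5%/year (0–8%) with a half-cycle correction
implemented as mid-cycle discounting: cycle *t* accruals (computed on
post-transition occupancy) are weighted by `(1+r)^−(t−0.5)`.  Undiscounted
life-years use a trapezoid on alive mass.  Rate-table inputs convert to
per-cycle probabilities as `p = 1 − exp(−rate)`; printed annual probabilities
are used as-is.

## Cost-effectiveness synthesis

ICER = Δcost/ΔQALY with dominance labels (dominated / cost-saving);
iNMB = (ΔQALY × WTP − Δcost)/100,000 reported per person at WTP CNY 242,928
(3× 2021 per-capita GDP; 1× GDP = 80,976 available as a scenario).  The
efficiency frontier removes strictly dominated points, then iteratively
removes extended-dominated points until segment ICERs are non-decreasing
(exact arithmetic, no tolerance); ties in both cost and QALYs break
deterministically by name.  Applied to the original study's printed
per-strategy values this recovers five of the six flagged frontier members:
the sixth (`H1-MH3-LM3-L3`) is extended-dominated by a 0.8% ICER margin at
printed precision, and the published frontier's own segment ICERs are
non-monotone at that point — a rounding artifact of the source table, which
we do not paper over with a tolerance.

## Uncertainty analysis

Probabilities and utilities carry Beta distributions, costs Gamma, adherence
and the discount rate Triangles, sampled independently (no correlations are
specified).  Parameters with printed distribution arguments use them
verbatim; "±50%" parameters use a method-of-moments fit reading the
half-width as a 95% margin (CV = 0.5/1.96 ≈ 0.2551), which reproduces the
published Gamma shape 15.37 and Beta parameters such as (9.33, 16.01) for
mean 0.3682.  PSA is a second-order Monte Carlo rerunning all selected
strategies per draw; the desk-scale default is 1,000 iterations (the original
analysis used 100,000 — results scale by rerunning with a larger `n_iter`).
The acceptance script uses 200 iterations for its CEAC estimate.  CEACs are
pairwise (strategy vs frontier predecessor) under strict-inequality iNMB > 0;
one-way analyses rerun all strategies at a parameter's bounds and record the
focal comparison's iNMB/ICER swing.

## Synthetic data: what it does and does not emulate

The source cohort and the supplementary tables (per-factor hazard ratios;
age/sex registry rates) are not public.  The package therefore ships:

* **A synthetic cohort generator** reproducing, exactly and by construction,
  every published risk-group marginal — counts per (group × 5-year age band),
  (group × sex), (group × pack-year band), (group × tuberculosis) and
  (group × emphysema) — for 19,146 individuals (18,560 men).  Within a group,
  attributes are assigned independently (only marginals are published); ages
  are uniform within bands (group mean ages land within 0.5 years of the
  published 67.2/61.7/57.0/52.3); pack-years are log-uniform within 30–49 and
  50–120 to approximate the right-skewed published medians.  The generator
  does not emulate recruitment, follow-up or registry linkage.
* **Synthetic rate and hazard-ratio stand-ins**, labeled as such, with age
  curves anchored at 5-year knots resembling Chinese registry/census levels
  and hazard ratios calibrated once so model-implied group incidence
  approximates the published 262/220/154/81 per 100,000 person-years (the
  fitted age-band ratios come out nearly flat because the registry age curve
  already carries most of the gradient; the 60–70 incidence plateau in the
  stand-in is a calibration artifact).

Consequences: passing tests demonstrate correct *mechanics* (conservation,
dominance logic, oracle agreement, exact arithmetic on published inputs), not
agreement of model-level outcomes with the original study.  With the
stand-ins, the no-screening arm yields 18.02 undiscounted life-years/person
(published: 18.305) and 2,645 lung-cancer deaths per 100,000 (published:
2,162); the absolute-risk range is 0.11–4.1% (published: 0.115–11.395%) and
quartile cut-points sit below the published thresholds.  Reproducing those
numbers requires the real supplementary tables.

## Known limitations and divergences

* **False-positive counts.**  Applying `(1 − specificity)` per screen to the
  healthy pool — the definitional reading — yields ~3×10⁵ false positives
  per 100,000 over 30 annual screens, whereas the original study reports
  8,373 ("false-positive lung cancers", ~0.8% of screens).  Their counting
  rule is not stated and cannot be recovered from specificity 0.765; our
  counter keeps the definitional reading, which also drives biopsy costs and
  the false-positive disutility.  The radiation-attributable counter
  (closed-form attributable fraction) similarly exceeds the published count
  (ours ~32 vs 1.09 per 100,000 for annual-for-all).
* Recurrence after treatment, incidental findings, non-lung radiation
  cancers, and societal costs (productivity, caregivers) are out of scope, as
  in the original analysis.
* The intra-cycle event order and the undetected-disease utility are
  documented assumptions (both configurable where a credible alternative
  exists).
* Numerical notes: occupancy is asserted conserved to 1e-9 every cycle;
  degenerate stratification inputs (all-equal risks) fall back to rank-based
  equal quarters; the 5-year risk formula saturates to 1.0 in floating point
  only for extreme hazards (total hazard ≳ 7/year).
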