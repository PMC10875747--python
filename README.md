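# lungscreen

Benefit–harm and cost-effectiveness modelling of **risk-stratified low-dose CT
(LDCT) lung-cancer screening** in heavy smokers (≥30 pack-years, aged 50–74),
from a Chinese health-system perspective.

Annual LDCT screening is recommended for all heavy smokers, but most of them
will never develop lung cancer while still being exposed to false positives,
overdiagnosis and radiation.  `lungscreen` asks whether stratifying the
screening *interval* by each person's absolute 5-year lung-cancer risk — e.g.
annual screening only for the highest-risk quartile, biennial/triennial for the
rest — preserves most of the mortality benefit at a fraction of the cost and
harm.

## What the package computes

**Absolute 5-year risk (Gail-type projection).**  For an individual of age *a*
and sex *j* with multiplicative relative risk *r* (built from per-factor hazard
ratios for age band, sex, pack-year band, tuberculosis and emphysema history):

```
P(a, r, j) = [h1j·r / (h1j·r + h2j)] · [1 − exp{−5(h1j·r + h2j)}]
```

where `h1j` is the baseline (factor-free) lung-cancer hazard — registry
incidence deflated by the population-attributable risk computed with Bruzzi's
formula, `PAR = 1 − Σ_c ρ_c / RR_c` — and `h2j` is competing non-lung-cancer
mortality (all-cause mortality inflated by the smoker relative risk 1.33 for
men / 1.44 for women, minus lung-cancer mortality).  Cohorts are split into
four risk groups (H / MH / LM / L) by quartiles or fixed thresholds.

**A cohort Markov model** (annual cycles, 30-year horizon, half-cycle
correction, 5% discounting) with a natural-history part (Healthy, undetected
stages I–IV, lung-cancer death, other death) and a post-diagnosis part
(aftercare stages I–IV with first-year/subsequent-year cost tunnels).
Screening overlays true/false positives (sensitivity 0.937, specificity
0.765), overdiagnosis, radiation excess risk and adherence.

**36 screening strategies** — no screening, annual-for-all (the status quo
`H1-MH1-LM1-L1`), and every risk-based assignment `H1-MH{i}-LM{i}-L{i}` of
intervals {annual, biennial, triennial, one-off, none} in which a lower-risk
group is never screened more often than a higher-risk one.

**Cost-effectiveness synthesis**: ICERs, incremental net monetary benefit
(iNMB = ΔQALY × WTP − Δcost, per person, WTP = CNY 242,928 ≈ 3× 2021 per-capita
GDP), strict and extended dominance, the efficiency frontier, benefit–harm
ratios (screens per death averted / per life-year gained), one-way sensitivity
analysis and probabilistic sensitivity analysis with CEAC curves.

Because the source cohort (19,146 heavy smokers) and the supplementary
registry/hazard-ratio tables are not public, the package ships a seeded
**synthetic cohort generator** that reproduces every published risk-group
marginal exactly, and clearly-labeled synthetic rate/HR stand-in tables
(`lungscreen._synthetic`), both replaceable by CSV inputs.

## Worked example

```python
from lungscreen.config import RunConfig
from lungscreen.pipeline import run_pipeline

cfg = RunConfig(seed=1, strategies="no_screening,H1-MH3-LM3-L3,H1-MH2-LM3-L3,H1-MH1-LM1-L1")
res = run_pipeline(cfg)
print(res["cea_table"][["strategy", "cost_per_100k", "qalys_per_100k",
                        "inmb_vs_sq", "frontier"]])
```

prints (costs in thousand CNY per 100,000 people; iNMB in CNY per person
vs the annual-for-all status quo):

```
     strategy  cost_per_100k  qalys_per_100k  inmb_vs_sq           frontier
H1-MH1-LM1-L1       826860.0       1054682.0         0.0          dominated
 no_screening       113919.0       1054700.0      7171.0        on-frontier
H1-MH3-LM3-L3       515912.0       1055298.0      4604.0 extended-dominated
H1-MH2-LM3-L3       543638.0       1055366.0      4493.0        on-frontier
```

Reading it: with the synthetic stand-in inputs, de-intensified risk-based
screening (`H1-MH2-LM3-L3`: annual for the top risk quartile, biennial for the
next, triennial below) achieves more QALYs than annual-for-all at roughly 60%
of the cost — annual screening of low-risk smokers buys extra false positives
and their disutility faster than it buys survival.  The benefit–harm table of
the same run shows `H1-MH2-LM3-L3` averting 395 of the 542 lung-cancer deaths
per 100,000 that annual-for-all averts, with half the screens (1,583 vs 2,423
screens per death averted).

The same CEA arithmetic applied to the *published* per-strategy costs and
QALYs (`lungscreen.reference`) reproduces the original study's headline
numbers exactly: iNMB of CNY 1032 per person for `H1-MH2-LM3-L3` and CNY 1002
for `H1-MH2-LM2-L2`, 1392 screens per death averted and a 35.6% mortality
reduction for the status quo.

A CLI mirrors the library: `lungscreen simulate-cohort`, `lungscreen run`,
`lungscreen owsa`, `lungscreen psa`, `lungscreen report`.

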