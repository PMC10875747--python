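"""Cohort Markov engine for lung-cancer natural history and LDCT screening.

The model couples a natural-history part (Healthy, four undetected cancer
stages, lung-cancer death, other-cause death) with a post-diagnosis part
(four aftercare stages split into a first-year and a subsequent-year
tunnel, plus the two death states).  Each annual cycle applies, in order:

1. screening (if offered): undetected stage ``s`` is diagnosed with
   probability adherence x sensitivity; healthy participants incur a
   false positive with probability adherence x (1 - specificity);
2. clinical detection of remaining undetected disease at stage-specific
   rates (symptomatic presentation);
3. other-cause death in every alive state at the age/sex hazard;
4. among remaining undetected cases: lung-cancer death, then progression
   to higher stages; new cancers arise from Healthy at the cycle's
   incidence (inflated by cumulative-screen radiation exposure);
5. lung-cancer (aftercare) death among previously diagnosed patients.

Sequential conditional composition is used throughout: each event applies
to the mass remaining after the previous one, so composed exit
probabilities can never exceed 1 (stage IV clinical detection 0.658 plus
lung-cancer death 0.588 would otherwise overflow).  Newly diagnosed
patients spend the diagnosis cycle in the first-year tunnel (first-year
care cost, stage utility) and face aftercare mortality from the next
cycle on.

The cohort is heterogeneous in age, sex and risk group, so the engine
runs one state vector per (risk group x entry age x sex) stratum and
aggregates with stratum weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import StrategyOutcome
from .cohort import _GROUP_INCIDENCE_DENSITY
from .economics import EconParams, baseline_utility, discount_factor
from .risk import GROUPS, HazardRateTable, RiskModelParams, age_band, competing_hazard
from .strategies import Strategy, build_schedule

__all__ = ["ModelParams", "IncidenceModel", "CohortStrata", "build_strata",
           "cycle_transition", "incidence_at_cycle", "apply_radiation_risk",
           "run_strategy", "run_all_strategies", "STATES"]

log = logging.getLogger(__name__)

STAGES = ("I", "II", "III", "IV")
#: State layout of the occupancy vector.
STATES = ("healthy",
          "u_I", "u_II", "u_III", "u_IV",
          "dnew_I", "dnew_II", "dnew_III", "dnew_IV",
          "dpost_I", "dpost_II", "dpost_III", "dpost_IV",
          "lc_death", "other_death")
HEALTHY, LC_DEATH, OTHER_DEATH = 0, 13, 14
U_SLICE, DNEW_SLICE, DPOST_SLICE = slice(1, 5), slice(5, 9), slice(9, 13)
N_STATES = len(STATES)


@dataclass
class ModelParams:
    """Annual transition probabilities and LDCT test characteristics."""

    progression: dict = field(default_factory=lambda: {
        ("I", "II"): 0.3682, ("I", "III"): 0.0328, ("I", "IV"): 0.0745,
        ("II", "III"): 0.2260, ("II", "IV"): 0.1510, ("III", "IV"): 0.1455})
    lc_death_undetected: dict = field(default_factory=lambda: {
        "I": 0.1739, "II": 0.2942, "III": 0.4626, "IV": 0.5880})
    aftercare_death: dict = field(default_factory=lambda: {
        "I": 0.089, "II": 0.153, "III": 0.288, "IV": 0.353})
    clinical_detection: dict = field(default_factory=lambda: {
        "I": 0.0246, "II": 0.027, "III": 0.518, "IV": 0.658})
    sensitivity: float = 0.937
    specificity: float = 0.765
    overdiagnosis_rate: float = 0.031
    excess_rr_per_screen: float = 0.001
    adherence: float = 1.0
    #: count overdiagnosis against screen-detected stage-I cases only
    overdiagnosis_stage_i_only: bool = True

    def __post_init__(self):
        probs = [*self.progression.values(), *self.lc_death_undetected.values(),
                 *self.aftercare_death.values(), *self.clinical_detection.values(),
                 self.sensitivity, self.specificity, self.overdiagnosis_rate,
                 self.adherence]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        P = np.zeros((4, 4))
        for (a, b), p in self.progression.items():
            P[STAGES.index(a), STAGES.index(b)] = p
        rowsum = P.sum(axis=1)
        if (rowsum > 1.0).any():
            warnings.warn("stage progression probabilities exceed 1; normalizing rows")
            log.warning("normalizing progression rows with sums %s", rowsum)
            P[rowsum > 1] /= rowsum[rowsum > 1, None]
        self._prog_matrix = P
        self._prog_out = P.sum(axis=1)
        self._p_lcd = np.array([self.lc_death_undetected[s] for s in STAGES])
        self._p_after = np.array([self.aftercare_death[s] for s in STAGES])
        self._p_clin = np.array([self.clinical_detection[s] for s in STAGES])


@dataclass
class IncidenceModel:
    """Per-cycle lung-cancer incidence: I_i = I_b x HR_i.

    ``baseline_incidence`` is the cohort-derived annual rate and
    ``hr_by_cycle`` the hazard-ratio multipliers from the relative-risk
    model as age (and, unless ``quit_smoking``, smoking intensity)
    advances; ``hr_by_cycle[i]`` applies to cycle ``i`` (index 0 unused).
    """

    baseline_incidence: float
    hr_by_cycle: np.ndarray
    quit_smoking: bool = False

    def __post_init__(self):
        if self.baseline_incidence < 0:
            raise ValueError("baseline incidence must be non-negative")
        self.hr_by_cycle = np.asarray(self.hr_by_cycle, dtype=float)
        if (self.hr_by_cycle[1:] <= 0).any():
            raise ValueError("incidence hazard ratios must be positive")


def incidence_at_cycle(model: IncidenceModel, cycle: int) -> float:
    """Annual incidence rate in cycle ``i`` (>= 1): I_b x HR_i."""
    if cycle < 1:
        raise ValueError("cycle must be >= 1")
    return float(model.baseline_incidence * model.hr_by_cycle[cycle])


def apply_radiation_risk(cumulative_screens, excess_rr_per_screen: float, incidence):
    """Radiation-inflated incidence and the attributable case fraction.

    ``incidence x (1 + err x n)``; the attributable fraction of incident
    cases is ``err x n / (1 + err x n)``.
    """
    n = np.asarray(cumulative_screens, dtype=float)
    if (n < 0).any():
        raise ValueError("cumulative screens must be non-negative")
    mult = 1.0 + excess_rr_per_screen * n
    return np.asarray(incidence) * mult, excess_rr_per_screen * n / mult


def cycle_transition(state, params: ModelParams, p_incidence, p_other,
                     screen_offered):
    """Apply one annual cycle to occupancy vector(s).

    ``state`` has shape (..., 15); ``p_incidence``/``p_other`` broadcast
    over the leading dimensions; ``screen_offered`` is boolean.  Returns
    ``(new_state, events)`` with events holding per-stratum screen counts,
    false positives, screen-detected mass per stage and new cases.
    Occupancy is conserved to machine precision.
    """
    s = np.array(state, dtype=float, copy=True)
    if (s < -1e-12).any():
        raise ValueError("negative occupancy")
    p_inc = np.asarray(p_incidence, dtype=float)
    p_oth = np.asarray(p_other, dtype=float)
    off = np.asarray(screen_offered, dtype=float)
    adh = params.adherence

    # 1. screening
    participants = off * adh * (s[..., HEALTHY] + s[..., U_SLICE].sum(axis=-1))
    detected = off[..., None] * adh * params.sensitivity * s[..., U_SLICE]
    s[..., U_SLICE] -= detected
    s[..., DNEW_SLICE] += detected
    false_pos = off * adh * (1.0 - params.specificity) * s[..., HEALTHY]

    # 2. clinical detection of remaining undetected disease
    clin = s[..., U_SLICE] * params._p_clin
    s[..., U_SLICE] -= clin
    s[..., DNEW_SLICE] += clin

    # 3. other-cause death in every alive state
    alive = s[..., :LC_DEATH]
    dead_other = alive * p_oth[..., None]
    s[..., :LC_DEATH] = alive - dead_other
    s[..., OTHER_DEATH] += dead_other.sum(axis=-1)

    # 4. new cancers + undetected lung-cancer death and stage progression
    new_cases = s[..., HEALTHY] * p_inc
    s[..., HEALTHY] -= new_cases
    lc_dead = s[..., U_SLICE] * params._p_lcd
    surv = s[..., U_SLICE] - lc_dead
    s[..., LC_DEATH] += lc_dead.sum(axis=-1)
    s[..., U_SLICE] = surv - surv * params._prog_out + surv @ params._prog_matrix
    s[..., 1] += new_cases  # new cancers enter undetected stage I

    # 5. aftercare lung-cancer death among previously diagnosed (post tunnel)
    after_dead = s[..., DPOST_SLICE] * params._p_after
    s[..., DPOST_SLICE] -= after_dead
    s[..., LC_DEATH] += after_dead.sum(axis=-1)

    events = {
        "screens": participants,
        "false_positives": false_pos,
        "screen_detected": detected,
        "new_cases": new_cases,
    }
    return s, events


@dataclass
class CohortStrata:
    """Vectorized per-(group x entry age x sex) cohort representation."""

    entry_age: np.ndarray
    sex: np.ndarray
    group: np.ndarray  # group label per stratum
    weight: np.ndarray
    tb_frac: np.ndarray
    emphysema_frac: np.ndarray
    i_b: np.ndarray  # baseline annual incidence rate per stratum
    hr_path: np.ndarray  # (S, horizon+1) incidence HR multiplier per cycle
    p_other_path: np.ndarray  # (S, horizon+1) per-cycle other-death probability
    horizon: int

    def __len__(self):
        return len(self.entry_age)


def build_strata(cohort_df: pd.DataFrame, rates: HazardRateTable,
                 risk_params: RiskModelParams, horizon: int = 30,
                 quit_smoking: bool = False, pack_year_rate: float = 1.0,
                 group_densities: dict | None = None) -> CohortStrata:
    """Aggregate an individual-level cohort into Markov strata.

    Baseline incidence per stratum is the risk group's observed incidence
    density; the per-cycle hazard-ratio path is the stratum mean of each
    member's relative-risk ratio as age advances (age-band HR clamped at
    the model's top 70-74 band) and, in the base case, as pack-years
    accumulate at ``pack_year_rate`` per year.  The quit-smoking scenario
    freezes pack-years so incidence rises with age only.
    """
    dens = group_densities or _GROUP_INCIDENCE_DENSITY
    df = cohort_df.reset_index(drop=True)
    n = len(df)
    cycles = np.arange(horizon + 1)

    # per-individual HR path (N, horizon+1), then averaged within stratum
    age0 = df["age"].to_numpy()
    py0 = df["pack_years"].to_numpy()
    hr_age0 = risk_params.hr_vector("age_band", age_band(age0))
    hr50 = risk_params.hr("pack_year_band", ">=50")
    hr_py0 = np.where(py0 >= 50, hr50, 1.0)
    hr_path = np.empty((n, horizon + 1))
    for t in cycles:
        a_t = np.minimum(age0 + t, 74)
        hr_age_t = risk_params.hr_vector("age_band", age_band(a_t))
        if quit_smoking:
            hr_py_t = hr_py0
        else:
            hr_py_t = np.where(py0 + pack_year_rate * t >= 50, hr50, 1.0)
        hr_path[:, t] = (hr_age_t / hr_age0) * (hr_py_t / hr_py0)

    df = df.assign(_hr=[row for row in hr_path])
    keys = ["group", "age", "sex"]
    grouped = df.groupby(keys, sort=True)
    S = grouped.ngroups
    out = {k: np.empty(S, dtype=object if k == "group" else float) for k in
           ("group", "age", "sex", "weight", "tb", "em", "ib")}
    hr_s = np.empty((S, horizon + 1))
    for i, ((g, a, sx), sub) in enumerate(grouped):
        out["group"][i] = g
        out["age"][i], out["sex"][i] = a, sx
        out["weight"][i] = len(sub) / n
        out["tb"][i] = sub["tb"].mean()
        out["em"][i] = sub["emphysema"].mean()
        out["ib"][i] = dens[g] / 1e5
        hr_s[i] = np.mean(np.stack(sub["_hr"].to_list()), axis=0)

    entry_age = out["age"].astype(int)
    sex = out["sex"].astype(int)
    p_other = np.zeros((S, horizon + 1))
    for t in range(1, horizon + 1):
        for i in range(S):
            h2 = competing_hazard(
                int(min(entry_age[i] + t - 1, rates.ages.max())), sex[i], rates,
                risk_params.smoker_allcause_rr, risk_params.adjust_allcause_first)
            p_other[i, t] = -np.expm1(-h2)

    return CohortStrata(
        entry_age=entry_age, sex=sex, group=out["group"],
        weight=out["weight"].astype(float), tb_frac=out["tb"].astype(float),
        emphysema_frac=out["em"].astype(float), i_b=out["ib"].astype(float),
        hr_path=hr_s, p_other_path=p_other, horizon=horizon,
    )


def _schedule_matrix(strategy: Strategy, strata: CohortStrata) -> np.ndarray:
    """Boolean (S, horizon+1) matrix of screen offers."""
    off = np.zeros((len(strata), strata.horizon + 1), dtype=bool)
    if not strategy.is_screening:
        return off
    cache = {}
    for i in range(len(strata)):
        key = (strata.group[i], strata.entry_age[i])
        if key not in cache:
            sched = build_schedule(strategy, key[0], int(key[1]), strata.horizon)
            cache[key] = sorted(sched.cycles)
        for c in cache[key]:
            off[i, c] = True
    return off


def _utility_paths(strata: CohortStrata, econ: EconParams) -> np.ndarray:
    """(S, horizon+1) healthy-state utility per stratum per cycle."""
    S, H = len(strata), strata.horizon
    u = np.zeros((S, H + 1))
    for t in range(1, H + 1):
        ages = strata.entry_age + t - 1
        base = baseline_utility(ages, strata.sex)
        u[:, t] = np.maximum(
            base - strata.tb_frac * econ.disutility_tb
            - strata.emphysema_frac * econ.disutility_emphysema, 0.0)
    return u


def run_strategy(strategy: Strategy, strata: CohortStrata, params: ModelParams,
                 econ: EconParams, horizon: int | None = None) -> StrategyOutcome:
    """Run the cohort model for one strategy; outcomes per 100,000 entrants."""
    horizon = horizon or strata.horizon
    S = len(strata)
    w = strata.weight
    state = np.zeros((S, N_STATES))
    state[:, HEALTHY] = 1.0

    offered = _schedule_matrix(strategy, strata)
    u_healthy = _utility_paths(strata, econ)
    stage_u = np.array([econ.utility_stage[s] for s in STAGES])
    cost_first = np.array([econ.cost_stage_first_year[s] for s in STAGES])
    cost_sub = np.array([econ.cost_stage_subsequent[s] for s in STAGES])

    cum_screens = np.zeros(S)
    tot = dict(cost=0.0, qaly=0.0, ly=0.0, screens=0.0, fp=0.0, od=0.0, rad=0.0)
    if strategy.is_screening and econ.charge_pre_diagnosis:
        tot["cost"] += econ.cost_pre_diagnosis * discount_factor(1, econ.discount_rate)
    alive_prev = np.ones(S)

    for t in range(1, horizon + 1):
        # advance the first-year tunnel from the previous cycle
        state[:, DPOST_SLICE] += state[:, DNEW_SLICE]
        state[:, DNEW_SLICE] = 0.0

        inc_rate = strata.i_b * strata.hr_path[:, t]
        adj_rate, att_frac = apply_radiation_risk(
            cum_screens, params.excess_rr_per_screen, inc_rate)
        p_inc = -np.expm1(-adj_rate)
        state, ev = cycle_transition(
            state, params, p_inc, strata.p_other_path[:, t], offered[:, t])
        cum_screens = cum_screens + offered[:, t] * params.adherence

        det = ev["screen_detected"]
        od_mass = det[:, 0] if params.overdiagnosis_stage_i_only else det.sum(axis=1)
        tot["screens"] += float(w @ ev["screens"])
        tot["fp"] += float(w @ ev["false_positives"])
        tot["od"] += params.overdiagnosis_rate * float(w @ od_mass)
        tot["rad"] += float(w @ (ev["new_cases"] * att_frac))

        df_t = discount_factor(t, econ.discount_rate)
        if econ.undetected_uses_stage_utility:
            u_undet = np.broadcast_to(stage_u, (S, 4))
        else:
            u_undet = u_healthy[:, t][:, None]
        qaly_t = (state[:, HEALTHY] * u_healthy[:, t]
                  + (state[:, U_SLICE] * u_undet).sum(axis=1)
                  + (state[:, DNEW_SLICE] * stage_u).sum(axis=1)
                  + (state[:, DPOST_SLICE] * stage_u).sum(axis=1)
                  - ev["false_positives"] * econ.fp_disutility * econ.fp_duration_years)
        cost_t = (state[:, U_SLICE].sum(axis=1) * econ.cost_background
                  + state[:, DNEW_SLICE] @ cost_first
                  + state[:, DPOST_SLICE] @ cost_sub
                  + ev["screens"] * econ.cost_ldct
                  + ev["false_positives"] * econ.cost_biopsy)
        tot["qaly"] += df_t * float(w @ qaly_t)
        tot["cost"] += df_t * float(w @ cost_t)

        alive = state[:, :LC_DEATH].sum(axis=1)
        tot["ly"] += float(w @ (0.5 * (alive_prev + alive)))
        alive_prev = alive

        occ = state.sum(axis=1)
        if not np.allclose(occ, 1.0, atol=1e-9):
            raise AssertionError(f"occupancy drifted at cycle {t}: {occ}")

    for v in tot.values():
        if not np.isfinite(v):
            raise FloatingPointError("non-finite accumulator in Markov run")

    lc_deaths = float(w @ state[:, LC_DEATH])
    return StrategyOutcome(
        strategy=strategy.name,
        total_cost=tot["cost"] * 1e5,
        total_qalys=tot["qaly"] * 1e5,
        life_years=tot["ly"] * 1e5,
        lc_deaths=lc_deaths * 1e5,
        screens=tot["screens"] * 1e5,
        false_positives=tot["fp"] * 1e5,
        overdiagnosed=tot["od"] * 1e5,
        radiation_lc=tot["rad"] * 1e5,
    )


def run_all_strategies(strategies, strata: CohortStrata, params: ModelParams,
                       econ: EconParams) -> list[StrategyOutcome]:
    return [run_strategy(s, strata, params, econ) for s in strategies]
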