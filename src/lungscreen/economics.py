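"""Cost and utility accounting with discounting and half-cycle correction.

All costs are 2022 Chinese yuan (CNY) from a health-system perspective:
one-off risk-scoring (pre-diagnosis) cost, per-screen LDCT cost, biopsy
work-up for false positives, stage-specific lung-cancer care split into a
first treatment year and subsequent years, and background medical
treatment for symptomatic-but-undiagnosed disease.  Utilities are EQ-5D
style weights: an age/sex baseline for smokers without lung cancer, minus
comorbidity decrements (tuberculosis, emphysema), stage-specific weights
after diagnosis, and a transient decrement for a false-positive result.

Future costs and QALYs are discounted at 5%/year (range 0-8%) with a
half-cycle correction: cycle ``t`` accruals are discounted to the cycle
midpoint, ``(1+rate)^-(t-0.5)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EconParams", "discount_factor", "cycle_cost", "cycle_utility",
           "baseline_utility", "WTP_DEFAULT"]

#: Willingness-to-pay threshold: 3 x 2021 per-capita GDP of China (CNY/QALY).
WTP_DEFAULT = 242_928.0
GDP_PER_CAPITA_2021 = 80_976.0

STAGES = ("I", "II", "III", "IV")

# Baseline utility for smokers without lung cancer, by sex and age band.
_BASE_UTILITY = {
    1: [(50, 0.99), (60, 0.984), (70, 0.976), (200, 0.947)],
    2: [(50, 0.988), (60, 0.982), (70, 0.964), (200, 0.936)],
}


@dataclass
class EconParams:
    """Cost (CNY 2022) and utility inputs with base-case defaults."""

    cost_pre_diagnosis: float = 613.3
    cost_ldct: float = 239.97
    cost_biopsy: float = 1202.9
    cost_stage_first_year: dict = field(default_factory=lambda: {
        "I": 83_984.91, "II": 97_435.6, "III": 90_813.2, "IV": 86_484.70})
    cost_stage_subsequent: dict = field(default_factory=lambda: {
        "I": 19_967.12, "II": 15_888.82, "III": 32_472.69, "IV": 54_962.59})
    cost_background: float = 5348.1
    disutility_tb: float = 0.01
    disutility_emphysema: float = 0.052
    utility_stage: dict = field(default_factory=lambda: {
        "I": 0.85, "II": 0.75, "III": 0.69, "IV": 0.69})
    fp_disutility: float = 0.063
    fp_duration_years: float = 0.25
    discount_rate: float = 0.05
    wtp: float = WTP_DEFAULT
    #: charge the one-off risk-scoring cost to every screening strategy
    #: (including the status quo, as a questionnaire cost); never to no-screening
    charge_pre_diagnosis: bool = True
    #: utility carried by undetected (undiagnosed) lung cancer: the age/sex
    #: baseline ("unaware") rather than the stage utility; configurable
    undetected_uses_stage_utility: bool = False

    def __post_init__(self):
        if not 0 <= self.discount_rate <= 0.08:
            raise ValueError(f"discount rate {self.discount_rate} outside [0, 0.08]")
        costs = [self.cost_pre_diagnosis, self.cost_ldct, self.cost_biopsy,
                 self.cost_background, *self.cost_stage_first_year.values(),
                 *self.cost_stage_subsequent.values()]
        if any(c < 0 for c in costs):
            raise ValueError("costs must be non-negative")
        utils = [*self.utility_stage.values()]
        if any(not 0 <= u <= 1 for u in utils):
            raise ValueError("stage utilities must lie in [0, 1]")


def baseline_utility(age, sex) -> np.ndarray:
    """Age/sex baseline utility for smokers without lung cancer."""
    age = np.asarray(age)
    sex = np.asarray(sex)
    out = np.empty(np.broadcast(age, sex).shape)
    for s, bands in _BASE_UTILITY.items():
        mask = sex == s
        val = np.full(age.shape, bands[-1][1])
        for upper, u in reversed(bands):
            val = np.where(age <= upper, u, val)
        out[mask] = np.broadcast_to(val, out.shape)[mask]
    if out.ndim == 0:
        return float(out)
    return out


def discount_factor(cycle: int, rate: float, half_cycle: bool = True) -> float:
    """Discount factor for cycle ``t``: (1+rate)^-(t-0.5) with half-cycle
    correction (for t >= 1), else (1+rate)^-t."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    if cycle < 0:
        raise ValueError("cycle must be non-negative")
    exponent = cycle - 0.5 if (half_cycle and cycle >= 1) else cycle
    return float((1.0 + rate) ** -exponent)


def cycle_cost(state: str, tunnel_phase: str | None, events: dict, econ: EconParams) -> float:
    """Undiscounted cost accrued by one person in one cycle.

    ``state`` is 'healthy', 'undetected_<stage>', 'diagnosed_<stage>',
    'lc_death' or 'other_death'; ``tunnel_phase`` for diagnosed states is
    'first' or 'subsequent'.  ``events`` may flag screened / fp / entry.
    """
    cost = 0.0
    if events.get("screened"):
        cost += econ.cost_ldct
    if events.get("fp"):
        cost += econ.cost_biopsy
    if events.get("entry"):
        cost += econ.cost_pre_diagnosis
    if state.startswith("undetected_"):
        cost += econ.cost_background
    elif state.startswith("diagnosed_"):
        stage = state.split("_", 1)[1]
        if stage not in STAGES:
            raise ValueError(f"unknown stage in state {state!r}")
        table = econ.cost_stage_first_year if tunnel_phase == "first" else econ.cost_stage_subsequent
        cost += table[stage]
    elif state not in ("healthy", "lc_death", "other_death"):
        raise ValueError(f"unknown state {state!r}")
    return cost


def cycle_utility(state: str, age: int, sex: int, comorbidity: dict | None,
                  fp_event: bool, econ: EconParams) -> float:
    """QALY weight for one person-cycle (deaths contribute 0)."""
    if state in ("lc_death", "other_death"):
        return 0.0
    if state.startswith("diagnosed_") or (
        state.startswith("undetected_") and econ.undetected_uses_stage_utility
    ):
        stage = state.split("_", 1)[1]
        u = econ.utility_stage[stage]
    else:
        u = baseline_utility(age, sex)
        comorbidity = comorbidity or {}
        if comorbidity.get("tb"):
            u -= econ.disutility_tb
        if comorbidity.get("emphysema"):
            u -= econ.disutility_emphysema
    if fp_event:
        u -= econ.fp_disutility * econ.fp_duration_years
    return float(max(u, 0.0))
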