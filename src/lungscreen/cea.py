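"""Cost-effectiveness synthesis: ICER, iNMB, dominance, frontier, benefit-harm.

Strategies are compared on aggregate discounted cost and QALYs per 100,000
entrants.  The incremental net monetary benefit (iNMB) of strategy A vs B
is ``(dQALY * WTP - dCost) / 100,000`` CNY per person.  The efficiency
frontier is constructed by removing strictly dominated strategies (another
strategy is no more costly and no less effective) and then extended-
dominated strategies (a blend of two other strategies dominates), leaving
a chain of non-decreasing incremental cost-effectiveness ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .economics import WTP_DEFAULT

__all__ = ["StrategyOutcome", "icer", "inmb", "efficiency_frontier",
           "benefit_harm_summary", "cea_table", "benefit_harm_table",
           "DOMINATED", "COST_SAVING", "UNDEFINED"]

DOMINATED = "dominated"
COST_SAVING = "cost-saving"
UNDEFINED = "undefined"

PER = 100_000.0


@dataclass
class StrategyOutcome:
    """Aggregate outcomes of one strategy, per 100,000 entrants.

    ``total_cost`` and ``total_qalys`` are discounted; ``life_years`` are
    undiscounted.  Harm counters accumulate over the whole 30-cycle run.
    """

    strategy: str
    total_cost: float
    total_qalys: float
    life_years: float
    lc_deaths: float
    screens: float
    false_positives: float
    overdiagnosed: float
    radiation_lc: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ValueError(f"non-finite outcome {f.name} for {self.strategy}")


def icer(delta_cost: float, delta_qaly: float):
    """Incremental cost-effectiveness ratio or a dominance label.

    Returns CNY/QALY when dQALY > 0 and dCost >= 0, ``cost-saving`` when
    the strategy is cheaper and more effective, ``dominated`` when it is
    no cheaper and no more effective, and ``undefined`` for a tie.
    """
    if delta_qaly == 0 and delta_cost == 0:
        return UNDEFINED
    if delta_qaly > 0:
        return COST_SAVING if delta_cost < 0 else delta_cost / delta_qaly
    return DOMINATED


def inmb(delta_qaly: float, delta_cost: float, wtp: float = WTP_DEFAULT,
         scale: float = PER) -> float:
    """Incremental net monetary benefit, CNY per person.

    Inputs are per-``scale`` aggregates (per 100,000 by default); a
    positive value means cost-effective vs the comparator at ``wtp``.
    """
    if wtp < 0:
        raise ValueError("WTP must be non-negative")
    return (delta_qaly * wtp - delta_cost) / scale


def efficiency_frontier(points, tie_break_by_name: bool = True):
    """Classify (name, cost, qaly) points for the efficiency frontier.

    Returns ``(frontier, labels)`` where ``frontier`` is the ordered list
    of on-frontier names with their segment ICERs (vs the preceding
    frontier member) and ``labels`` maps every name to ``on-frontier``,
    ``dominated`` or ``extended-dominated``.  The anchor is the least
    costly strategy; segment ICERs along the frontier are non-decreasing.
    """
    pts = [(str(n), float(c), float(q)) for n, c, q in points]
    if len(pts) < 2:
        raise ValueError("frontier needs at least two strategies")
    pts.sort(key=lambda p: (p[1], -p[2], p[0] if tie_break_by_name else ""))
    labels = {}
    # strict dominance: sorted by (cost asc, qaly desc), a point is dominated
    # iff some earlier point reaches at least its qaly at no greater cost
    survivors = []
    best_q = -np.inf
    for name, c, q in pts:
        if q <= best_q:
            labels[name] = DOMINATED
        else:
            survivors.append((name, c, q))
            best_q = q
    # extended dominance: drop points until segment ICERs are non-decreasing
    changed = True
    while changed and len(survivors) > 2:
        changed = False
        for i in range(1, len(survivors) - 1):
            n0, c0, q0 = survivors[i - 1]
            n1, c1, q1 = survivors[i]
            n2, c2, q2 = survivors[i + 1]
            icer_in = (c1 - c0) / (q1 - q0)
            icer_out = (c2 - c1) / (q2 - q1)
            if icer_in > icer_out:
                labels[n1] = "extended-dominated"
                survivors.pop(i)
                changed = True
                break
    frontier = []
    for i, (name, c, q) in enumerate(survivors):
        labels[name] = "on-frontier"
        seg = None if i == 0 else (c - survivors[i - 1][1]) / (q - survivors[i - 1][2])
        frontier.append({"strategy": name, "cost": c, "qaly": q, "icer_vs_previous": seg})
    return frontier, labels


def benefit_harm_summary(outcome: StrategyOutcome, baseline: StrategyOutcome) -> dict:
    """Screening efficiency ratios vs a no-screening baseline.

    ``screens_per_death_averted`` and ``screens_per_ly_gained`` are NaN
    when nothing is averted/gained; mortality reduction is in percent.
    """
    deaths_averted = baseline.lc_deaths - outcome.lc_deaths
    ly_gained = outcome.life_years - baseline.life_years
    return {
        "strategy": outcome.strategy,
        "screens": outcome.screens,
        "deaths_averted": deaths_averted,
        "mortality_reduction_pct": (
            deaths_averted / baseline.lc_deaths * 100.0 if baseline.lc_deaths > 0 else float("nan")
        ),
        "screens_per_death_averted": (
            outcome.screens / deaths_averted if deaths_averted > 0 else float("nan")
        ),
        "ly_gained": ly_gained,
        "screens_per_ly_gained": (
            outcome.screens / ly_gained if ly_gained > 0 else float("nan")
        ),
        "overdiagnosed": outcome.overdiagnosed,
        "radiation_lc": outcome.radiation_lc,
        "false_positives": outcome.false_positives,
    }


def cea_table(outcomes: list[StrategyOutcome], status_quo: str,
              wtp: float = WTP_DEFAULT) -> pd.DataFrame:
    """Strategy-level cost-effectiveness table (ordered by QALYs).

    Columns mirror the standard published layout: cost and QALYs per
    100,000 people, increments and ICER vs the status quo and vs the
    frontier predecessor, iNMB per person, and the dominance label.
    """
    by_name = {o.strategy: o for o in outcomes}
    if status_quo not in by_name:
        raise ValueError(f"status quo strategy {status_quo!r} missing from outcomes")
    sq = by_name[status_quo]
    frontier, labels = efficiency_frontier(
        [(o.strategy, o.total_cost, o.total_qalys) for o in outcomes])
    frontier_names = [f["strategy"] for f in frontier]
    seg_icer = {f["strategy"]: f["icer_vs_previous"] for f in frontier}
    rows = []
    for o in sorted(outcomes, key=lambda o: o.total_qalys):
        dc, dq = o.total_cost - sq.total_cost, o.total_qalys - sq.total_qalys
        row = {
            "strategy": o.strategy,
            "cost_per_100k": o.total_cost,
            "qalys_per_100k": o.total_qalys,
            "incr_cost_vs_sq": dc,
            "incr_qaly_vs_sq": dq,
            "icer_vs_sq": icer(dc, dq),
            "inmb_vs_sq": inmb(dq, dc, wtp),
            "frontier": labels[o.strategy],
            "icer_vs_frontier_pred": seg_icer.get(o.strategy),
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["frontier"] = frontier_names
    return df


def benefit_harm_table(outcomes: list[StrategyOutcome], baseline_name: str) -> pd.DataFrame:
    by_name = {o.strategy: o for o in outcomes}
    base = by_name[baseline_name]
    rows = [benefit_harm_summary(o, base) for o in outcomes if o.strategy != baseline_name]
    return pd.DataFrame(rows)
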