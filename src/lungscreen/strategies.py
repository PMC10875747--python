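"""Screening-strategy grammar, enumeration and per-group schedules.

A risk-based strategy assigns one screening interval to each of the four
risk groups, written ``H{i}-MH{i}-LM{i}-L{i}`` where ``i`` is ``1``
(annual), ``2`` (biennial), ``3`` (triennial), ``one-off`` (a single
baseline screen) or ``none``.  The high-risk group is always screened
annually and a lower-risk group is never screened more frequently than a
higher-risk one, under the frequency order
annual > biennial > triennial > one-off > none.  Together with
``no_screening`` this yields exactly 36 strategies (34 risk-based plus the
status quo ``H1-MH1-LM1-L1`` and no screening).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

from .risk import GROUPS

__all__ = ["Strategy", "ScreeningSchedule", "parse_strategy", "enumerate_strategies",
           "build_schedule", "NO_SCREENING", "STATUS_QUO", "INTERVALS"]

#: Interval codes ordered from most to least frequent.
INTERVALS = ("1", "2", "3", "one-off", "none")
_FREQ_RANK = {code: i for i, code in enumerate(INTERVALS)}

NO_SCREENING = "no_screening"
STATUS_QUO = "H1-MH1-LM1-L1"

#: Screening starts at entry (cycle 1) and stops once attained age exceeds 74.
STOP_AGE = 74


class StrategyParseError(ValueError):
    pass


@dataclass(frozen=True)
class Strategy:
    """A named mapping of risk groups to screening intervals."""

    name: str
    intervals: tuple  # interval code per group, in GROUPS order

    @property
    def is_screening(self) -> bool:
        return self.name != NO_SCREENING

    def interval(self, group: str) -> str:
        return self.intervals[GROUPS.index(group)]

    def canonical_name(self) -> str:
        if not self.is_screening:
            return NO_SCREENING
        return "-".join(f"{g}{c}" for g, c in zip(GROUPS, self.intervals))


def parse_strategy(name: str) -> Strategy:
    """Parse a strategy name, enforcing grammar and frequency monotonicity."""
    if name == NO_SCREENING:
        return Strategy(name=NO_SCREENING, intervals=("none",) * 4)
    tokens = name.split("-")
    # 'one-off' itself contains a dash: re-join split fragments
    merged, i = [], 0
    while i < len(tokens):
        if tokens[i].endswith("one") and i + 1 < len(tokens) and tokens[i + 1] == "off":
            merged.append(tokens[i] + "-off")
            i += 2
        else:
            merged.append(tokens[i])
            i += 1
    if len(merged) != 4:
        raise StrategyParseError(f"expected 4 group tokens in {name!r}, got {merged}")
    codes = []
    for g, tok in zip(GROUPS, merged):
        if not tok.startswith(g):
            raise StrategyParseError(f"token {tok!r} does not start with group {g!r}")
        code = tok[len(g):]
        if code not in INTERVALS:
            raise StrategyParseError(f"unknown interval {code!r} for group {g}")
        codes.append(code)
    if codes[0] != "1":
        raise StrategyParseError(f"high-risk group must be screened annually in {name!r}")
    for (g_hi, c_hi), (g_lo, c_lo) in zip(zip(GROUPS, codes), zip(GROUPS[1:], codes[1:])):
        if _FREQ_RANK[c_lo] < _FREQ_RANK[c_hi]:
            raise StrategyParseError(
                f"group {g_lo} screened more frequently ({c_lo}) than {g_hi} ({c_hi})"
            )
    strat = Strategy(name=name, intervals=tuple(codes))
    assert strat.canonical_name() == name
    return strat


def enumerate_strategies() -> list[Strategy]:
    """All 36 strategies: no screening + H-annual frequency-monotone mappings."""
    out = [parse_strategy(NO_SCREENING)]
    for trio in combinations_with_replacement(INTERVALS, 3):
        # combinations_with_replacement yields non-decreasing frequency rank,
        # i.e. non-increasing frequency from MH to L, as required
        name = "-".join(f"{g}{c}" for g, c in zip(GROUPS, ("1",) + trio))
        out.append(parse_strategy(name))
    assert len(out) == 36
    return out


@dataclass(frozen=True)
class ScreeningSchedule:
    """Cycle indices (1-based) at which a screen is offered."""

    cycles: frozenset

    def offered(self, cycle: int) -> bool:
        return cycle in self.cycles


def build_schedule(strategy: Strategy, group: str, entry_age: int, horizon: int = 30) -> ScreeningSchedule:
    """Screens at cycles 1, 1+k, 1+2k, ... while attained age <= 74.

    The first screen is the baseline screen at cycle 1; attained age at
    cycle ``c`` is ``entry_age + c - 1``.  ``one-off`` screens once at
    baseline, ``none`` never.
    """
    if not 50 <= entry_age <= 74:
        raise ValueError(f"entry age {entry_age} outside 50-74")
    code = strategy.interval(group) if strategy.is_screening else "none"
    if code == "none":
        return ScreeningSchedule(frozenset())
    if code == "one-off":
        return ScreeningSchedule(frozenset({1}))
    k = int(code)
    cycles = [c for c in range(1, horizon + 1, k) if entry_age + c - 1 <= STOP_AGE]
    return ScreeningSchedule(frozenset(cycles))
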