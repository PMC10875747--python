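"""Individual lung-cancer risk projection and risk stratification.

Implements a Gail-type absolute-risk model for heavy smokers: a
multiplicative relative risk ``r`` built from per-factor hazard ratios
(age band, sex, pack-year band, tuberculosis, emphysema), a baseline
lung-cancer hazard ``h1`` obtained by deflating registry incidence by the
population-attributable risk (Bruzzi's formula), a competing non-lung-cancer
mortality hazard ``h2``, and the absolute 5-year risk

    P(a, r, j) = [h1j*r / (h1j*r + h2j)] * [1 - exp(-5*(h1j*r + h2j))]

i.e. the probability that, of two competing exponential clocks with rates
``h1j*r`` (lung-cancer onset) and ``h2j`` (death from other causes), the
cancer clock fires first within 5 years.  Cohorts are stratified into four
risk groups (H, MH, LM, L) either by empirical quartiles of the absolute
risk or by fixed published thresholds.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "Individual",
    "HazardRateTable",
    "RiskModelParams",
    "RiskStratification",
    "AGE_BANDS",
    "age_band",
    "pack_year_band",
    "relative_risk",
    "population_attributable_risk",
    "baseline_lc_hazard",
    "competing_hazard",
    "absolute_5yr_risk",
    "stratify",
    "GROUPS",
]

#: Risk groups ordered from highest to lowest risk.
GROUPS = ("H", "MH", "LM", "L")

#: 5-year age bands covered by the relative-risk model (entry ages 50-74).
AGE_BANDS = ("50-54", "55-59", "60-64", "65-69", "70-74")

#: Default risk thresholds (absolute 5-year risk) separating H/MH, MH/LM, LM/L.
DEFAULT_THRESHOLDS = (0.0170, 0.0103, 0.0049)

#: All-cause mortality relative risk of heavy smokers vs the general population.
SMOKER_ALLCAUSE_RR = {1: 1.33, 2: 1.44}


class Sex(enum.IntEnum):
    MALE = 1
    FEMALE = 2


class RiskConfigError(ValueError):
    """Raised for unknown factor levels or inconsistent risk-model inputs."""


def age_band(age) -> np.ndarray:
    """Map age(s) to the model's 5-year band label, clamping outside 50-74."""
    age = np.asarray(age)
    idx = np.clip((age - 50) // 5, 0, len(AGE_BANDS) - 1).astype(int)
    return np.asarray(AGE_BANDS)[idx]


def pack_year_band(pack_years) -> np.ndarray:
    """Pack-year exposure band: '30-49' (reference) or '>=50'."""
    return np.where(np.asarray(pack_years) >= 50.0, ">=50", "30-49")


@dataclass
class Individual:
    """A heavy smoker eligible for LDCT screening.

    Eligibility: age 50-74 at entry and >=30 pack-years.
    """

    age: int
    sex: Sex
    pack_years: float
    tb_history: bool = False
    emphysema_history: bool = False
    relative_risk: float | None = None
    abs_risk_5yr: float | None = None
    risk_group: str | None = None

    def __post_init__(self):
        if not 50 <= self.age <= 74:
            raise ValueError(f"entry age {self.age} outside 50-74")
        if self.pack_years < 30:
            raise ValueError(f"pack-years {self.pack_years} below heavy-smoker minimum 30")
        if self.relative_risk is not None and self.relative_risk <= 0:
            raise ValueError("relative risk must be positive")
        if self.abs_risk_5yr is not None and not 0 <= self.abs_risk_5yr <= 1:
            raise ValueError("absolute risk must lie in [0, 1]")


class HazardRateTable:
    """Annual rates per person-year, indexed by (age, sex).

    Columns: ``lc_incidence`` (registry lung-cancer incidence),
    ``lc_mortality`` (lung-cancer mortality) and ``all_cause_mortality``.
    All rates are annual *rates*, not probabilities; the per-cycle
    conversion ``p = 1 - exp(-rate)`` happens in the Markov engine.
    """

    COLUMNS = ("lc_incidence", "lc_mortality", "all_cause_mortality")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        required = {"age", "sex", *self.COLUMNS}
        missing = required - set(frame.columns)
        if missing:
            raise RiskConfigError(f"rate table missing columns: {sorted(missing)}")
        if (frame[list(self.COLUMNS)] < 0).any().any():
            raise RiskConfigError("rate table contains negative rates")
        bad = frame["all_cause_mortality"] < frame["lc_mortality"]
        if bad.any():
            rows = frame.loc[bad, ["age", "sex"]].to_records(index=False)
            raise RiskConfigError(
                f"all-cause mortality below lung-cancer mortality at {list(rows)[:5]}"
            )
        self.frame = frame.set_index(["age", "sex"]).sort_index()

    @classmethod
    def from_csv(cls, path) -> "HazardRateTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.reset_index().to_csv(path, index=False)

    @property
    def ages(self) -> np.ndarray:
        return self.frame.index.get_level_values("age").unique().to_numpy()

    def rate(self, age: int, sex: int, column: str, clamp: bool = False) -> float:
        """Single rate lookup.  ``clamp=True`` clips age to the covered range."""
        if clamp:
            age = int(np.clip(age, self.ages.min(), self.ages.max()))
        try:
            return float(self.frame.loc[(int(age), int(sex)), column])
        except KeyError:
            raise KeyError(f"no rate for age={age}, sex={sex}") from None

    def column_by_age(self, sex: int, column: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (ages, values) arrays for one sex, sorted by age."""
        sub = self.frame.xs(int(sex), level="sex")[column].sort_index()
        return sub.index.to_numpy(), sub.to_numpy()


@dataclass
class RiskModelParams:
    """Hazard ratios, PAR and the smoker all-cause adjustment.

    ``hazard_ratio_table`` is a DataFrame with columns (factor, level, hr);
    the reference level of every factor must carry hr == 1.
    ``case_category_weights`` (optional) is a DataFrame with columns
    (weight, rr) describing the proportion of lung-cancer cases in each
    joint risk-factor category and that category's relative risk vs the
    all-lowest-risk category; used by :func:`population_attributable_risk`.
    """

    hazard_ratio_table: pd.DataFrame
    par: float = 0.0
    smoker_allcause_rr: dict = field(default_factory=lambda: dict(SMOKER_ALLCAUSE_RR))
    case_category_weights: pd.DataFrame | None = None
    #: apply the smoker RR to all-cause mortality before subtracting lung-cancer
    #: mortality (the stated order); False applies the RR after subtraction.
    adjust_allcause_first: bool = True

    def __post_init__(self):
        t = self.hazard_ratio_table
        required = {"factor", "level", "hr"}
        if not required <= set(t.columns):
            raise RiskConfigError("hazard ratio table needs columns factor, level, hr")
        if (t["hr"] <= 0).any():
            raise RiskConfigError("hazard ratios must be positive")
        if not 0 <= self.par < 1:
            raise RiskConfigError(f"PAR {self.par} outside [0, 1)")
        self._hr = {
            (str(f), str(lv)): float(h)
            for f, lv, h in zip(t["factor"], t["level"], t["hr"])
        }

    def hr(self, factor: str, level) -> float:
        key = (str(factor), str(level))
        try:
            return self._hr[key]
        except KeyError:
            raise RiskConfigError(
                f"unknown level {level!r} for factor {factor!r} in hazard ratio table"
            ) from None

    def hr_vector(self, factor: str, levels) -> np.ndarray:
        return np.array([self.hr(factor, lv) for lv in np.asarray(levels).ravel()])


def _factor_levels(age, sex, pack_years, tb, emphysema):
    return {
        "age_band": age_band(age),
        "sex": np.asarray(sex).astype(int).astype(str),
        "pack_year_band": pack_year_band(pack_years),
        "tb": np.where(np.asarray(tb).astype(bool), "yes", "no"),
        "emphysema": np.where(np.asarray(emphysema).astype(bool), "yes", "no"),
    }


def relative_risk(individual, params: RiskModelParams):
    """Multiplicative relative risk vs the all-reference individual.

    Accepts an :class:`Individual` (returns a float) or a cohort DataFrame
    with columns age, sex, pack_years, tb, emphysema (returns an ndarray).
    """
    if isinstance(individual, Individual):
        levels = _factor_levels(
            [individual.age], [int(individual.sex)], [individual.pack_years],
            [individual.tb_history], [individual.emphysema_history],
        )
        r = np.ones(1)
        for factor, lvl in levels.items():
            r *= params.hr_vector(factor, lvl)
        return float(r[0])
    df = individual
    levels = _factor_levels(
        df["age"].to_numpy(), df["sex"].to_numpy(), df["pack_years"].to_numpy(),
        df["tb"].to_numpy(), df["emphysema"].to_numpy(),
    )
    r = np.ones(len(df))
    for factor, lvl in levels.items():
        r *= params.hr_vector(factor, lvl)
    return r


def population_attributable_risk(weights, relative_risks) -> float:
    """Bruzzi's population-attributable risk: PAR = 1 - sum_c rho_c / RR_c.

    ``weights`` are the proportions of lung-cancer cases falling in each
    joint risk-factor category and ``relative_risks`` the category relative
    risks vs the all-lowest-risk category.
    """
    rho = np.asarray(weights, dtype=float)
    rr = np.asarray(relative_risks, dtype=float)
    if rho.shape != rr.shape:
        raise RiskConfigError("weights and relative risks must align")
    if abs(rho.sum() - 1.0) > 1e-6:
        raise RiskConfigError(f"case-category weights sum to {rho.sum():.8f}, not 1")
    if (rr <= 0).any():
        raise RiskConfigError("category relative risks must be positive")
    return float(1.0 - np.sum(rho / rr))


def baseline_lc_hazard(age: int, sex: int, rates: HazardRateTable, par: float) -> float:
    """Factor-free baseline lung-cancer hazard h1j = incidence * (1 - PAR)."""
    if not 0 <= par < 1:
        raise RiskConfigError(f"PAR {par} outside [0, 1)")
    return rates.rate(age, sex, "lc_incidence") * (1.0 - par)


def competing_hazard(
    age: int,
    sex: int,
    rates: HazardRateTable,
    smoker_allcause_rr=None,
    adjust_allcause_first: bool = True,
) -> float:
    """Non-lung-cancer mortality hazard h2j for heavy smokers.

    Default order (as stated for the source rates): inflate all-cause
    mortality by the smoker relative risk, then subtract lung-cancer
    mortality.  ``adjust_allcause_first=False`` subtracts first.
    """
    rr_map = smoker_allcause_rr or SMOKER_ALLCAUSE_RR
    rr = float(rr_map[int(sex)]) if isinstance(rr_map, dict) else float(rr_map)
    acm = rates.rate(age, sex, "all_cause_mortality")
    lcm = rates.rate(age, sex, "lc_mortality")
    h2 = acm * rr - lcm if adjust_allcause_first else (acm - lcm) * rr
    if h2 < 0:
        raise RiskConfigError(
            f"negative competing hazard at age={age}, sex={sex}: "
            "all-cause and lung-cancer mortality tables are inconsistent"
        )
    return h2


def absolute_5yr_risk(h1, r, h2):
    """Absolute 5-year lung-cancer risk under competing mortality.

    P = [h1*r / (h1*r + h2)] * [1 - exp(-5*(h1*r + h2))].  Vectorized;
    returns 0 where h1 == 0.
    """
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = np.asarray(r, dtype=float)
    if (h1 < 0).any() or (h2 < 0).any():
        raise RiskConfigError("hazards must be non-negative")
    if (r <= 0).any():
        raise RiskConfigError("relative risk must be positive")
    total = h1 * r + h2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, (h1 * r) / np.where(total > 0, total, 1.0), 0.0)
        p = p * -np.expm1(-5.0 * total)
    if p.ndim == 0:
        return float(p)
    return p


def cohort_absolute_risk(df: pd.DataFrame, rates: HazardRateTable,
                         params: RiskModelParams) -> pd.DataFrame:
    """Attach relative risk and absolute 5-year risk to a cohort frame.

    Returns a copy with columns ``relative_risk`` and ``abs_risk_5yr``.
    """
    out = df.copy()
    r = relative_risk(out, params)
    h1 = np.array([
        baseline_lc_hazard(int(a), int(s), rates, params.par)
        for a, s in zip(out["age"], out["sex"])
    ])
    h2 = np.array([
        competing_hazard(int(a), int(s), rates, params.smoker_allcause_rr,
                         params.adjust_allcause_first)
        for a, s in zip(out["age"], out["sex"])
    ])
    out["relative_risk"] = r
    out["abs_risk_5yr"] = absolute_5yr_risk(h1, r, h2)
    return out


def bruzzi_params_from_cohort(cohort_df: pd.DataFrame, hazard_ratio_table: pd.DataFrame,
                              group_densities: dict) -> RiskModelParams:
    """Risk-model parameters with the PAR from the cohort's case distribution.

    Case-category weights are simulated from the observed group incidence
    densities: each individual contributes expected cases proportional to
    their risk group's density, and their joint risk-factor category's
    relative risk is the multiplicative HR product.  Bruzzi's formula then
    gives PAR = 1 - sum_i rho_i / r_i.
    """
    params = RiskModelParams(hazard_ratio_table=hazard_ratio_table, par=0.0)
    r = relative_risk(cohort_df, params)
    dens = cohort_df["group"].map(group_densities).to_numpy(dtype=float)
    rho = dens / dens.sum()
    par = population_attributable_risk(rho, r)
    par = min(max(par, 0.0), 1.0 - 1e-9)
    return dataclasses.replace(params, par=par)


@dataclass
class RiskStratification:
    """Result of partitioning a cohort into the four risk groups."""

    thresholds: tuple
    labels: np.ndarray
    group_sizes: dict

    def __post_init__(self):
        t = self.thresholds
        if not (t[0] > t[1] > t[2]):
            raise RiskConfigError(f"thresholds must be strictly decreasing, got {t}")


def stratify(abs_risks, mode: str = "quartile", thresholds=DEFAULT_THRESHOLDS) -> RiskStratification:
    """Partition individuals into H/MH/LM/L by absolute 5-year risk.

    ``quartile`` ranks by risk (descending, stable tie-break on input
    order) and splits into four groups as equal in size as possible, H
    being the top quarter.  ``fixed_thresholds`` applies the given
    cut-points with ties going to the higher-risk group (>= semantics).
    """
    risks = np.asarray(abs_risks, dtype=float)
    n = risks.size
    if n == 0:
        raise RiskConfigError("cannot stratify an empty cohort")
    labels = np.empty(n, dtype=object)
    if mode == "fixed_thresholds":
        hi, mid, lo = thresholds
        labels[risks >= hi] = "H"
        labels[(risks >= mid) & (risks < hi)] = "MH"
        labels[(risks >= lo) & (risks < mid)] = "LM"
        labels[risks < lo] = "L"
        thr = tuple(thresholds)
    elif mode == "quartile":
        order = np.argsort(-risks, kind="stable")
        bounds = [round(n * k / 4) for k in range(5)]
        for gi, g in enumerate(GROUPS):
            labels[order[bounds[gi]:bounds[gi + 1]]] = g
        # empirical cut-points: lowest risk inside each of the top three groups
        thr = tuple(
            float(risks[order[bounds[k + 1] - 1]]) if bounds[k + 1] > bounds[k] else np.nan
            for k in range(3)
        )
        if not (thr[0] > thr[1] > thr[2]):
            # degenerate ties: fall back to nominal decreasing placeholders
            thr = (3.0, 2.0, 1.0)
    else:
        raise ValueError(f"unknown stratification mode {mode!r}")
    sizes = {g: int((labels == g).sum()) for g in GROUPS}
    assert sum(sizes.values()) == n
    return RiskStratification(thresholds=thr, labels=labels, group_sizes=sizes)
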