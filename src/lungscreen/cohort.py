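"""Seeded synthetic screening cohorts with the published joint-group structure.

The original screening cohort (19,146 heavy smokers from an urban-China
screening programme) is not public.  This module generates stand-in cohorts
that reproduce, exactly and by construction, every published risk-group
marginal: counts per (group x 5-year age band), (group x sex),
(group x pack-year band), (group x tuberculosis history) and
(group x emphysema history), plus group-level lung-cancer incidence
densities.  Only the marginals are published, so within a group the
attributes are assigned independently of one another (each attribute column
is permuted independently with a seeded RNG).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .risk import GROUPS

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "simulate_group_incidence",
           "TABLE2_SPEC"]

AGE_BAND_EDGES = {"50-54": (50, 54), "55-59": (55, 59), "60-64": (60, 64),
                  "65-69": (65, 69), "70-74": (70, 74)}

# Published baseline characteristics by risk group (counts).
_GROUP_AGE_COUNTS = {
    "H":  {"50-54": 0,    "55-59": 46,   "60-64": 449,  "65-69": 3451, "70-74": 1072},
    "MH": {"50-54": 0,    "55-59": 272,  "60-64": 4467, "65-69": 6,    "70-74": 27},
    "LM": {"50-54": 84,   "55-59": 4337, "60-64": 90,   "65-69": 69,   "70-74": 0},
    "L":  {"50-54": 4658, "55-59": 118,  "60-64": 0,    "65-69": 0,    "70-74": 0},
}
_GROUP_SEX_COUNTS = {  # (male, female)
    "H": (4988, 30), "MH": (4711, 61), "LM": (4370, 210), "L": (4491, 285),
}
_GROUP_PACKYEAR_COUNTS = {  # (30-49, >=50)
    "H": (3090, 1928), "MH": (3168, 1604), "LM": (3218, 1362), "L": (3402, 1374),
}
_GROUP_TB_COUNTS = {  # (no, yes)
    "H": (4597, 421), "MH": (4700, 72), "LM": (4421, 159), "L": (4625, 151),
}
_GROUP_EMPHYSEMA_COUNTS = {  # (no, yes)
    "H": (4336, 682), "MH": (4538, 234), "LM": (4474, 106), "L": (4577, 199),
}
#: Observed lung-cancer incidence density per 100,000 person-years by group.
_GROUP_INCIDENCE_DENSITY = {"H": 262.0, "MH": 220.0, "LM": 154.0, "L": 81.0}

#: Upper cap for continuous pack-years in the open-ended >=50 band.
PACK_YEAR_CAP = 120.0


@dataclass
class CohortSpec:
    """Target marginals for synthetic cohort generation (defaults published)."""

    n_total: int = 19146
    group_age_counts: dict = field(default_factory=lambda: {g: dict(v) for g, v in _GROUP_AGE_COUNTS.items()})
    group_sex_counts: dict = field(default_factory=lambda: dict(_GROUP_SEX_COUNTS))
    group_packyear_counts: dict = field(default_factory=lambda: dict(_GROUP_PACKYEAR_COUNTS))
    group_tb_counts: dict = field(default_factory=lambda: dict(_GROUP_TB_COUNTS))
    group_emphysema_counts: dict = field(default_factory=lambda: dict(_GROUP_EMPHYSEMA_COUNTS))
    group_incidence_density: dict = field(default_factory=lambda: dict(_GROUP_INCIDENCE_DENSITY))
    seed: int = 0

    def group_sizes(self) -> dict:
        return {g: sum(self.group_age_counts[g].values()) for g in GROUPS}

    def validate(self) -> None:
        sizes = self.group_sizes()
        if sum(sizes.values()) != self.n_total:
            raise ValueError(
                f"group sizes {sizes} sum to {sum(sizes.values())}, expected n_total={self.n_total}"
            )
        for name, marg in [
            ("sex", self.group_sex_counts), ("pack-year", self.group_packyear_counts),
            ("tuberculosis", self.group_tb_counts), ("emphysema", self.group_emphysema_counts),
        ]:
            for g in GROUPS:
                if sum(marg[g]) != sizes[g]:
                    raise ValueError(
                        f"{name} marginal for group {g} sums to {sum(marg[g])}, "
                        f"but the age marginal gives {sizes[g]}"
                    )
        if any(d < 0 for d in self.group_incidence_density.values()):
            raise ValueError("incidence densities must be non-negative")

    def digest(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in (
                "n_total", "group_age_counts", "group_sex_counts", "group_packyear_counts",
                "group_tb_counts", "group_emphysema_counts", "group_incidence_density", "seed",
            )}, sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SyntheticCohort:
    """Generated cohort: one row per individual plus provenance."""

    individuals: pd.DataFrame  # columns: group, age, sex, pack_years, tb, emphysema
    seed: int
    spec_digest: str

    def __len__(self):
        return len(self.individuals)


TABLE2_SPEC = CohortSpec()


def _fill_by_counts(rng, counts_and_values, size):
    """Build a column with exact category counts, independently permuted."""
    col = np.concatenate([np.full(c, v, dtype=object) for v, c in counts_and_values])
    assert col.size == size
    return col[rng.permutation(size)]


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a cohort matching every marginal in ``spec`` exactly.

    Deterministic for a given seed.  Ages are drawn uniformly over the
    integer years of each 5-year band; continuous pack-years are drawn
    log-uniformly within the 30-49 and 50-120 bands (approximating the
    published right-skewed medians).
    """
    spec = spec or TABLE2_SPEC
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    frames = []
    for g in GROUPS:
        n = sum(spec.group_age_counts[g].values())
        # ages: uniform integer years within each band, counts exact
        ages = np.concatenate([
            lo + rng.integers(0, hi - lo + 1, size=c)
            for band, c in spec.group_age_counts[g].items()
            for lo, hi in [AGE_BAND_EDGES[band]]
        ])
        ages = ages[rng.permutation(n)]
        sex = _fill_by_counts(rng, [(1, spec.group_sex_counts[g][0]),
                                    (2, spec.group_sex_counts[g][1])], n).astype(int)
        n_lo, n_hi = spec.group_packyear_counts[g]
        py = np.concatenate([
            np.exp(rng.uniform(np.log(30.0), np.log(50.0), size=n_lo)),
            np.exp(rng.uniform(np.log(50.0), np.log(PACK_YEAR_CAP), size=n_hi)),
        ])
        # keep band membership exact after 0.1-precision rounding
        py = np.round(py, 1)
        py[n_lo:] = np.clip(py[n_lo:], 50.0, PACK_YEAR_CAP)
        py[:n_lo] = np.clip(py[:n_lo], 30.0, 49.9)
        py = py[rng.permutation(n)]
        tb = _fill_by_counts(rng, [(False, spec.group_tb_counts[g][0]),
                                   (True, spec.group_tb_counts[g][1])], n).astype(bool)
        em = _fill_by_counts(rng, [(False, spec.group_emphysema_counts[g][0]),
                                   (True, spec.group_emphysema_counts[g][1])], n).astype(bool)
        frames.append(pd.DataFrame({
            "group": g, "age": ages.astype(int), "sex": sex,
            "pack_years": py, "tb": tb, "emphysema": em,
        }))
    df = pd.concat(frames, ignore_index=True)
    _assert_marginals(df, spec)
    return SyntheticCohort(individuals=df, seed=seed, spec_digest=spec.digest())


def _assert_marginals(df: pd.DataFrame, spec: CohortSpec) -> None:
    """Every published marginal must be reproduced exactly by construction."""
    for g in GROUPS:
        sub = df[df["group"] == g]
        for band, (lo, hi) in AGE_BAND_EDGES.items():
            got = int(((sub["age"] >= lo) & (sub["age"] <= hi)).sum())
            assert got == spec.group_age_counts[g][band], (g, band, got)
        assert int((sub["sex"] == 1).sum()) == spec.group_sex_counts[g][0]
        assert int((sub["pack_years"] < 50).sum()) == spec.group_packyear_counts[g][0]
        assert int(sub["tb"].sum()) == spec.group_tb_counts[g][1]
        assert int(sub["emphysema"].sum()) == spec.group_emphysema_counts[g][1]


def simulate_group_incidence(group_sizes: dict, years: float, densities: dict) -> dict:
    """Expected lung-cancer case counts per group: person-years x density.

    ``densities`` are per 100,000 person-years.  Used for calibration
    checks of the placeholder hazard-ratio table.
    """
    if years <= 0:
        raise ValueError("years must be positive")
    return {
        g: group_sizes[g] * years * densities[g] / 1e5
        for g in group_sizes
    }
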