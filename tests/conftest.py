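import numpy as np
import pandas as pd
import pytest

from lungscreen._synthetic import synthetic_hazard_ratio_table, synthetic_rate_table
from lungscreen.cohort import generate_cohort
from lungscreen.config import RunConfig
from lungscreen.economics import EconParams
from lungscreen.markov import CohortStrata, ModelParams, build_strata
from lungscreen.pipeline import prepare_inputs
from lungscreen.risk import RiskModelParams


@pytest.fixture(scope="session")
def rates():
    return synthetic_rate_table()


@pytest.fixture(scope="session")
def hr_table():
    return synthetic_hazard_ratio_table()


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def inputs():
    """Full prepared base-case inputs (cohort, risk params, strata)."""
    return prepare_inputs(RunConfig(seed=1))


@pytest.fixture(scope="session")
def strata(inputs):
    return inputs["strata"]


@pytest.fixture
def model_params():
    return ModelParams()


@pytest.fixture
def econ_params():
    return EconParams()


@pytest.fixture
def toy_strata():
    """Two hand-built strata with flat hazards for oracle comparisons."""
    horizon = 3
    S = 2
    return CohortStrata(
        entry_age=np.array([55, 65]),
        sex=np.array([1, 1]),
        group=np.array(["MH", "H"], dtype=object),
        weight=np.array([0.6, 0.4]),
        tb_frac=np.array([0.0, 0.1]),
        emphysema_frac=np.array([0.05, 0.0]),
        i_b=np.array([0.02, 0.04]),
        hr_path=np.ones((S, horizon + 1)),
        p_other_path=np.tile(np.array([0.0, 0.01, 0.012, 0.015]), (S, 1)),
        horizon=horizon,
    )


def simple_hr_frame(**factor_levels):
    """Build a minimal hazard-ratio table for unit tests.

    ``factor_levels`` maps factor name to {level: hr}; reference levels
    with hr 1 must be included by the caller.
    """
    rows = [(f, lv, hr) for f, levels in factor_levels.items()
            for lv, hr in levels.items()]
    return pd.DataFrame(rows, columns=["factor", "level", "hr"])


@pytest.fixture
def flat_risk_params():
    """Risk params where every factor is at reference (r = 1 for anyone)."""
    table = simple_hr_frame(
        age_band={b: 1.0 for b in ("50-54", "55-59", "60-64", "65-69", "70-74")},
        sex={"1": 1.0, "2": 1.0},
        pack_year_band={"30-49": 1.0, ">=50": 1.0},
        tb={"no": 1.0, "yes": 1.0},
        emphysema={"no": 1.0, "yes": 1.0},
    )
    return RiskModelParams(hazard_ratio_table=table)
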