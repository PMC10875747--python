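"""Risk model: relative risk, PAR, hazards, absolute 5-year risk, stratification."""

import numpy as np
import pandas as pd
import pytest

from lungscreen.risk import (HazardRateTable, Individual, RiskConfigError,
                             RiskModelParams, Sex, absolute_5yr_risk,
                             baseline_lc_hazard, competing_hazard,
                             population_attributable_risk, relative_risk, stratify)
from tests.conftest import simple_hr_frame


def make_params(**overrides):
    levels = dict(
        age_band={b: 1.0 for b in ("50-54", "55-59", "60-64", "65-69", "70-74")},
        sex={"1": 1.0, "2": 1.0},
        pack_year_band={"30-49": 1.0, ">=50": 1.0},
        tb={"no": 1.0, "yes": 1.0},
        emphysema={"no": 1.0, "yes": 1.0},
    )
    for factor, mapping in overrides.items():
        levels[factor].update(mapping)
    return RiskModelParams(hazard_ratio_table=simple_hr_frame(**levels))


class TestRelativeRisk:
    def test_reference_individual_is_one(self, flat_risk_params):
        ind = Individual(age=50, sex=Sex.MALE, pack_years=30)
        assert relative_risk(ind, flat_risk_params) == 1.0

    def test_product_of_two_factors(self):
        params = make_params(tb={"yes": 2.0}, emphysema={"yes": 1.5})
        ind = Individual(age=50, sex=Sex.MALE, pack_years=30,
                         tb_history=True, emphysema_history=True)
        assert relative_risk(ind, params) == pytest.approx(3.0)

    def test_three_equal_factors(self):
        params = make_params(tb={"yes": 1.2}, emphysema={"yes": 1.2},
                             pack_year_band={">=50": 1.2})
        ind = Individual(age=52, sex=Sex.MALE, pack_years=60,
                         tb_history=True, emphysema_history=True)
        assert relative_risk(ind, params) == pytest.approx(1.728)

    def test_multiplicative_over_disjoint_factor_sets(self):
        params = make_params(tb={"yes": 1.7}, emphysema={"yes": 2.3},
                             age_band={"65-69": 1.9}, pack_year_band={">=50": 1.4})
        a_only = Individual(age=67, sex=Sex.MALE, pack_years=30)  # age factor
        b_only = Individual(age=50, sex=Sex.MALE, pack_years=60,
                            tb_history=True, emphysema_history=True)
        both = Individual(age=67, sex=Sex.MALE, pack_years=60,
                          tb_history=True, emphysema_history=True)
        assert relative_risk(both, params) == pytest.approx(
            relative_risk(a_only, params) * relative_risk(b_only, params))

    def test_unknown_level_names_the_level(self):
        table = simple_hr_frame(age_band={"50-54": 1.0})  # missing bands
        params = RiskModelParams(hazard_ratio_table=table)
        ind = Individual(age=67, sex=Sex.MALE, pack_years=30)
        with pytest.raises(RiskConfigError, match="65-69"):
            relative_risk(ind, params)


class TestPAR:
    def test_single_reference_category(self):
        assert population_attributable_risk([1.0], [1.0]) == 0.0

    @pytest.mark.parametrize("rho,rr,expected", [
        ((0.5, 0.5), (1.0, 2.0), 0.25),
        ((1.0,), (4.0,), 0.75),
    ])
    def test_bruzzi_examples(self, rho, rr, expected):
        assert population_attributable_risk(rho, rr) == pytest.approx(expected)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(RiskConfigError, match="sum"):
            population_attributable_risk([0.5, 0.4], [1.0, 2.0])

    def test_zero_iff_all_rr_one_and_monotone(self):
        rho = np.array([0.25, 0.25, 0.5])
        assert population_attributable_risk(rho, np.ones(3)) == 0.0
        base = population_attributable_risk(rho, [1.0, 2.0, 3.0])
        assert base > 0
        higher = population_attributable_risk(rho, [1.0, 2.5, 3.0])
        assert higher > base


class TestHazards:
    def test_baseline_deflation(self, rates):
        table = HazardRateTable(pd.DataFrame(
            {"age": [60], "sex": [1], "lc_incidence": [1e-3],
             "lc_mortality": [5e-4], "all_cause_mortality": [1e-2]}))
        assert baseline_lc_hazard(60, 1, table, 0.75) == pytest.approx(2.5e-4)
        assert baseline_lc_hazard(60, 1, table, 0.0) == pytest.approx(1e-3)

    def test_missing_age_raises(self, rates):
        with pytest.raises(KeyError):
            baseline_lc_hazard(40, 1, rates, 0.5)

    def test_competing_hazard_order_of_adjustment(self):
        table = HazardRateTable(pd.DataFrame(
            {"age": [60], "sex": [1], "lc_incidence": [0.0],
             "lc_mortality": [1e-3], "all_cause_mortality": [0.02]}))
        h2 = competing_hazard(60, 1, table, {1: 1.33, 2: 1.44})
        assert h2 == pytest.approx(0.02 * 1.33 - 1e-3)
        alt = competing_hazard(60, 1, table, {1: 1.33, 2: 1.44},
                               adjust_allcause_first=False)
        assert alt == pytest.approx((0.02 - 1e-3) * 1.33)

    def test_inconsistent_mortality_tables_rejected(self):
        # all-cause mortality below lung-cancer mortality can never yield a
        # valid competing hazard; the table constructor already refuses it
        with pytest.raises(RiskConfigError, match="all-cause"):
            HazardRateTable(pd.DataFrame(
                {"age": [60], "sex": [1], "lc_incidence": [0.0],
                 "lc_mortality": [2e-3], "all_cause_mortality": [1e-3]}))

    def test_competing_hazard_negative_guard(self):
        table = HazardRateTable(pd.DataFrame(
            {"age": [60], "sex": [1], "lc_incidence": [0.0],
             "lc_mortality": [2e-3], "all_cause_mortality": [2.1e-3]}))
        # a sub-unity smoker RR (pathological input) exposes the guard
        with pytest.raises(RiskConfigError, match="inconsistent"):
            competing_hazard(60, 1, table, {1: 0.5, 2: 0.5})


class TestAbsoluteRisk:
    def test_zero_hazard(self):
        assert absolute_5yr_risk(0.0, 2.0, 0.01) == 0.0

    def test_frozen_example(self):
        # independently verified against a competing-exponential Monte Carlo
        assert absolute_5yr_risk(0.002, 2.0, 0.01) == pytest.approx(0.019316, abs=1e-6)

    def test_saturation_limit(self):
        # as total hazard grows, risk approaches the cause-specific share
        assert absolute_5yr_risk(10.0, 1.0, 5.0) == pytest.approx(10 / 15, rel=1e-6)

    def test_strictly_increasing_in_r_and_h1(self):
        rs = np.linspace(0.5, 8, 25)
        h1s = np.linspace(1e-4, 5e-2, 25)
        p_r = absolute_5yr_risk(2e-3, rs, 0.01)
        p_h = absolute_5yr_risk(h1s, 1.5, 0.01)
        assert (np.diff(p_r) > 0).all()
        assert (np.diff(p_h) > 0).all()

    def test_agrees_with_competing_exponential_monte_carlo(self):
        rng = np.random.default_rng(42)
        n = 1_000_000
        for _ in range(20):
            h1 = rng.uniform(1e-4, 2e-2)
            r = rng.uniform(0.5, 10)
            h2 = rng.uniform(1e-3, 5e-2)
            t_lc = rng.exponential(1 / (h1 * r), n)
            t_oth = rng.exponential(1 / h2, n)
            p_hat = np.mean((t_lc < t_oth) & (t_lc < 5))
            se = np.sqrt(p_hat * (1 - p_hat) / n)
            p = absolute_5yr_risk(h1, r, h2)
            assert abs(p - p_hat) < 3 * se + 1e-12

    def test_negative_inputs_rejected(self):
        with pytest.raises(RiskConfigError):
            absolute_5yr_risk(-1e-3, 1.0, 0.01)
        with pytest.raises(RiskConfigError):
            absolute_5yr_risk(1e-3, -1.0, 0.01)


class TestStratify:
    def test_fixed_thresholds_label_each_band(self):
        res = stratify([0.020, 0.012, 0.006, 0.002], mode="fixed_thresholds")
        assert list(res.labels) == ["H", "MH", "LM", "L"]
        assert res.group_sizes == {"H": 1, "MH": 1, "LM": 1, "L": 1}

    def test_threshold_boundary_goes_to_higher_group(self):
        res = stratify([0.0170, 0.0103, 0.0049], mode="fixed_thresholds")
        assert list(res.labels) == ["H", "MH", "LM"]

    def test_quartile_equal_sizes_with_ties(self):
        res = stratify(np.full(8, 0.01), mode="quartile")
        assert sorted(res.group_sizes.values()) == [2, 2, 2, 2]

    def test_quartile_partitions_exactly(self):
        rng = np.random.default_rng(3)
        risks = rng.uniform(0, 0.1, 1001)
        res = stratify(risks, mode="quartile")
        assert sum(res.group_sizes.values()) == 1001
        # top quarter really is the largest risks
        h_risks = risks[res.labels == "H"]
        rest = risks[res.labels != "H"]
        assert h_risks.min() >= rest.max()

    def test_empty_cohort_rejected(self):
        with pytest.raises(RiskConfigError):
            stratify([], mode="quartile")
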