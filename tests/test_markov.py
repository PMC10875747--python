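"""Markov engine: single transitions, full runs, and oracle agreement."""

import dataclasses

import numpy as np
import pytest

from lungscreen.economics import EconParams
from lungscreen.markov import (HEALTHY, LC_DEATH, N_STATES, OTHER_DEATH,
                               IncidenceModel, ModelParams, apply_radiation_risk,
                               cycle_transition, incidence_at_cycle, run_strategy)
from lungscreen.strategies import enumerate_strategies, parse_strategy
from tests._micro import microsim_stratum

NO_SCREEN = parse_strategy("no_screening")
STATUS_QUO = parse_strategy("H1-MH1-LM1-L1")


def all_healthy():
    s = np.zeros(N_STATES)
    s[HEALTHY] = 1.0
    return s


def zeroed_params(**kw):
    zero4 = {k: 0.0 for k in ("I", "II", "III", "IV")}
    zero_prog = {k: 0.0 for k in ModelParams().progression}
    base = dict(progression=zero_prog, lc_death_undetected=dict(zero4),
                aftercare_death=dict(zero4), clinical_detection=dict(zero4),
                sensitivity=0.0, specificity=1.0, overdiagnosis_rate=0.0,
                excess_rr_per_screen=0.0)
    base.update(kw)
    return ModelParams(**base)


class TestCycleTransition:
    def test_identity_without_hazards(self):
        s, ev = cycle_transition(all_healthy(), ModelParams(), 0.0, 0.0, False)
        np.testing.assert_allclose(s, all_healthy(), atol=1e-15)
        assert ev["screens"] == 0.0

    def test_null_screen_equals_no_screen(self):
        params = dataclasses.replace(ModelParams(), sensitivity=0.0, specificity=1.0)
        start = np.full(N_STATES, 1.0 / N_STATES)
        with_screen, _ = cycle_transition(start, params, 0.01, 0.02, True)
        without, _ = cycle_transition(start, params, 0.01, 0.02, False)
        np.testing.assert_allclose(with_screen, without, atol=1e-15)

    def test_stage_iv_sequential_composition(self):
        # all mass undetected stage IV: clinical detection 0.658 first, then
        # lung-cancer death 0.588 among the remainder
        s = np.zeros(N_STATES)
        s[4] = 1.0  # u_IV
        out, _ = cycle_transition(s, ModelParams(), 0.0, 0.0, False)
        assert out[8] == pytest.approx(0.658)  # newly diagnosed stage IV
        assert out[LC_DEATH] == pytest.approx((1 - 0.658) * 0.588, abs=1e-12)
        assert out[4] == pytest.approx((1 - 0.658) * (1 - 0.588), abs=1e-12)

    def test_occupancy_conserved_under_random_inputs(self):
        rng = np.random.default_rng(7)
        params = ModelParams()
        for _ in range(50):
            s = rng.dirichlet(np.ones(N_STATES))
            out, _ = cycle_transition(s, params, rng.uniform(0, 0.2),
                                      rng.uniform(0, 0.2), bool(rng.integers(2)))
            assert out.sum() == pytest.approx(1.0, abs=1e-12)
            assert (out >= -1e-15).all()

    def test_screen_detects_and_counts(self):
        s = np.zeros(N_STATES)
        s[HEALTHY], s[1] = 0.9, 0.1  # 10% undetected stage I
        params = zeroed_params(sensitivity=0.9, specificity=0.8)
        out, ev = cycle_transition(s, params, 0.0, 0.0, True)
        assert ev["screens"] == pytest.approx(1.0)  # everyone participates
        assert out[5] == pytest.approx(0.1 * 0.9)  # screen-detected stage I
        assert ev["false_positives"] == pytest.approx(0.9 * 0.2)


class TestIncidence:
    def test_baseline_rate(self):
        m = IncidenceModel(baseline_incidence=178.43e-5, hr_by_cycle=np.ones(31))
        assert incidence_at_cycle(m, 1) == pytest.approx(0.0017843)

    def test_hr_doubles_rate(self):
        m = IncidenceModel(baseline_incidence=1e-3, hr_by_cycle=np.full(31, 2.0))
        assert incidence_at_cycle(m, 5) == pytest.approx(2e-3)

    def test_radiation_examples(self):
        inc, frac = apply_radiation_risk(0, 0.001, 0.002)
        assert inc == pytest.approx(0.002) and frac == 0.0
        inc, frac = apply_radiation_risk(10, 0.001, 0.002)
        assert inc == pytest.approx(0.00202)
        assert frac == pytest.approx(0.0099010, abs=1e-6)
        inc, _ = apply_radiation_risk(30, 0.001, 1.0)
        assert inc == pytest.approx(1.03)


class TestRunStrategy:
    def test_null_screen_equivalence_full_run(self, strata):
        econ = EconParams(cost_ldct=0.0, cost_pre_diagnosis=0.0)
        params = dataclasses.replace(ModelParams(), sensitivity=0.0,
                                     specificity=1.0, excess_rr_per_screen=0.0)
        a = run_strategy(STATUS_QUO, strata, params, econ)
        b = run_strategy(NO_SCREEN, strata, params, econ)
        for f in ("total_cost", "total_qalys", "life_years", "lc_deaths",
                  "false_positives", "overdiagnosed", "radiation_lc"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-12 * 1e5)
        assert a.screens > 0 and b.screens == 0

    def test_zero_incidence_gives_life_table_life_years(self, toy_strata):
        params = zeroed_params()
        strata = dataclasses.replace(toy_strata, i_b=np.zeros(2))
        out = run_strategy(NO_SCREEN, strata, params, EconParams())
        assert out.lc_deaths == 0.0
        # closed-form life table from the other-cause mortality path alone
        expected = 0.0
        for w, prow in zip(strata.weight, strata.p_other_path):
            surv, ly = 1.0, 0.0
            for t in range(1, strata.horizon + 1):
                nxt = surv * (1 - prow[t])
                ly += 0.5 * (surv + nxt)
                surv = nxt
            expected += w * ly
        assert out.life_years == pytest.approx(expected * 1e5, rel=1e-12)

    def test_three_cycle_hand_trace(self, toy_strata):
        # single hazard: incidence 0.1/cycle, no deaths, no detection
        params = zeroed_params()
        strata = dataclasses.replace(
            toy_strata, i_b=np.array([-np.log(1 - 0.1)] * 2),
            p_other_path=np.zeros_like(toy_strata.p_other_path))
        out = run_strategy(NO_SCREEN, strata, params, EconParams(discount_rate=0.0))
        # healthy: 0.9, 0.81, 0.729; everyone alive all three cycles
        assert out.life_years == pytest.approx(3.0 * 1e5, rel=1e-12)
        assert out.lc_deaths == 0.0
        # undetected cases accrue background cost: u-mass 0.1, 0.19, 0.271
        expected_cost = (0.1 + 0.19 + 0.271) * 5348.1
        assert out.total_cost == pytest.approx(expected_cost * 1e5, rel=1e-9)

    def test_screening_cannot_increase_lc_deaths_without_radiation(self, strata):
        params = dataclasses.replace(ModelParams(), excess_rr_per_screen=0.0)
        econ = EconParams()
        base = run_strategy(NO_SCREEN, strata, params, econ)
        for name in ("H1-MH1-LM1-L1", "H1-MH2-LM3-L3", "H1-MHnone-LMnone-Lnone"):
            out = run_strategy(parse_strategy(name), strata, params, econ)
            assert out.lc_deaths <= base.lc_deaths

    def test_harms_monotone_in_screening_frequency(self, strata):
        params, econ = ModelParams(), EconParams()
        outcomes = {s.name: run_strategy(s, strata, params, econ)
                    for s in enumerate_strategies()}
        sq = outcomes["H1-MH1-LM1-L1"]
        for name, o in outcomes.items():
            # annual-for-all dominates every strategy on every harm counter
            assert o.screens <= sq.screens + 1e-9
            assert o.false_positives <= sq.false_positives + 1e-9
            assert o.overdiagnosed <= sq.overdiagnosed + 1e-9
            assert o.radiation_lc <= sq.radiation_lc + 1e-9
        # a nested chain of increasing frequency
        chain = ["H1-MHnone-LMnone-Lnone", "H1-MH3-LMnone-Lnone",
                 "H1-MH2-LM3-L3", "H1-MH2-LM2-L2", "H1-MH1-LM1-L1"]
        for a, b in zip(chain, chain[1:]):
            assert outcomes[a].screens <= outcomes[b].screens
            assert outcomes[a].false_positives <= outcomes[b].false_positives


class TestMicrosimOracle:
    @pytest.mark.parametrize("name", ["no_screening", "H1-MH1-LM1-L1", "H1-MH2-LM3-L3"])
    def test_cohort_matrix_matches_micro_simulation(self, toy_strata, name):
        """3-cycle toy: the deterministic cohort engine must agree with an
        individual-level Monte Carlo using the same probabilities."""
        from lungscreen.markov import _schedule_matrix

        params = dataclasses.replace(ModelParams(), excess_rr_per_screen=0.0)
        strategy = parse_strategy(name)
        det = run_strategy(strategy, toy_strata, params, EconParams())
        offered = _schedule_matrix(strategy, toy_strata)
        rng = np.random.default_rng(11)
        n = 200_000
        weights = toy_strata.weight
        est = {"lc_death": 0.0, "life_years": 0.0}
        var = {"lc_death": 0.0, "life_years": 0.0}
        for i in range(len(toy_strata)):
            p_inc = -np.expm1(-toy_strata.i_b[i] * toy_strata.hr_path[i])
            res = microsim_stratum(n, params, p_inc, toy_strata.p_other_path[i],
                                   offered[i], toy_strata.horizon, rng)
            for k in est:
                est[k] += weights[i] * res[k].mean()
                var[k] += weights[i] ** 2 * res[k].var() / n
        for k, field in (("lc_death", "lc_deaths"), ("life_years", "life_years")):
            se = max(np.sqrt(var[k]), 1e-12)
            assert abs(getattr(det, field) / 1e5 - est[k]) < 3 * se, (k, est[k])
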