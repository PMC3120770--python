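"""Markov cohort mechanics: matrices, traces, DALY and cost accumulation."""

import numpy as np
import pytest

from conftest import microsimulate
from schizocea import (
    CostProfile,
    InterventionEffect,
    ModelConfig,
    TransitionParameters,
    accumulate_costs,
    accumulate_dalys,
    build_transition_matrix,
    dalys_averted,
    run_cohort,
)
from schizocea.markov import InvalidTransitionError, build_matrices
from schizocea.params import WeightRiskModel


def _tp(**kw):
    defaults = dict(
        p_remission=0.0,
        p_suicide_base=0.0,
        p_other_mortality=[[0.0, 0.0]],
        weight_risk=WeightRiskModel(p_weight_related_base=0.0),
    )
    defaults.update(kw)
    return TransitionParameters(**defaults)


NULL_EFF = InterventionEffect()


class TestTransitionMatrix:
    def test_all_rates_zero(self):
        m, _ = build_transition_matrix(_tp(), NULL_EFF, 30)
        assert np.allclose(m[0], [1.0, 0.0, 0.0])

    def test_death_is_absorbing(self):
        m, _ = build_transition_matrix(TransitionParameters(), NULL_EFF, 30)
        assert np.allclose(m[2], [0.0, 0.0, 1.0])

    def test_additive_competing_risks_example(self):
        tp = _tp(p_remission=0.02, p_suicide_base=0.005, p_other_mortality=[[0.0, 0.01]])
        m, causes = build_transition_matrix(tp, NULL_EFF, 30)
        assert np.allclose(m[0], [0.965, 0.02, 0.015])
        assert causes["suicide"] == pytest.approx(0.005)
        assert causes["other"] == pytest.approx(0.01)

    def test_suicide_rr_scales_base_rate(self):
        tp = _tp(p_suicide_base=0.005)
        _, causes = build_transition_matrix(
            tp, InterventionEffect(rr_suicide=0.53), 30
        )
        assert causes["suicide"] == pytest.approx(0.005 * 0.53)

    def test_weight_gain_adds_mortality_via_pif(self):
        tp = _tp(weight_risk=WeightRiskModel(0.05, 1.6, 0.003))
        eff = InterventionEffect(weight_gain_kg=4.15)
        _, causes = build_transition_matrix(tp, eff, 30)
        shift = 4.15 / 1.6**2
        assert causes["weight"] == pytest.approx(0.003 * (np.exp(0.05 * shift) - 1))

    def test_excess_exit_probability_raises(self):
        tp = _tp(p_remission=0.6, p_other_mortality=[[0.0, 0.5]])
        with pytest.raises(InvalidTransitionError):
            build_transition_matrix(tp, NULL_EFF, 30)

    def test_rows_are_stochastic_across_ages(self):
        ages, mats, _ = build_matrices(TransitionParameters(), NULL_EFF, 30, 80)
        assert mats.shape == (50, 3, 3)
        assert np.allclose(mats.sum(axis=2), 1.0, atol=1e-12)


class TestCohortTrace:
    def test_identity_matrices_leave_occupancy_constant(self):
        mats = np.broadcast_to(np.eye(3), (10, 3, 3)).copy()
        causes = [{"suicide": 0, "weight": 0, "other": 0, "other_R": 0}] * 10
        trace = run_cohort(mats, causes, np.array([0.6, 0.3, 0.1]))
        assert np.allclose(trace.occupancy, [0.6, 0.3, 0.1])

    def test_mass_conservation(self):
        ages, mats, causes = build_matrices(TransitionParameters(), NULL_EFF, 30, 80)
        trace = run_cohort(mats, causes, np.array([1.0, 0.0, 0.0]), ages)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        assert (trace.occupancy >= -1e-15).all()

    def test_deaths_partition_the_dead_increment(self):
        ages, mats, causes = build_matrices(TransitionParameters(), NULL_EFF, 30, 80)
        trace = run_cohort(mats, causes, np.array([1.0, 0.0, 0.0]), ages)
        total_deaths = sum(trace.deaths_by_cause.values())
        d_increment = np.diff(trace.occupancy[:, 2])
        assert np.allclose(total_deaths, d_increment, atol=1e-12)

    def test_age_constant_matrix_equals_matrix_power_oracle(self):
        """The cohort trace must reproduce start @ M^t exactly."""
        tp = _tp(p_remission=0.03, p_suicide_base=0.004, p_other_mortality=[[0.0, 0.012]])
        m, causes = build_transition_matrix(tp, NULL_EFF, 30)
        t = 40
        mats = np.repeat(m[None], t, axis=0)
        trace = run_cohort(mats, [causes] * t, np.array([1.0, 0.0, 0.0]))
        for cycle in range(t + 1):
            expected = np.array([1.0, 0.0, 0.0]) @ np.linalg.matrix_power(m, cycle)
            assert np.allclose(trace.occupancy[cycle], expected, atol=1e-12)

    def test_microsimulation_agreement(self):
        """A 10,000-person per-person sampling oracle agrees with the cohort
        trace within 3 Monte Carlo standard errors at cycles 1, 5 and 20."""
        ages, mats, causes = build_matrices(TransitionParameters(), NULL_EFF, 30, 80)
        trace = run_cohort(mats, causes, np.array([1.0, 0.0, 0.0]), ages)
        n = 10_000
        sim = microsimulate(mats, n, seed=2024, record_cycles={1, 5, 20})
        for cycle, frac in sim.items():
            expected = trace.occupancy[cycle]
            se = np.sqrt(np.clip(expected * (1 - expected), 1e-12, None) / n)
            assert (np.abs(frac - expected) <= 3 * se + 1e-9).all(), cycle


def _simple_trace(s_occupancy, deaths=None, t=None):
    """Trace with prescribed S occupancy, everyone else recovered."""
    s = np.asarray(s_occupancy, dtype=float)
    t = len(s) - 1 if t is None else t
    occ = np.zeros((len(s), 3))
    occ[:, 0] = s
    occ[:, 1] = 1.0 - s
    zeros = np.zeros(len(s) - 1)
    d = {"suicide": zeros.copy(), "weight": zeros.copy(), "other": zeros.copy()}
    if deaths:
        for k, v in deaths.items():
            d[k] = np.asarray(v, dtype=float)
        occ[:, 2] = np.concatenate([[0.0], np.cumsum(sum(d.values()))])
        occ[:, 1] = 1.0 - occ[:, 0] - occ[:, 2]
    from schizocea.markov import CohortTrace

    return CohortTrace(np.arange(len(s) - 1, dtype=float), occ, d)


class TestDalyAccumulation:
    def test_zero_dw_no_deaths_no_dalys(self):
        trace = _simple_trace([1.0, 1.0, 1.0])
        out = accumulate_dalys(trace, 0.0, ModelConfig())
        assert out["DALY"] == 0.0

    def test_two_cycle_yld_example(self):
        """One person alive 2 cycles at DW 0.5, r = 3%: YLD = 0.5 (1 + 1/1.03)."""
        trace = _simple_trace([1.0, 1.0, 0.0])
        out = accumulate_dalys(trace, 0.5, ModelConfig(discount_rate=0.03))
        assert out["YLD"] == pytest.approx(0.5 * (1 + 1 / 1.03))
        assert out["YLD"] == pytest.approx(0.98544, abs=1e-5)

    def test_zero_discount_equals_person_years(self):
        s = np.array([1.0, 0.9, 0.8, 0.7, 0.0])
        trace = _simple_trace(s)
        out = accumulate_dalys(trace, 0.25, ModelConfig(discount_rate=0.0))
        assert out["YLD"] == pytest.approx(0.25 * s[:-1].sum())

    def test_constant_survival_geometric_closed_form(self):
        r, t, dw = 0.03, 30, 0.4
        trace = _simple_trace(np.ones(t + 1))
        out = accumulate_dalys(trace, dw, ModelConfig(discount_rate=r))
        v = 1 / (1 + r)
        assert out["YLD"] == pytest.approx(dw * (1 - v**t) / (1 - v))

    def test_yll_counts_remaining_discounted_horizon_years(self):
        """A death in the first cycle of a 3-cycle horizon loses the years a
        survivor would still accrue: cycles 1 and 2."""
        trace = _simple_trace([1.0, 0.0, 0.0, 0.0], deaths={"suicide": [1.0, 0.0, 0.0]})
        out = accumulate_dalys(trace, 0.0, ModelConfig(discount_rate=0.03))
        assert out["YLL"] == pytest.approx(1 / 1.03 + 1 / 1.03**2)
        assert out["YLL_by_cause"]["suicide"] == out["YLL"]

    def test_discounting_is_monotone(self):
        trace = _simple_trace(np.linspace(1.0, 0.5, 21))
        dalys = [
            accumulate_dalys(trace, 0.3, ModelConfig(discount_rate=r))["DALY"]
            for r in (0.0, 0.015, 0.03, 0.06)
        ]
        assert all(a >= b for a, b in zip(dalys, dalys[1:]))

    def test_dw_out_of_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            accumulate_dalys(_simple_trace([1.0, 1.0]), 1.2, ModelConfig())


class TestCostAccumulation:
    PROFILE = CostProfile(
        drug_admin_cost=3300,
        side_effect_cost=400,
        hosp_rate=0.27,
        hosp_unit_cost=30_000,
        time_travel_cost=1300,
    )

    def test_zero_occupancy_zero_cost(self):
        trace = _simple_trace([0.0, 0.0, 0.0])
        out = accumulate_costs(trace, self.PROFILE, ModelConfig())
        assert out["total"] == 0.0

    def test_undiscounted_components_equal_sums(self):
        trace = _simple_trace([1.0, 1.0, 1.0])
        out = accumulate_costs(trace, self.PROFILE, ModelConfig(discount_rate=0.0))
        assert out["intervention"] == pytest.approx(2 * 3300)
        assert out["hospitalization"] == pytest.approx(2 * 0.27 * 30_000)
        assert out["total"] == pytest.approx(2 * (3300 + 400 + 8100 + 1300))

    def test_family_intervention_cost_timing(self):
        """Program costs hit the first cycle; boosters every cycle after."""
        cp = CostProfile(
            fi_startup_amortized=200,
            fi_session_cost=1800,
            fi_booster_cost=360,
            fi_time_first_year=3100,
            fi_time_booster=600,
        )
        trace = _simple_trace([1.0, 1.0, 1.0, 1.0])
        out = accumulate_costs(trace, cp, ModelConfig(discount_rate=0.0))
        assert out["intervention"] == pytest.approx(2000 + 2 * 360)
        assert out["time_travel"] == pytest.approx(3100 + 2 * 600)

    def test_discounted_total_below_undiscounted(self):
        trace = _simple_trace(np.ones(11))
        undisc = accumulate_costs(trace, self.PROFILE, ModelConfig(discount_rate=0.0))
        disc = accumulate_costs(trace, self.PROFILE, ModelConfig(discount_rate=0.03))
        assert disc["total"] < undisc["total"]


class TestDalysAverted:
    def test_identical_runs_avert_nothing(self):
        trace = _simple_trace([1.0, 0.9, 0.8], deaths={"other": [0.05, 0.05]})
        d = accumulate_dalys(trace, 0.3, ModelConfig())
        out = dalys_averted(d, d)
        assert out["total"] == 0.0
        assert out["severity"] == out["weight_gain"] == out["suicide"] == 0.0

    def test_components_sum_to_total_difference(self):
        cfg = ModelConfig()
        strat = _simple_trace([1.0, 0.95, 0.9], deaths={"weight": [0.01, 0.01], "suicide": [0.0, 0.0]})
        null = _simple_trace([1.0, 0.9, 0.8], deaths={"suicide": [0.02, 0.02]})
        d_s = accumulate_dalys(strat, 0.25, cfg)
        d_n = accumulate_dalys(null, 0.30, cfg)
        out = dalys_averted(d_s, d_n)
        assert out["total"] == pytest.approx(d_n["DALY"] - d_s["DALY"], abs=1e-12)
        assert out["total"] == pytest.approx(
            out["severity"] + out["weight_gain"] + out["suicide"], abs=1e-12
        )
        assert out["weight_gain"] < 0.0  # strategy's weight gain is a harm
        assert out["suicide"] > 0.0
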