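"""Cohort-engine dynamics: transition structure, mass conservation,
closed-form checks and the microsimulation oracle."""
import math

import numpy as np
import pytest

import bpcea
from bpcea import cycle_probabilities, run_cohort, step_cohort, transition_matrix
from bpcea.params import ARMS, CV_EVENTS, EVENT_INDEX, NONFATAL_CV_EVENTS, STATE_INDEX
from bpcea.synthetic import TRIAL_EVENT_RATES

from conftest import build_inputs, microsimulate


class TestCycleProbabilities:
    def test_trial_phase_returns_table_values_verbatim(self, cn_inputs):
        probs = cycle_probabilities("no_cvd", 66, "intensive", cn_inputs, "trial")
        assert probs["stroke"] == pytest.approx(0.002840265, abs=1e-12)
        assert probs["acs"] == pytest.approx(0.003256504, abs=1e-12)

    def test_absorbing_states_stay_put(self, cn_inputs):
        for state in ("dead_cv", "dead_noncv"):
            probs = cycle_probabilities(state, 80, "standard", cn_inputs, "post_trial")
            assert probs["stay"] == 1.0
            assert all(v == 0.0 for k, v in probs.items() if k != "stay")

    def test_terminal_age_rule_forces_death(self, cn_inputs):
        probs = cycle_probabilities("no_cvd", 101, "standard", cn_inputs, "post_trial")
        assert probs["noncv_death"] == 1.0

    def test_unknown_phase_rejected(self, cn_inputs):
        with pytest.raises(ValueError):
            cycle_probabilities("no_cvd", 70, "standard", cn_inputs, "mid_trial")


class TestStepCohort:
    def test_all_dead_cohort_is_inert(self, cn_inputs):
        T, F = transition_matrix(cn_inputs, "standard", 70, "post_trial")
        occ = np.zeros(len(bpcea.STATES))
        occ[STATE_INDEX["dead_noncv"]] = 1.0
        nxt, events = step_cohort(occ, T, F)
        assert np.array_equal(nxt, occ)
        assert events.sum() == 0.0

    def test_two_state_toy_decays_geometrically(self):
        inputs = build_inputs(qx=0.1, event_probs={
            (arm, "all_cause_death"): 0.1 for arm in ARMS})
        trace = run_cohort(inputs, "standard", horizon=25)
        alive = trace.occupancy[:, STATE_INDEX["no_cvd"]]
        for k in range(26):
            assert alive[k] == pytest.approx(0.9 ** k, abs=1e-12)

    def test_one_step_stroke_incidence_matches_hand_computation(self, cn_inputs):
        # independent composition of the cycle order: death first, then one
        # competing nonfatal CV event among survivors
        p = {e: TRIAL_EVENT_RATES[("standard", e)][0] for e in CV_EVENTS}
        p_all = TRIAL_EVENT_RATES[("standard", "all_cause_death")][0]
        p_death = p_all  # cv + non-cv death rates recombine to all-cause
        rates = {e: -math.log(1.0 - p[e]) for e in NONFATAL_CV_EVENTS}
        r_tot = sum(rates.values())
        expected = ((1.0 - p_death) * (1.0 - math.exp(-r_tot))
                    * rates["stroke"] / r_tot)
        trace = run_cohort(cn_inputs, "standard", horizon=1)
        got = trace.events[0, STATE_INDEX["no_cvd"], EVENT_INDEX["stroke"]]
        assert got == pytest.approx(expected, abs=1e-12)
        # and the competing-risk value stays within 1% of the marginal
        # yearly stroke probability
        assert got == pytest.approx(0.004185055, rel=0.01)

    def test_malformed_occupancy_rejected(self, cn_inputs):
        T, F = transition_matrix(cn_inputs, "standard", 70, "post_trial")
        with pytest.raises(ValueError):
            step_cohort(np.full(7, 0.2), T, F)


class TestCohortInvariants:
    @pytest.mark.parametrize("arm", ARMS)
    def test_mass_conservation_and_monotone_death(self, cn_traces, arm):
        trace = cn_traces[arm]
        sums = trace.occupancy.sum(axis=1)
        assert np.all(np.abs(sums - 1.0) < 1e-10)
        dead = trace.occupancy[:, STATE_INDEX["dead_cv"]:].sum(axis=1)
        assert np.all(np.diff(dead) >= -1e-15)
        assert np.all(trace.events >= 0.0)

    def test_transition_rows_sum_to_one(self, cn_inputs):
        for arm in ARMS:
            for age, phase in ((66, "trial"), (75, "post_trial"), (95, "post_trial")):
                T, _ = transition_matrix(cn_inputs, arm, age, phase)
                assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_pure_life_table_mortality_reproduces_survival_curve(self):
        inputs = build_inputs(qx=0.02, trial_years=0)
        trace = run_cohort(inputs, "standard", horizon=30)
        alive = trace.occupancy[1:, STATE_INDEX["no_cvd"]]
        expected = inputs.life_table.survival_from(66, 30)
        assert np.allclose(alive, expected, atol=1e-12)

    def test_raising_one_event_probability_cannot_reduce_its_events(self, cn_inputs):
        base = run_cohort(cn_inputs, "standard").event_totals()[:, EVENT_INDEX["stroke"]].sum()
        bumped_inputs = cn_inputs.copy()
        bumped_inputs.rates.set_mean(
            "standard", "stroke", 1.3 * cn_inputs.rates.prob("standard", "stroke"))
        bumped = run_cohort(bumped_inputs, "standard").event_totals()[:, EVENT_INDEX["stroke"]].sum()
        assert bumped >= base

    def test_horizon_validation(self, cn_inputs):
        with pytest.raises(ValueError):
            run_cohort(cn_inputs, "standard", horizon=0)
        with pytest.raises(ValueError):
            run_cohort(cn_inputs, "arm3")


class TestClosedFormQALYs:
    def test_constant_hazard_matches_truncated_geometric_series(self):
        p, u, d, horizon = 0.05, 0.8, 0.03, 200
        inputs = build_inputs(qx=p, discount=d, utility=u, event_probs={
            (arm, "all_cause_death"): p for arm in ARMS})
        trace = run_cohort(inputs, "intensive", horizon=horizon)
        x = (1.0 - p) / (1.0 + d)
        truncated = u * (1.0 - x ** horizon) / (1.0 - x)
        assert trace.total_qaly == pytest.approx(truncated, abs=1e-9)
        # and the infinite-horizon limit u(1+d)/(d+p) bounds it from above
        assert trace.total_qaly < u * (1.0 + d) / (d + p)


class TestMicrosimulationOracle:
    def test_cohort_engine_matches_individual_simulation(self, cn_inputs):
        n, years, seed = 200_000, 10, 20260922
        for arm in ARMS:
            det = run_cohort(cn_inputs, arm, horizon=years).occupancy[years]
            mc = microsimulate(cn_inputs, arm, years, n, seed)
            se = np.sqrt(np.maximum(det * (1.0 - det), 1e-12) / n)
            assert np.all(np.abs(mc - det) <= 3.0 * se), (arm, mc, det)
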