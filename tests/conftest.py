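"""Shared fixtures: synthetic country bundles, minimal hand-built inputs,
and a seeded per-individual microsimulation oracle for the cohort engine."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bpcea
import bpcea.markov as markov_mod
from bpcea import (
    AdherenceScenario,
    CostSet,
    CountryProfile,
    EventRate,
    EventRateTable,
    LifeTable,
    ModelInputs,
    ModelOptions,
    RiskCoefficients,
    RiskProfile,
    UtilitySet,
)
from bpcea.params import ARMS, TABLE_EVENTS

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def cn_inputs() -> ModelInputs:
    return bpcea.generate_inputs(bpcea.SyntheticProfile(country="CN", seed=0))


@pytest.fixture(scope="session")
def cn_traces(cn_inputs):
    return {arm: bpcea.run_cohort(cn_inputs, arm) for arm in ARMS}


@pytest.fixture(scope="session")
def cn_ce(cn_inputs, cn_traces):
    return bpcea.compute_ce(cn_traces["intensive"], cn_traces["standard"],
                            cn_inputs.country)


def build_inputs(event_probs: dict[tuple[str, str], float] | None = None,
                 qx: float = 0.0,
                 utility: float = 1.0,
                 discount: float = 0.0,
                 attainment: tuple[float, float] = (1.0, 1.0),
                 adherence: tuple[float, float] = (1.0, 1.0),
                 terminal_age: int = 400,
                 trial_years: int = 4,
                 costs: dict | None = None) -> ModelInputs:
    """A minimal hand-built input bundle: all event probabilities default to
    zero, mortality is a flat ``qx`` at every age, utilities are constant."""
    rates = {}
    for arm in ARMS:
        for event in TABLE_EVENTS:
            p = (event_probs or {}).get((arm, event), 0.0)
            rates[(arm, event)] = EventRate(p, 0.0, "beta")
    costs = costs or {}
    inputs = ModelInputs(
        rates=EventRateTable(rates),
        costs=CostSet(
            currency="CNY",
            intervention={"intensive": costs.get("intervention_intensive", 0.0),
                          "standard": costs.get("intervention_standard", 0.0)},
            acute=costs.get("acute", {}),
            chronic=costs.get("chronic", {}),
            background=costs.get("background", 0.0),
        ),
        utilities=UtilitySet(baseline=utility, age_decrement=0.0, anchor_age=66.0,
                             state_decrement={}, event_decrement={}),
        adherence=AdherenceScenario("custom", *adherence),
        country=CountryProfile(country="CN", currency="CNY",
                               discount_rate=discount, wtp_lower=89_300.0,
                               wtp_upper=267_900.0, terminal_age=terminal_age),
        life_table=LifeTable(range(60, terminal_age),
                             [qx] * len(range(60, terminal_age))),
        risk_coefficients=RiskCoefficients("null", ("age", "sbp"), (0.0, 0.0),
                                           (70.0, 140.0), s0=1.0),
        risk_profiles={"intensive": RiskProfile(age=66, sbp=127),
                       "standard": RiskProfile(age=66, sbp=136)},
        options=ModelOptions(trial_years=trial_years,
                             trial_attainment_intensive=attainment[0],
                             trial_attainment_standard=attainment[1],
                             chronic_cv_death_multiplier=1.0),
    )
    inputs.validate()
    return inputs


def microsimulate(inputs: ModelInputs, arm: str, years: int, n: int,
                  seed: int) -> np.ndarray:
    """Seeded individual-level Monte Carlo using the same per-cycle
    transition matrices as the deterministic engine; returns end-of-window
    state occupancy fractions."""
    calib = markov_mod._calibration(inputs)
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(bpcea.STATES), dtype=np.int64)
    counts[0] = n
    for k in range(1, years + 1):
        age = inputs.country.start_age + k - 1
        phase = "trial" if k <= inputs.options.trial_years else "post_trial"
        T, _ = bpcea.transition_matrix(inputs, arm, age, phase, calib)
        nxt = np.zeros_like(counts)
        for s in range(len(counts)):
            if counts[s] > 0:
                nxt += rng.multinomial(counts[s], T[s])
        counts = nxt
    return counts / n
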