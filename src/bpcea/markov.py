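"""Yearly-cycle deterministic cohort engine.

A closed cohort starts at age 66 in the event-free state and is pushed
through one-year cycles until death (or a fixed horizon).  Cycles 1..4 use
the trial-period yearly probabilities; later cycles extrapolate
cardiovascular risk with the risk equation and take competing non-CVD
mortality from the national life table.  Within a cycle events resolve in
a fixed order, each drawn from the mass surviving the previous step:

1. death (cardiovascular and non-cardiovascular, competing in rate space),
2. at most one acute cardiovascular event per surviving person-fraction
   (a competing multinomial built from the marginal yearly rates; the new
   event's sequela state becomes the person's state),
3. adverse events, which preserve the state and only accrue costs and
   utility decrements.

The engine is a deterministic fraction-of-cohort recursion; ``cohort_size``
only scales reported counts.  A seeded per-individual microsimulation of
the same transition matrices is used as an independent oracle in the test
suite, not here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import econ
from .params import (
    ADVERSE_EVENTS,
    ALIVE_STATES,
    ARMS,
    CHRONIC_STATES,
    CV_EVENTS,
    DEAD_STATES,
    EVENT_COLUMNS,
    EVENT_DESTINATION,
    EVENT_INDEX,
    NONFATAL_CV_EVENTS,
    STATE_INDEX,
    STATES,
    ModelInputs,
    prob_to_rate,
    rate_to_prob,
)
from .risk import ten_year_cvd_risk

logger = logging.getLogger("bpcea")

_N_STATES = len(STATES)
_N_EVENTS = len(EVENT_COLUMNS)
_DEAD_CV = STATE_INDEX["dead_cv"]
_DEAD_NONCV = STATE_INDEX["dead_noncv"]


# --------------------------------------------------------------------------
# Per-arm yearly event rates
# --------------------------------------------------------------------------

def _trial_event_rates(inputs: ModelInputs, arm: str) -> dict[str, float]:
    """Yearly rates for one arm during the trial window (table values)."""
    rates: dict[str, float] = {}
    hr = inputs.options.treatment_effect_hr
    for event in CV_EVENTS:
        if hr is not None and arm == "intensive":
            rates[event] = hr * inputs.rates.rate("standard", event)
        else:
            rates[event] = inputs.rates.rate(arm, event)
    for event in ADVERSE_EVENTS:
        rates[event] = inputs.rates.rate(arm, event)
    r_all = inputs.rates.rate(arm, "all_cause_death")
    rates["noncv_death"] = max(0.0, r_all - rates["cv_death"])
    return rates


def _event_mix(inputs: ModelInputs, arm: str) -> dict[str, float]:
    """Rate-space shares of the six cardiovascular events in one arm."""
    rates = _trial_event_rates(inputs, arm)
    total = sum(rates[e] for e in CV_EVENTS)
    if total <= 0.0:
        return {e: 0.0 for e in CV_EVENTS}
    return {e: rates[e] / total for e in CV_EVENTS}


def _model_yearly_rate(inputs: ModelInputs, arm: str, age: float) -> float:
    """Yearly composite CV rate implied by the risk equation at ``age``."""
    profile = inputs.risk_profiles[arm].at_age(age)
    risk10 = ten_year_cvd_risk(profile, inputs.risk_coefficients)
    if risk10 >= 1.0:
        return prob_to_rate(1.0 - 1e-12, 10.0)
    return prob_to_rate(risk10, 10.0)


def _calibration(inputs: ModelInputs) -> dict[str, float | None]:
    """Per-arm composite rate ratio for the post-trial extrapolation.

    The standard arm follows the risk equation's own composite rate; the
    intensive arm keeps its trial-period composite rate ratio relative to
    the standard arm (the proportional treatment effect observed in the
    trial).  ``None`` flags a degenerate risk equation (zero modelled risk
    with non-zero trial risk); the engine then holds that arm's trial rates
    flat and warns.
    """
    age0 = inputs.country.start_age + inputs.options.trial_years
    r_model = _model_yearly_rate(inputs, "standard", age0)
    r_std = sum(_trial_event_rates(inputs, "standard")[e] for e in CV_EVENTS)
    out: dict[str, float | None] = {}
    for arm in ARMS:
        r_table = sum(_trial_event_rates(inputs, arm)[e] for e in CV_EVENTS)
        if r_model <= 0.0 and r_table > 0.0:
            logger.warning("risk equation predicts zero CV risk; holding arm %s "
                           "trial rates flat after the trial period", arm)
            out[arm] = None
        elif r_std > 0.0:
            out[arm] = r_table / r_std
        else:
            out[arm] = 0.0 if r_table == 0.0 else None
    return out


def _post_trial_event_rates(inputs: ModelInputs, arm: str, age: float,
                            calib: dict[str, float | None]) -> dict[str, float]:
    """Yearly rates for one arm after the trial window."""
    mix = _event_mix(inputs, arm)
    ratio = calib[arm]
    if ratio is None:
        composite = sum(_trial_event_rates(inputs, arm)[e] for e in CV_EVENTS)
    else:
        composite = ratio * _model_yearly_rate(inputs, "standard", age)
    composite *= inputs.options.post_trial_risk_scale
    rates = {e: composite * mix[e] for e in CV_EVENTS}
    for event in ADVERSE_EVENTS:  # adverse-event risks held at trial values
        rates[event] = inputs.rates.rate(arm, event)
    qx = inputs.life_table.qx_at(age)
    if qx >= 1.0 or age >= inputs.country.terminal_age:
        rates["noncv_death"] = np.inf  # terminal rule: certain death
    else:
        rates["noncv_death"] = max(0.0, prob_to_rate(qx) - rates["cv_death"])
    return rates


def effective_event_rates(inputs: ModelInputs, arm: str, age: float,
                          phase: str,
                          calib: dict[str, float | None] | None = None) -> dict[str, float]:
    """Arm-level yearly event rates after target-attainment/adherence blending.

    During the trial the arm is a fixed mix of patients at and off their
    assigned target (attainment 70%/75% by default); after the trial the
    active :class:`~bpcea.params.AdherenceScenario` governs the mix.  The
    off-target fraction of either arm experiences standard-arm rates.
    """
    if calib is None and phase == "post_trial":
        calib = _calibration(inputs)
    if phase == "trial":
        own = _trial_event_rates(inputs, arm)
        ref = _trial_event_rates(inputs, "standard")
        a = inputs.options.trial_attainment(arm)
    else:
        own = _post_trial_event_rates(inputs, arm, age, calib)
        ref = _post_trial_event_rates(inputs, "standard", age, calib)
        a = inputs.adherence.fraction(arm)
    if a >= 1.0:
        return own
    if a <= 0.0:
        return ref
    return {e: a * own[e] + (1.0 - a) * ref[e] for e in own}


def cycle_probabilities(state: str, age: float, arm: str, inputs: ModelInputs,
                        phase: str) -> dict[str, float]:
    """Marginal yearly event probabilities for one state/arm/age.

    Trial phase returns the table probabilities verbatim (rate round-trip);
    post-trial delegates cardiovascular events to the risk equation and
    non-CVD death to the life table.  Absorbing states return all zeros and
    ``stay = 1``.
    """
    if phase not in ("trial", "post_trial"):
        raise ValueError(f"unknown phase {phase!r}")
    probs = {e: 0.0 for e in EVENT_COLUMNS}
    if state in DEAD_STATES:
        probs["stay"] = 1.0
        return probs
    if phase == "trial":
        rates = _trial_event_rates(inputs, arm)
    else:
        rates = _post_trial_event_rates(inputs, arm, age, _calibration(inputs))
    chronic = state in CHRONIC_STATES
    mult = inputs.options.repeated_cvd_multiplier if chronic else 1.0
    for e in EVENT_COLUMNS:
        r = rates[e] * (mult if e in CV_EVENTS else 1.0)
        if chronic and e == "cv_death":
            r *= inputs.options.chronic_cv_death_multiplier
        probs[e] = 1.0 if np.isinf(r) else rate_to_prob(r)
    probs["stay"] = 1.0 - min(1.0, sum(probs[e] for e in
                                       CV_EVENTS + ("noncv_death",)))
    return probs


# --------------------------------------------------------------------------
# Transition structure
# --------------------------------------------------------------------------

def transition_matrix(inputs: ModelInputs, arm: str, age: float, phase: str,
                      calib: dict[str, float | None] | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """One-cycle transition matrix and event-flow matrix.

    Returns ``(T, F)`` where ``T[s, d]`` is the probability that a person
    starting the cycle in state ``s`` ends it in state ``d`` (rows sum to
    1), and ``F[s, e]`` is the expected number of incident events of type
    ``e`` (columns of :data:`EVENT_COLUMNS`) per person starting in ``s``.
    """
    rates = effective_event_rates(inputs, arm, age, phase, calib)
    T = np.zeros((_N_STATES, _N_STATES))
    F = np.zeros((_N_STATES, _N_EVENTS))
    T[_DEAD_CV, _DEAD_CV] = 1.0
    T[_DEAD_NONCV, _DEAD_NONCV] = 1.0
    for s in ALIVE_STATES:
        si = STATE_INDEX[s]
        chronic = s in CHRONIC_STATES
        mult = inputs.options.repeated_cvd_multiplier if chronic else 1.0
        r_cvd = rates["cv_death"] * mult
        if chronic:
            r_cvd *= inputs.options.chronic_cv_death_multiplier
        r_noncv = rates["noncv_death"]
        # step 1: death, competing in rate space
        if np.isinf(r_noncv):
            T[si, _DEAD_NONCV] = 1.0
            F[si, EVENT_INDEX["noncv_death"]] = 1.0
            continue
        r_death = r_cvd + r_noncv
        p_death = rate_to_prob(r_death)
        p_dcv = p_death * (r_cvd / r_death) if r_death > 0 else 0.0
        p_dnoncv = p_death - p_dcv
        T[si, _DEAD_CV] += p_dcv
        T[si, _DEAD_NONCV] += p_dnoncv
        F[si, EVENT_INDEX["cv_death"]] = p_dcv
        F[si, EVENT_INDEX["noncv_death"]] = p_dnoncv
        survive = 1.0 - p_death
        # step 2: one acute CV event at most, competing multinomial
        r_nf = {e: rates[e] * mult for e in NONFATAL_CV_EVENTS}
        r_tot = sum(r_nf.values())
        p_any = rate_to_prob(r_tot)
        if r_tot > 0:
            for e, r_e in r_nf.items():
                mass = survive * p_any * (r_e / r_tot)
                if mass < 0:
                    raise RuntimeError(f"negative transition mass for {e} from {s}")
                T[si, STATE_INDEX[EVENT_DESTINATION[e]]] += mass
                F[si, EVENT_INDEX[e]] = mass
        T[si, si] += survive * (1.0 - p_any)
        # step 3: adverse events, state-preserving
        for e in ADVERSE_EVENTS:
            F[si, EVENT_INDEX[e]] = survive * rate_to_prob(rates[e])
    return T, F


def step_cohort(occupancy: np.ndarray, T: np.ndarray, F: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Advance the cohort one cycle.

    Returns ``(next_occupancy, events_by_origin)`` with
    ``events_by_origin[s, e]`` the expected incident events of type ``e``
    among the fraction starting the cycle in state ``s``.  Mass is
    conserved exactly (rows of ``T`` sum to 1).
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if abs(occupancy.sum() - 1.0) > 1e-9:
        raise ValueError("occupancy must sum to 1")
    if np.any(occupancy < -1e-12):
        raise RuntimeError("negative occupancy mass — probability misconfiguration")
    return occupancy @ T, occupancy[:, None] * F


# --------------------------------------------------------------------------
# Trace container
# --------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Per-cycle record of one arm's cohort run.

    All masses are fractions of the cohort; ``cohort_size`` scales them to
    counts in reports.  ``occupancy[0]`` is the initial distribution and
    ``occupancy[k]`` the distribution at the end of cycle ``k``.
    Costs/QALYs are per patient.
    """

    arm: str
    cohort_size: float
    start_age: int
    ages: np.ndarray                 # (K,) age during each cycle
    occupancy: np.ndarray            # (K+1, n_states)
    events: np.ndarray               # (K, n_states, n_events) by origin state
    person_years: np.ndarray         # (K,) alive person-years (mid-cycle)
    cost: np.ndarray                 # (K,) undiscounted cost per patient
    qaly: np.ndarray                 # (K,) undiscounted QALY per patient
    cost_disc: np.ndarray            # (K,) discounted
    qaly_disc: np.ndarray            # (K,)

    @property
    def n_cycles(self) -> int:
        return len(self.ages)

    def event_totals(self) -> np.ndarray:
        """(K, n_events) incident event fractions summed over origin states."""
        return self.events.sum(axis=1)

    def cumulative_cv_events(self) -> float:
        """Lifetime cardiovascular events (all six types) per cohort member."""
        idx = [EVENT_INDEX[e] for e in CV_EVENTS]
        return float(self.event_totals()[:, idx].sum())

    def first_cv_events(self) -> np.ndarray:
        """(K,) first (from the event-free state) CV events per cycle."""
        idx = [EVENT_INDEX[e] for e in CV_EVENTS]
        return self.events[:, STATE_INDEX["no_cvd"], idx].sum(axis=1)

    @property
    def total_cost(self) -> float:
        return float(self.cost_disc.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_disc.sum())

    def to_dataframe(self) -> pd.DataFrame:
        totals = self.event_totals() * self.cohort_size
        data = {"cycle": np.arange(1, self.n_cycles + 1), "age": self.ages}
        for s, i in STATE_INDEX.items():
            data[f"occ_{s}"] = self.occupancy[1:, i]
        for e, i in EVENT_INDEX.items():
            data[f"ev_{e}"] = totals[:, i]
        data["person_years"] = self.person_years * self.cohort_size
        data["cost"] = self.cost
        data["qaly"] = self.qaly
        data["cost_disc"] = self.cost_disc
        data["qaly_disc"] = self.qaly_disc
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# --------------------------------------------------------------------------
# Cohort runner
# --------------------------------------------------------------------------

def run_cohort(inputs: ModelInputs, arm: str, horizon: int | str = "lifetime",
               cohort_size: float = 10_000) -> CohortTrace:
    """Run the deterministic cohort for one arm.

    ``horizon`` is a number of yearly cycles or ``"lifetime"`` (until the
    cohort is extinct or the terminal age is passed).  Trial-phase cycles
    use the trial probabilities; later cycles the risk-equation
    extrapolation under the active adherence scenario.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if horizon != "lifetime":
        horizon = int(horizon)
        if horizon < 1:
            raise ValueError("horizon must be at least 1 cycle")
    inputs.validate()
    start_age = inputs.country.start_age
    max_cycles = (horizon if horizon != "lifetime"
                  else inputs.country.terminal_age - start_age + 2)
    calib = _calibration(inputs)

    occ = np.zeros(_N_STATES)
    occ[STATE_INDEX["no_cvd"]] = 1.0
    occ_hist = [occ.copy()]
    ages, events, pys = [], [], []
    cost_u, qaly_u, cost_d, qaly_d = [], [], [], []

    alive_idx = [STATE_INDEX[s] for s in ALIVE_STATES]
    for k in range(1, max_cycles + 1):
        age = start_age + k - 1
        phase = "trial" if k <= inputs.options.trial_years else "post_trial"
        T, F = transition_matrix(inputs, arm, age, phase, calib)
        occ_next, ev = step_cohort(occ, T, F)
        ev_total = ev.sum(axis=0)
        cu, qu, cd, qd = econ.accrue_cycle(
            occ, occ_next, ev_total, age, k, inputs, arm, phase)
        ages.append(age)
        events.append(ev)
        alive_start = occ[alive_idx].sum()
        alive_end = occ_next[alive_idx].sum()
        pys.append(0.5 * (alive_start + alive_end))
        cost_u.append(cu)
        qaly_u.append(qu)
        cost_d.append(cd)
        qaly_d.append(qd)
        occ = occ_next
        occ_hist.append(occ.copy())
        if occ[alive_idx].sum() < 1e-9:
            break

    return CohortTrace(
        arm=arm,
        cohort_size=cohort_size,
        start_age=start_age,
        ages=np.asarray(ages),
        occupancy=np.asarray(occ_hist),
        events=np.asarray(events),
        person_years=np.asarray(pys),
        cost=np.asarray(cost_u),
        qaly=np.asarray(qaly_u),
        cost_disc=np.asarray(cost_d),
        qaly_disc=np.asarray(qaly_d),
    )
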