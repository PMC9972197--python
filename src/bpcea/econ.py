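"""Discounting, cost/QALY accrual, ICER/NMB and events-averted summaries.

Costs and QALYs are accrued per cycle on the start-of-cycle occupancy (no
half-cycle correction unless enabled), with acute-event costs and utility
decrements charged once in the cycle the event occurs and chronic-state
costs/utilities applying from the next cycle onward.  Both costs and
effects are discounted at the same country rate, with the first cycle
undiscounted: cycle ``k`` carries the factor ``(1 + d)^-(k-1)``.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .params import (
    ALIVE_STATES,
    ARMS,
    CV_EVENTS,
    EVENT_COLUMNS,
    EVENT_INDEX,
    STATE_INDEX,
    CountryProfile,
    ModelInputs,
)

if TYPE_CHECKING:  # pragma: no cover
    from .markov import CohortTrace


def discount_factor(rate: float, cycle: int) -> float:
    """``(1 + rate)^(-cycle)``; cycle 0 (and rate 0) give exactly 1."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    if cycle < 0:
        raise ValueError("cycle index must be non-negative")
    return (1.0 + rate) ** (-cycle)


def round_currency(value: float) -> int:
    """Round to a whole currency unit, halves away from zero."""
    return int(math.floor(abs(value) + 0.5) * (1 if value >= 0 else -1))


def icer(delta_cost: float, delta_qaly: float) -> float:
    """Incremental cost-effectiveness ratio; undefined for zero QALY gain."""
    if delta_qaly == 0:
        raise ZeroDivisionError("ICER undefined when the QALY increment is zero")
    return delta_cost / delta_qaly


def accrue_cycle(occ_start: np.ndarray, occ_end: np.ndarray,
                 event_totals: np.ndarray, age: float, cycle_index: int,
                 inputs: ModelInputs, arm: str, phase: str
                 ) -> tuple[float, float, float, float]:
    """Cost and QALY accrued in one cycle (per patient).

    ``event_totals`` follows :data:`~bpcea.params.EVENT_COLUMNS`.  Returns
    ``(cost, qaly, discounted cost, discounted qaly)``.  The yearly
    intervention cost is blended across the on-/off-target mix of the arm
    (attainment during the trial, the adherence scenario afterwards), since
    the off-target fraction receives standard-arm treatment.
    """
    costs, utils = inputs.costs, inputs.utilities
    a = (inputs.options.trial_attainment(arm) if phase == "trial"
         else inputs.adherence.fraction(arm))
    interv = (a * costs.intervention[arm]
              + (1.0 - a) * costs.intervention["standard"])

    occ = np.asarray(occ_start, dtype=float)
    if inputs.options.half_cycle_correction:
        occ = 0.5 * (occ + np.asarray(occ_end, dtype=float))

    cost = 0.0
    qaly = 0.0
    for s in ALIVE_STATES:
        m = occ[STATE_INDEX[s]]
        if m <= 0.0:
            continue
        cost += m * (costs.chronic_cost(s) + costs.background + interv)
        qaly += m * utils.state_utility(s, age)
    for e in EVENT_COLUMNS:
        n = event_totals[EVENT_INDEX[e]]
        if n <= 0.0:
            continue
        cost += n * costs.acute_cost(e)
        qaly -= n * utils.event_qaly_loss(e)
    d = discount_factor(inputs.country.discount_rate, cycle_index - 1)
    return cost, qaly, cost * d, qaly * d


@dataclass
class CEResult:
    """Cost-effectiveness comparison of the two arms.

    Costs/QALYs are per patient and discounted; ``icer`` is ``None`` with a
    ``dominance`` flag when the ratio is not meaningful (zero or negative
    QALY increment, or cost-saving dominance).
    """

    cost_intensive: float
    cost_standard: float
    qaly_intensive: float
    qaly_standard: float
    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str  # "none", "intensive_dominant", "intensive_dominated", "undefined"
    nmb: dict[float, float]
    events_averted_per_1000: float
    currency: str = ""
    country: str = ""

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["nmb"] = {f"{k:g}": v for k, v in self.nmb.items()}
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def events_averted(trace_intensive: "CohortTrace", trace_standard: "CohortTrace",
                   per: float = 1000) -> float:
    """Cardiovascular events averted by the intensive arm, per ``per`` patients."""
    diff = (trace_standard.cumulative_cv_events()
            - trace_intensive.cumulative_cv_events())
    return diff * per


def compute_ce(trace_intensive: "CohortTrace", trace_standard: "CohortTrace",
               country: CountryProfile) -> CEResult:
    """ICER, NMB at both WTP thresholds, and events averted per 1000."""
    c_int, c_std = trace_intensive.total_cost, trace_standard.total_cost
    e_int, e_std = trace_intensive.total_qaly, trace_standard.total_qaly
    dc, de = c_int - c_std, e_int - e_std
    if de == 0:
        ratio, dominance = None, "undefined"
    elif de > 0 and dc < 0:
        ratio, dominance = dc / de, "intensive_dominant"
    elif de < 0 and dc > 0:
        ratio, dominance = dc / de, "intensive_dominated"
    else:
        ratio, dominance = dc / de, "none"
    nmb = {wtp: wtp * de - dc for wtp in (country.wtp_lower, country.wtp_upper)}
    return CEResult(
        cost_intensive=c_int, cost_standard=c_std,
        qaly_intensive=e_int, qaly_standard=e_std,
        delta_cost=dc, delta_qaly=de, icer=ratio, dominance=dominance,
        nmb=nmb,
        events_averted_per_1000=events_averted(trace_intensive, trace_standard),
        currency=country.currency, country=country.country,
    )
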