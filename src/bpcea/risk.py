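"""Post-trial extrapolation: risk equations, competing mortality, adherence.

After the 4-year trial window the cohort's cardiovascular event risk is no
longer taken from the trial table but from a proportional-hazards risk
equation (SCORE2-style: ten-year risk ``1 - S0^exp(beta . (x - xbar))``),
annualized, split across the individual event types, and blended by the
fraction of each arm still at its blood-pressure target.  Non-CVD death is
the life-table all-cause risk net of the modelled cardiovascular death, so
the two death causes together never exceed the national all-cause risk.
"""
from __future__ import annotations

import logging
from typing import Mapping

import numpy as np

from .params import (
    LifeTable,
    RiskCoefficients,
    RiskProfile,
    prob_to_rate,
    rate_to_prob,
)

logger = logging.getLogger("bpcea")


def ten_year_cvd_risk(profile: RiskProfile, coefficients: RiskCoefficients) -> float:
    """Ten-year cardiovascular risk for one covariate profile.

    ``risk = scale * (1 - s0 ** exp(sum beta_i (x_i - mean_i)))``, clipped to
    [0, 1].  Raises :class:`ValueError` naming any covariate the profile
    lacks.
    """
    coefficients.validate()
    lp = 0.0
    for name, beta, mean in zip(coefficients.covariates, coefficients.betas,
                                coefficients.means):
        lp += beta * (profile.covariate(name) - mean)
    risk = 1.0 - coefficients.s0 ** np.exp(lp)
    risk *= coefficients.scale
    return float(min(1.0, max(0.0, risk)))


def annualize_composite_risk(ten_year_risk: float,
                             event_mix: Mapping[str, float]) -> dict[str, float]:
    """Split a ten-year composite risk into yearly per-event probabilities.

    The composite is rescaled to a yearly rate; each event receives its
    share of that rate (shares must sum to 1) and is transformed back to a
    probability.  Per-event rates therefore sum exactly to the annualized
    composite rate.
    """
    shares = dict(event_mix)
    total = sum(shares.values())
    if shares and abs(total - 1.0) > 1e-9:
        raise ValueError(f"event-mix shares sum to {total}, expected 1")
    if any(v < 0 for v in shares.values()):
        raise ValueError("event-mix shares must be non-negative")
    yearly_rate = prob_to_rate(ten_year_risk, 10.0)
    return {event: rate_to_prob(yearly_rate * share)
            for event, share in shares.items()}


def blend_adherence(p_on_target: float, p_off_target: float,
                    adherent_fraction: float) -> float:
    """Mix on-target and off-target yearly probabilities in rate space.

    ``1 - exp(-(a * r_on + (1 - a) * r_off))`` with ``r = -ln(1 - p)``; the
    result always lies between the two anchors and is monotone in ``a``.
    """
    if not 0.0 <= adherent_fraction <= 1.0:
        raise ValueError(f"adherent fraction {adherent_fraction} outside [0, 1]")
    r = (adherent_fraction * prob_to_rate(p_on_target)
         + (1.0 - adherent_fraction) * prob_to_rate(p_off_target))
    return rate_to_prob(r)


def noncvd_death_prob(age: float, life_table: LifeTable,
                      modeled_cv_death: float) -> float:
    """Non-cardiovascular yearly death probability at ``age``.

    All-cause life-table risk minus the modelled cardiovascular death risk,
    subtracted in rate space and floored at zero (with a logged warning when
    the floor bites).  With no modelled CV death this is the life-table
    probability exactly.
    """
    qx = life_table.qx_at(age)
    if qx >= 1.0:
        return 1.0
    r_all = prob_to_rate(qx)
    r_cv = prob_to_rate(modeled_cv_death)
    if r_cv > r_all:
        logger.warning(
            "modelled CV death rate %.3g exceeds all-cause rate %.3g at age %s; "
            "flooring non-CVD death at 0", r_cv, r_all, age)
        return 0.0
    return rate_to_prob(r_all - r_cv)
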