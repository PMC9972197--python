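"""Synthetic model inputs: a complete, plausible stand-in for the
country-specific cost/utility tables, life tables and risk-equation
coefficients that national analyses would supply.

The yearly event probabilities are the published STEP-trial estimates
(embedded verbatim below); everything else — costs, utilities, Gompertz
life tables and proportional-hazards coefficients — is synthesized
deterministically from a seed.  Cost magnitudes are anchored to the order
of magnitude of published lifetime totals for each country (for example,
lifetime costs near ¥100 000 per patient in China) so that sign and
ranking assertions on the fixtures are meaningful; they are NOT the
confidential national inputs and carry no authority beyond that.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    ARMS,
    CHRONIC_STATES,
    TABLE_EVENTS,
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
    rate_to_prob,
)

# --------------------------------------------------------------------------
# STEP-trial yearly transition probabilities (mean, SD), Beta-distributed.
# Estimated over the 4-year trial period; the primary composite comprises
# stroke, acute coronary syndrome, acute heart failure, coronary
# revascularization, atrial fibrillation and cardiovascular death.
# --------------------------------------------------------------------------

TRIAL_EVENT_RATES: dict[tuple[str, str], tuple[float, float]] = {
    ("intensive", "primary_composite"): (0.008776182, 0.001431865),
    ("standard", "primary_composite"): (0.011683970, 0.001644868),
    ("intensive", "stroke"): (0.002840265, 0.000817006),
    ("standard", "stroke"): (0.004185055, 0.000988161),
    ("intensive", "acs"): (0.003256504, 0.000874643),
    ("standard", "acs"): (0.004838185, 0.001062126),
    ("intensive", "acute_hf"): (0.000299955, 0.000265844),
    ("standard", "acute_hf"): (0.000899595, 0.000458898),
    ("intensive", "revascularization"): (0.000999500, 0.000485107),
    ("standard", "revascularization"): (0.001998001, 0.000683520),
    ("intensive", "af"): (0.001417103, 0.000577506),
    ("standard", "af"): (0.001467614, 0.000585969),
    ("intensive", "cv_death"): (0.001062262, 0.000500090),
    ("standard", "cv_death"): (0.001467614, 0.000585969),
    ("intensive", "hypotension"): (0.008715688, 0.001426965),
    ("standard", "hypotension"): (0.006685776, 0.001247404),
    ("intensive", "dizziness"): (0.002662037, 0.000791028),
    ("standard", "dizziness"): (0.002882637, 0.000820646),
    ("intensive", "syncope"): (0.000353711, 0.000288676),
    ("standard", "syncope"): (0.000117171, 0.000165681),
    ("intensive", "fracture"): (0.000884983, 0.000456498),
    ("standard", "fracture"): (0.001114796, 0.000510791),
    ("intensive", "aki"): (0.003386435, 0.000909393),
    ("standard", "aki"): (0.003724914, 0.000949418),
    ("intensive", "all_cause_death"): (0.003971272, 0.000965527),
    ("standard", "all_cause_death"): (0.003770095, 0.000938088),
}

#: Intensive/standard relative risk of the primary composite (log-normal).
TRIAL_PRIMARY_RELATIVE_RISK = (0.751130175, 0.215494892)

#: Primary-outcome incidence observed in the trial, per 100 person-years.
OBSERVED_TRIAL_INCIDENCE = {"intensive": 1.00, "standard": 1.40}


def trial_event_rate_table() -> EventRateTable:
    """The trial probability table as an :class:`EventRateTable`."""
    return EventRateTable({
        (arm, event): EventRate(mean, sd, "beta")
        for (arm, event), (mean, sd) in TRIAL_EVENT_RATES.items()
    })


# --------------------------------------------------------------------------
# Country templates
# --------------------------------------------------------------------------

# Gompertz all-cause mortality (a = baseline yearly hazard at 60, b = slope
# per year) roughly reproducing each country's remaining life expectancy at
# 66; China has the highest old-age mortality of the three.
_COUNTRY_TEMPLATES: dict[str, dict] = {
    "CN": {
        "currency": "CNY",
        "discount": 0.03,
        "wtp": (89_300.0, 267_900.0),
        "ppp_to_usd": 21_364.0 / 89_300.0,
        "gompertz": (0.0070, 0.105),
        "costs": {
            "intervention": {"intensive": 3000.0, "standard": 1500.0},
            "background": 5200.0,
            "chronic": {"chronic_chd": 1800.0, "post_stroke": 3000.0,
                        "chronic_hf": 2600.0, "chronic_af": 1500.0},
            "acute": {"stroke": 18000.0, "acs": 20000.0, "acute_hf": 12000.0,
                      "revascularization": 30000.0, "af": 6000.0,
                      "cv_death": 8000.0, "hypotension": 800.0,
                      "dizziness": 400.0, "syncope": 1500.0,
                      "fracture": 16000.0, "aki": 7000.0},
        },
    },
    "US": {
        "currency": "USD",
        "discount": 0.03,
        "wtp": (50_000.0, 100_000.0),
        "ppp_to_usd": 1.0,
        "gompertz": (0.0050, 0.102),
        "costs": {
            "intervention": {"intensive": 1450.0, "standard": 750.0},
            "background": 15500.0,
            "chronic": {"chronic_chd": 2500.0, "post_stroke": 4000.0,
                        "chronic_hf": 3500.0, "chronic_af": 2000.0},
            "acute": {"stroke": 22000.0, "acs": 25000.0, "acute_hf": 17000.0,
                      "revascularization": 35000.0, "af": 8000.0,
                      "cv_death": 11000.0, "hypotension": 500.0,
                      "dizziness": 300.0, "syncope": 1800.0,
                      "fracture": 18000.0, "aki": 9000.0},
        },
    },
    "UK": {
        "currency": "GBP",
        "discount": 0.035,
        "wtp": (20_000.0, 30_000.0),
        "ppp_to_usd": 29_940.0 / 20_000.0,
        "gompertz": (0.0056, 0.100),
        "costs": {
            "intervention": {"intensive": 640.0, "standard": 330.0},
            "background": 4600.0,
            "chronic": {"chronic_chd": 900.0, "post_stroke": 1600.0,
                        "chronic_hf": 1300.0, "chronic_af": 700.0},
            "acute": {"stroke": 9000.0, "acs": 8000.0, "acute_hf": 6000.0,
                      "revascularization": 12000.0, "af": 3000.0,
                      "cv_death": 4000.0, "hypotension": 250.0,
                      "dizziness": 150.0, "syncope": 800.0,
                      "fracture": 7000.0, "aki": 3500.0},
        },
    },
}

# Baseline utility 0.80 at age 66 with a 0.003/year age decrement; the
# post-stroke state carries the largest chronic decrement.  Acute events
# subtract their decrement for the stated number of weeks only.
_UTILITY_TEMPLATE = {
    "baseline": 0.80,
    "age_decrement": 0.003,
    "state_decrement": {"chronic_chd": 0.10, "post_stroke": 0.25,
                        "chronic_hf": 0.18, "chronic_af": 0.06},
    "event_decrement": {
        "stroke": (0.20, 4.0), "acs": (0.12, 4.0), "acute_hf": (0.12, 4.0),
        "revascularization": (0.08, 4.0), "af": (0.06, 4.0),
        "aki": (0.10, 4.0), "fracture": (0.15, 12.0),
        "hypotension": (0.05, 2.0), "dizziness": (0.03, 2.0),
        "syncope": (0.06, 2.0),
    },
}


@dataclass
class SyntheticProfile:
    """Recipe for one synthetic country input bundle.

    The seed fully determines every generated number; ``cost_scale``
    multiplies all costs and ``cost_cv`` is the coefficient of variation
    assumed for cost parameters in probabilistic sensitivity analysis.
    """

    country: str = "CN"
    seed: int = 0
    cost_scale: float = 1.0
    cost_cv: float = 0.20
    utility_sd: float = 0.03
    jitter: float = 0.02  # relative spread of the seeded cost/utility jitter

    def __post_init__(self) -> None:
        if self.country not in _COUNTRY_TEMPLATES:
            raise ValueError(f"unknown country template {self.country!r}; "
                             f"choose from {sorted(_COUNTRY_TEMPLATES)}")


def generate_lifetable(a: float, b: float, ages: range = range(60, 101)) -> LifeTable:
    """Gompertz life table: ``qx(age) = 1 - exp(-a e^{b (age - 60)})``.

    Strictly increasing in age for ``b > 0``; the last tabulated age is
    terminal (``qx = 1``).
    """
    if a <= 0 or b < 0:
        raise ValueError("Gompertz parameters require a > 0 and b >= 0")
    ages = list(ages)
    qx = [min(1.0, rate_to_prob(a * np.exp(b * (age - ages[0])))) for age in ages]
    qx[-1] = 1.0
    return LifeTable(ages, qx)


def generate_risk_coefficients(profile: SyntheticProfile) -> RiskCoefficients:
    """Synthetic proportional-hazards coefficients with positive age and SBP
    effects, deterministic per seed."""
    rng = np.random.default_rng(profile.seed + 101)
    jit = lambda x: float(x * (1.0 + profile.jitter * rng.uniform(-1, 1)))
    # S0 near 0.75 with a calibration scale of 1.4: a ten-year composite
    # risk around 35% at the covariate means (age 70, SBP 140), in line
    # with risk-equation estimates for older high-cardiovascular-risk
    # hypertensive cohorts — well above the protocolized within-trial
    # event rates, which is why a risk equation (and not a trial-rate
    # extrapolation) drives the post-trial phase.
    s0 = float(np.clip(0.75 + 0.02 * rng.uniform(-1, 1), 0.701, 0.979))
    coef = RiskCoefficients(
        name="synthetic",
        covariates=("age", "sbp", "diabetes", "smoking", "sex"),
        betas=(jit(0.072), jit(0.016), jit(0.50), jit(0.42), jit(-0.25)),
        means=(70.0, 140.0, 0.19, 0.20, 0.535),
        s0=s0,
        scale=jit(1.4),
    )
    coef.validate()
    return coef


def generate_inputs(profile: SyntheticProfile) -> ModelInputs:
    """Build a complete, validated :class:`ModelInputs` bundle.

    The event-rate table is the trial table exactly; costs and utilities
    are the country template with a small seeded jitter; the life table is
    Gompertz; risk-equation coefficients are synthetic.
    """
    tpl = _COUNTRY_TEMPLATES[profile.country]
    rng = np.random.default_rng(profile.seed)

    def jitter(x: float) -> float:
        return float(x * (1.0 + profile.jitter * rng.uniform(-1, 1)))

    cost_tpl = tpl["costs"]
    costs = CostSet(
        currency=tpl["currency"],
        intervention={arm: jitter(v) * profile.cost_scale
                      for arm, v in cost_tpl["intervention"].items()},
        acute={k: jitter(v) * profile.cost_scale for k, v in cost_tpl["acute"].items()},
        chronic={k: jitter(v) * profile.cost_scale for k, v in cost_tpl["chronic"].items()},
        background=jitter(cost_tpl["background"]) * profile.cost_scale,
    )
    utilities = UtilitySet(
        baseline=float(np.clip(jitter(_UTILITY_TEMPLATE["baseline"]), 0.0, 1.0)),
        age_decrement=_UTILITY_TEMPLATE["age_decrement"],
        anchor_age=66.0,
        state_decrement={k: float(np.clip(jitter(v), 0.0, 1.0))
                         for k, v in _UTILITY_TEMPLATE["state_decrement"].items()},
        event_decrement={k: (float(np.clip(jitter(d), 0.0, 1.0)), w)
                         for k, (d, w) in _UTILITY_TEMPLATE["event_decrement"].items()},
    )
    country = CountryProfile(
        country=profile.country,
        currency=tpl["currency"],
        discount_rate=tpl["discount"],
        wtp_lower=tpl["wtp"][0],
        wtp_upper=tpl["wtp"][1],
        ppp_to_usd=tpl["ppp_to_usd"],
    )
    a, b = tpl["gompertz"]
    # Achieved on-treatment systolic pressures: intensive near 127 mm Hg,
    # standard near 136 mm Hg.
    profiles = {
        "intensive": RiskProfile(age=66.0, sbp=127.0, sex=0.535,
                                 diabetes=0.19, smoking=0.20),
        "standard": RiskProfile(age=66.0, sbp=136.0, sex=0.535,
                                diabetes=0.19, smoking=0.20),
    }
    inputs = ModelInputs(
        rates=trial_event_rate_table(),
        costs=costs,
        utilities=utilities,
        adherence=AdherenceScenario.named("base"),
        country=country,
        life_table=generate_lifetable(a, b),
        risk_coefficients=generate_risk_coefficients(profile),
        risk_profiles=profiles,
        options=ModelOptions(),
    )
    inputs.validate()
    return inputs


# --------------------------------------------------------------------------
# Subgroup fixtures
# --------------------------------------------------------------------------

#: (start age, CV-rate scale applied to both arms, SBP shift in mm Hg,
#: diabetes prevalence override or None).  Scales are synthetic but ordered
#: the way trial subgroups order their event risks (men > women, older and
#: higher-SBP strata > their complements).
SUBGROUP_DEFS: dict[str, dict] = {
    "age_60_69": {"start_age": 65, "rate_scale": 0.80, "sbp_shift": 0.0, "diabetes": None},
    "age_70_80": {"start_age": 75, "rate_scale": 1.30, "sbp_shift": 0.0, "diabetes": None},
    "sex_m": {"start_age": 66, "rate_scale": 1.25, "sbp_shift": 0.0, "diabetes": None, "sex": 0.0},
    "sex_f": {"start_age": 66, "rate_scale": 0.85, "sbp_shift": 0.0, "diabetes": None, "sex": 1.0},
    "sbp_le138": {"start_age": 66, "rate_scale": 0.90, "sbp_shift": -8.0, "diabetes": None},
    "sbp_139_151": {"start_age": 66, "rate_scale": 1.00, "sbp_shift": 0.0, "diabetes": None},
    "sbp_ge152": {"start_age": 66, "rate_scale": 1.20, "sbp_shift": 10.0, "diabetes": None},
    "diabetes_yes": {"start_age": 66, "rate_scale": 1.40, "sbp_shift": 0.0, "diabetes": 1.0},
    "diabetes_no": {"start_age": 66, "rate_scale": 0.90, "sbp_shift": 0.0, "diabetes": 0.0},
    "app_bp": {"start_age": 66, "rate_scale": 0.95, "sbp_shift": 0.0, "diabetes": None},
    "usual_bp": {"start_age": 66, "rate_scale": 1.05, "sbp_shift": 0.0, "diabetes": None},
}


def generate_subgroup_rates(scale: float) -> EventRateTable:
    """Trial rate table with all cardiovascular rows scaled by ``scale``
    (both arms, so the arm relative risk is preserved)."""
    table = trial_event_rate_table()
    for arm in ARMS:
        for event in ("primary_composite", "stroke", "acs", "acute_hf",
                      "revascularization", "af", "cv_death"):
            table.set_mean(arm, event, min(0.999, scale * table.prob(arm, event)))
    return table
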