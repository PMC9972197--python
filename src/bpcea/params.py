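"""Domain types, parameter-table ingestion and the probability/rate calculus.

Everything downstream (the cohort engine, the risk extrapolation, the
sensitivity machinery) works in terms of the objects defined here.  The
central container is :class:`ModelInputs`, a fully validated bundle of
yearly event probabilities, costs, utilities, adherence assumptions, a
national life table and a cardiovascular risk equation for one country.

Probabilities and rates
-----------------------
Yearly transition probabilities ``p`` and instantaneous yearly rates ``r``
are interconverted under the usual constant-hazard assumption::

    r = -ln(1 - p) / t          p = 1 - exp(-r * t)

All blending, rescaling and competing-risk arithmetic in this package is
done in rate space and transformed back, so that combined probabilities
never leave [0, 1).
"""
from __future__ import annotations

import copy
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("bpcea")

# --------------------------------------------------------------------------
# Labels
# --------------------------------------------------------------------------

#: The six live/dead health states plus the cause-split of death.  Death is
#: modelled as two absorbing states (cardiovascular / non-cardiovascular) so
#: that cardiovascular-death events and life-table competing mortality can be
#: tallied separately; the reported "death" state is their union.
STATES = (
    "no_cvd",
    "chronic_chd",
    "post_stroke",
    "chronic_hf",
    "chronic_af",
    "dead_cv",
    "dead_noncv",
)
ALIVE_STATES = STATES[:5]
CHRONIC_STATES = STATES[1:5]
DEAD_STATES = STATES[5:]
STATE_INDEX = {s: i for i, s in enumerate(STATES)}

ARMS = ("intensive", "standard")

#: Acute cardiovascular events making up the primary composite outcome.
CV_EVENTS = ("stroke", "acs", "acute_hf", "revascularization", "af", "cv_death")
NONFATAL_CV_EVENTS = CV_EVENTS[:5]
#: Treatment-related adverse events (state-preserving; cost/utility only).
ADVERSE_EVENTS = ("hypotension", "dizziness", "syncope", "fracture", "aki")
#: Columns of the per-cycle incident-event tally.
EVENT_COLUMNS = CV_EVENTS + ADVERSE_EVENTS + ("noncv_death",)
EVENT_INDEX = {e: i for i, e in enumerate(EVENT_COLUMNS)}

#: Rows of the yearly-probability input table (one per arm).
TABLE_EVENTS = ("primary_composite",) + CV_EVENTS + ADVERSE_EVENTS + ("all_cause_death",)

#: New cardiovascular events move the survivor to the chronic sequela state
#: of that event; the most recent event defines the state.
EVENT_DESTINATION = {
    "stroke": "post_stroke",
    "acs": "chronic_chd",
    "revascularization": "chronic_chd",
    "acute_hf": "chronic_hf",
    "af": "chronic_af",
}

DISTRIBUTIONS = ("beta", "log_normal")


# --------------------------------------------------------------------------
# Probability <-> rate calculus
# --------------------------------------------------------------------------

def prob_to_rate(p: float, t: float = 1.0) -> float:
    """Convert a probability over duration ``t`` years to a yearly rate.

    ``r = -ln(1 - p) / t``.  Raises :class:`ValueError` outside ``0 <= p < 1``
    or for non-positive ``t``.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0.0) or np.any(p_arr >= 1.0):
        raise ValueError(f"probability must be in [0, 1), got {p!r}")
    if t <= 0:
        raise ValueError(f"duration must be positive, got {t!r}")
    out = -np.log1p(-p_arr) / t
    return float(out) if np.isscalar(p) or p_arr.ndim == 0 else out


def rate_to_prob(r: float, t: float = 1.0) -> float:
    """Convert a yearly rate to a probability over ``t`` years: ``1 - exp(-rt)``."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0.0):
        raise ValueError(f"rate must be non-negative, got {r!r}")
    if t <= 0:
        raise ValueError(f"duration must be positive, got {t!r}")
    out = -np.expm1(-r_arr * t)
    return float(out) if np.isscalar(r) or r_arr.ndim == 0 else out


def rescale_probability(p: float, from_t: float, to_t: float) -> float:
    """Re-express a probability over ``from_t`` years on a ``to_t``-year basis.

    Composition of the two hazard transforms; identity when the durations
    match, monotone in both ``p`` and ``to_t``.
    """
    return rate_to_prob(prob_to_rate(p, from_t), to_t)


# --------------------------------------------------------------------------
# Event-rate table
# --------------------------------------------------------------------------

@dataclass
class EventRate:
    """Mean yearly probability of one event in one arm plus its PSA spread."""

    mean: float
    sd: float
    distribution: str = "beta"

    def validate(self, label: str = "") -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError(f"{label}: probability {self.mean} outside [0, 1]")
        if self.sd < 0.0:
            raise ValueError(f"{label}: SD {self.sd} negative")
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"{label}: unknown distribution {self.distribution!r}")


class EventRateTable:
    """Yearly event probabilities by (arm, event), mirroring the trial table.

    All thirteen events (`TABLE_EVENTS`) must be present for both arms.
    """

    def __init__(self, rates: Mapping[tuple[str, str], EventRate]):
        self._rates: dict[tuple[str, str], EventRate] = dict(rates)
        self.validate()

    def validate(self) -> None:
        for arm in ARMS:
            for event in TABLE_EVENTS:
                key = (arm, event)
                if key not in self._rates:
                    raise ValueError(f"event rate table missing row ({arm}, {event})")
                self._rates[key].validate(label=f"({arm}, {event})")

    def __getitem__(self, key: tuple[str, str]) -> EventRate:
        return self._rates[key]

    def prob(self, arm: str, event: str) -> float:
        return self._rates[(arm, event)].mean

    def rate(self, arm: str, event: str) -> float:
        return prob_to_rate(self._rates[(arm, event)].mean)

    def set_mean(self, arm: str, event: str, value: float) -> None:
        self._rates[(arm, event)] = replace(self._rates[(arm, event)], mean=value)
        self._rates[(arm, event)].validate(label=f"({arm}, {event})")

    def copy(self) -> "EventRateTable":
        return EventRateTable({k: replace(v) for k, v in self._rates.items()})

    # -- I/O ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"event": e, "arm": a, "mean": r.mean, "sd": r.sd, "distribution": r.distribution}
            for (a, e), r in sorted(self._rates.items(), key=lambda kv: (TABLE_EVENTS.index(kv[0][1]), kv[0][0]))
        ]
        return pd.DataFrame(rows, columns=["event", "arm", "mean", "sd", "distribution"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EventRateTable":
        required = {"event", "arm", "mean", "sd", "distribution"}
        if not required.issubset(df.columns):
            raise ValueError(f"rate table needs columns {sorted(required)}")
        rates = {}
        for i, row in df.iterrows():
            arm, event = str(row["arm"]), str(row["event"])
            if arm not in ARMS:
                raise ValueError(f"row {i} ({event}): unknown arm {arm!r}")
            if event not in TABLE_EVENTS:
                raise ValueError(f"row {i}: unknown event {event!r}")
            er = EventRate(float(row["mean"]), float(row["sd"]), str(row["distribution"]))
            er.validate(label=f"row {i} ({arm}, {event})")
            rates[(arm, event)] = er
        return cls(rates)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False,
                                   float_format=lambda x: repr(float(x)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventRateTable":
        return cls.from_dataframe(pd.read_csv(path, float_precision="round_trip"))


# --------------------------------------------------------------------------
# Costs and utilities
# --------------------------------------------------------------------------

CURRENCIES = ("CNY", "USD", "GBP")


@dataclass
class CostSet:
    """Health-care payer costs, all in one native currency.

    ``intervention`` is the yearly cost of blood-pressure control per arm
    (medications + clinic visits + monitoring); ``acute`` holds one-time
    costs per cardiovascular or adverse event; ``chronic`` yearly costs per
    live health state; ``background`` the yearly non-CVD health-care cost.
    """

    currency: str
    intervention: dict[str, float]
    acute: dict[str, float]
    chronic: dict[str, float]
    background: float = 0.0

    def validate(self) -> None:
        if self.currency not in CURRENCIES:
            raise ValueError(f"unknown currency {self.currency!r}")
        for arm in ARMS:
            if arm not in self.intervention:
                raise ValueError(f"intervention cost missing for arm {arm!r}")
        for name, value in self.iter_items():
            if value < 0:
                raise ValueError(f"cost {name} is negative ({value})")

    def iter_items(self) -> Iterable[tuple[str, float]]:
        for arm, v in self.intervention.items():
            yield f"intervention.{arm}", v
        for ev, v in self.acute.items():
            yield f"acute.{ev}", v
        for st, v in self.chronic.items():
            yield f"chronic.{st}", v
        yield "background", self.background

    def acute_cost(self, event: str) -> float:
        return self.acute.get(event, 0.0)

    def chronic_cost(self, state: str) -> float:
        return self.chronic.get(state, 0.0)


@dataclass
class UtilitySet:
    """Health-state utilities and acute-event decrements.

    The utility of a live state at age ``x`` is
    ``baseline - age_decrement * (x - anchor_age) - state_decrement[state]``
    (additive decrements, clipped to [0, 1]).  Acute events subtract
    ``decrement * weeks / 52`` in the cycle they occur; the defaults follow
    the convention of 4 weeks for acute kidney injury, 12 weeks for
    fracture and 2 weeks for the other adverse events.
    """

    baseline: float
    age_decrement: float
    anchor_age: float
    state_decrement: dict[str, float]
    event_decrement: dict[str, tuple[float, float]]  # event -> (decrement, weeks)

    def validate(self) -> None:
        if not 0.0 <= self.baseline <= 1.0:
            raise ValueError(f"baseline utility {self.baseline} outside [0, 1]")
        for st, d in self.state_decrement.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"state decrement {st}={d} outside [0, 1]")
        for ev, (d, weeks) in self.event_decrement.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"event decrement {ev}={d} outside [0, 1]")
            if not 0.0 < weeks <= 52.0:
                raise ValueError(f"event {ev} duration {weeks} weeks outside (0, 52]")

    def state_utility(self, state: str, age: float) -> float:
        if state in DEAD_STATES:
            return 0.0
        u = self.baseline - self.age_decrement * (age - self.anchor_age)
        u -= self.state_decrement.get(state, 0.0)
        return min(1.0, max(0.0, u))

    def event_qaly_loss(self, event: str) -> float:
        d, weeks = self.event_decrement.get(event, (0.0, 1.0))
        return d * weeks / 52.0


# --------------------------------------------------------------------------
# Adherence, country, life table
# --------------------------------------------------------------------------

@dataclass
class AdherenceScenario:
    """Post-trial fraction of each arm that keeps its assigned target.

    The non-adherent fraction of either arm reverts to standard-arm event
    rates.  Named scenarios follow the trial-based convention: base
    (70%/75%), worst (0%/100%), best (100%/75%).
    """

    name: str
    intensive: float
    standard: float

    NAMED = {"base": (0.70, 0.75), "worst": (0.0, 1.0), "best": (1.00, 0.75)}

    def __post_init__(self) -> None:
        for a in (self.intensive, self.standard):
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"adherent fraction {a} outside [0, 1]")

    @classmethod
    def named(cls, name: str) -> "AdherenceScenario":
        if name not in cls.NAMED:
            raise ValueError(f"unknown adherence scenario {name!r}; choose from {sorted(cls.NAMED)}")
        i, s = cls.NAMED[name]
        return cls(name, i, s)

    def fraction(self, arm: str) -> float:
        return self.intensive if arm == "intensive" else self.standard


@dataclass
class CountryProfile:
    """Country-level analysis settings: discounting, WTP thresholds, ages."""

    country: str
    currency: str
    discount_rate: float
    wtp_lower: float
    wtp_upper: float
    ppp_to_usd: float = 1.0
    start_age: int = 66
    terminal_age: int = 100

    def validate(self) -> None:
        if not 0.0 <= self.discount_rate <= 0.2:
            raise ValueError(f"discount rate {self.discount_rate} outside [0, 0.2]")
        if not self.wtp_lower < self.wtp_upper:
            raise ValueError("lower WTP threshold must be below the upper one")
        if self.currency not in CURRENCIES:
            raise ValueError(f"unknown currency {self.currency!r}")
        if self.terminal_age <= self.start_age:
            raise ValueError("terminal age must exceed start age")


class LifeTable:
    """Age-indexed yearly all-cause death probabilities (``qx``).

    Ages beyond the tabulated range fall under the terminal rule: the death
    probability is 1.
    """

    def __init__(self, ages: Iterable[int], qx: Iterable[float]):
        self.ages = np.asarray(list(ages), dtype=int)
        self.qx = np.asarray(list(qx), dtype=float)
        if self.ages.shape != self.qx.shape or self.ages.size == 0:
            raise ValueError("life table ages and qx must be equal-length, non-empty")
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("life table ages must be consecutive integers")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValueError("life table probabilities must lie in [0, 1]")
        self._lo, self._hi = int(self.ages[0]), int(self.ages[-1])

    def qx_at(self, age: float) -> float:
        a = int(math.floor(age))
        if a < self._lo:
            raise ValueError(f"age {age} below life-table range (starts {self._lo})")
        if a > self._hi:
            return 1.0
        return float(self.qx[a - self._lo])

    def survival_from(self, age: int, years: int) -> np.ndarray:
        """Cumulative survival at the end of each of ``years`` yearly steps."""
        probs = np.array([self.qx_at(age + k) for k in range(years)])
        return np.cumprod(1.0 - probs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False,
                                   float_format=lambda x: repr(float(x)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path, float_precision="round_trip")
        if not {"age", "qx"}.issubset(df.columns):
            raise ValueError("life table CSV needs columns age,qx")
        return cls(df["age"].astype(int), df["qx"].astype(float))


# --------------------------------------------------------------------------
# Risk-equation containers (used by risk.py; defined here so ModelInputs is
# self-contained)
# --------------------------------------------------------------------------

@dataclass
class RiskCoefficients:
    """Proportional-hazards risk-equation parameters.

    Ten-year event risk is ``1 - s0 ** exp(sum(beta * (x - mean)))`` scaled
    by ``scale``; the coefficient files follow the SCORE2-style layout of a
    named covariate list with log-hazard coefficients and covariate means.
    """

    name: str
    covariates: tuple[str, ...]
    betas: tuple[float, ...]
    means: tuple[float, ...]
    s0: float
    scale: float = 1.0

    def validate(self) -> None:
        if not 0.0 < self.s0 <= 1.0:
            raise ValueError(f"baseline survival {self.s0} outside (0, 1]")
        if not (len(self.covariates) == len(self.betas) == len(self.means)):
            raise ValueError("covariates, betas and means must be equal length")
        if self.scale < 0:
            raise ValueError("calibration scale must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# model: {self.name}\n")
            fh.write(f"# s0: {self.s0!r}\n")
            fh.write(f"# scale: {self.scale!r}\n")
            fh.write("covariate,beta,mean\n")
            for c, b, m in zip(self.covariates, self.betas, self.means):
                fh.write(f"{c},{b!r},{m!r}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RiskCoefficients":
        meta: dict[str, str] = {}
        rows: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    key, _, value = line.lstrip("# ").partition(":")
                    meta[key.strip()] = value.strip()
                elif line:
                    rows.append(line)
        if rows and rows[0].startswith("covariate"):
            rows = rows[1:]
        covs, betas, means = [], [], []
        for r in rows:
            c, b, m = r.split(",")
            covs.append(c)
            betas.append(float(b))
            means.append(float(m))
        obj = cls(
            name=meta.get("model", "unnamed"),
            covariates=tuple(covs),
            betas=tuple(betas),
            means=tuple(means),
            s0=float(meta["s0"]),
            scale=float(meta.get("scale", 1.0)),
        )
        obj.validate()
        return obj


@dataclass
class RiskProfile:
    """Covariate values for the risk equation (one representative patient)."""

    age: float
    sbp: float
    sex: float = 0.5  # cohort fraction female
    diabetes: float = 0.0
    smoking: float = 0.0
    extra: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.age < 60:
            raise ValueError(f"age {self.age} below the supported range (>= 60)")
        if not 80 <= self.sbp <= 250:
            raise ValueError(f"SBP {self.sbp} outside [80, 250] mm Hg")

    def covariate(self, name: str) -> float:
        if hasattr(self, name) and name != "extra":
            return float(getattr(self, name))
        if name in self.extra:
            return float(self.extra[name])
        raise ValueError(f"risk profile is missing covariate {name!r}")

    def at_age(self, age: float) -> "RiskProfile":
        return replace(self, age=age)

    def to_dict(self) -> dict:
        d = {"age": self.age, "sbp": self.sbp, "sex": self.sex,
             "diabetes": self.diabetes, "smoking": self.smoking}
        d.update(self.extra)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "RiskProfile":
        d = dict(d)
        base = {k: float(d.pop(k)) for k in ("age", "sbp", "sex", "diabetes", "smoking") if k in d}
        return cls(extra={k: float(v) for k, v in d.items()}, **base)


# --------------------------------------------------------------------------
# The full input bundle
# --------------------------------------------------------------------------

@dataclass
class ModelOptions:
    """Structural switches and scenario hooks of the cohort engine."""

    trial_years: int = 4
    #: Fraction of each arm reaching its blood-pressure target during the
    #: trial period; the remainder experiences standard-arm event rates.
    trial_attainment_intensive: float = 0.70
    trial_attainment_standard: float = 0.75
    repeated_cvd_multiplier: float = 1.0
    #: Excess cardiovascular case fatality of established disease: the
    #: cardiovascular death rate in the chronic states is the first-event
    #: rate times this factor (survivors of stroke/heart failure/coronary
    #: disease do not face general-population cardiovascular mortality).
    chronic_cv_death_multiplier: float = 4.0
    treatment_effect_hr: float | None = None
    post_trial_risk_scale: float = 1.0
    half_cycle_correction: bool = False

    def validate(self) -> None:
        if self.trial_years < 0:
            raise ValueError("trial_years must be >= 0")
        for a in (self.trial_attainment_intensive, self.trial_attainment_standard):
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"trial attainment {a} outside [0, 1]")
        if self.repeated_cvd_multiplier < 0:
            raise ValueError("repeated-CVD multiplier must be >= 0")
        if self.chronic_cv_death_multiplier < 0:
            raise ValueError("chronic CV case-fatality multiplier must be >= 0")
        if self.post_trial_risk_scale < 0:
            raise ValueError("post-trial risk scale must be >= 0")
        if self.treatment_effect_hr is not None and self.treatment_effect_hr < 0:
            raise ValueError("treatment-effect hazard ratio must be >= 0")

    def trial_attainment(self, arm: str) -> float:
        return (self.trial_attainment_intensive if arm == "intensive"
                else self.trial_attainment_standard)


@dataclass
class ModelInputs:
    """Everything one country/arm-pair analysis needs."""

    rates: EventRateTable
    costs: CostSet
    utilities: UtilitySet
    adherence: AdherenceScenario
    country: CountryProfile
    life_table: LifeTable
    risk_coefficients: RiskCoefficients
    risk_profiles: dict[str, RiskProfile]
    options: ModelOptions = field(default_factory=ModelOptions)

    def validate(self) -> None:
        self.rates.validate()
        self.costs.validate()
        self.utilities.validate()
        self.country.validate()
        self.risk_coefficients.validate()
        self.options.validate()
        for arm in ARMS:
            if arm not in self.risk_profiles:
                raise ValueError(f"risk profile missing for arm {arm!r}")
            self.risk_profiles[arm].validate()
        if self.life_table.ages[0] > self.country.start_age + self.options.trial_years:
            raise ValueError("life table must start by the first post-trial age")

    def copy(self) -> "ModelInputs":
        return copy.deepcopy(self)

    # -- parameter paths ---------------------------------------------------
    # Dot-paths give the tornado and scenario layers a uniform handle on
    # every scalar input.

    def param_paths(self) -> list[str]:
        paths = [f"rates.{arm}.{event}.mean" for arm in ARMS for event in TABLE_EVENTS]
        paths += [f"costs.{name}" for name, _ in self.costs.iter_items()]
        paths += ["utilities.baseline", "utilities.age_decrement"]
        paths += [f"utilities.state.{st}" for st in self.utilities.state_decrement]
        paths += [f"utilities.event.{ev}" for ev in self.utilities.event_decrement]
        paths += ["country.discount_rate"]
        return paths

    def get_param(self, path: str) -> float:
        parts = path.split(".")
        try:
            if parts[0] == "rates":
                return self.rates[(parts[1], parts[2])].mean
            if parts[0] == "costs":
                if parts[1] == "intervention":
                    return self.costs.intervention[parts[2]]
                if parts[1] == "acute":
                    return self.costs.acute[parts[2]]
                if parts[1] == "chronic":
                    return self.costs.chronic[parts[2]]
                if parts[1] == "background":
                    return self.costs.background
            if parts[0] == "utilities":
                if parts[1] == "baseline":
                    return self.utilities.baseline
                if parts[1] == "age_decrement":
                    return self.utilities.age_decrement
                if parts[1] == "state":
                    return self.utilities.state_decrement[parts[2]]
                if parts[1] == "event":
                    return self.utilities.event_decrement[parts[2]][0]
            if parts[0] == "country" and parts[1] == "discount_rate":
                return self.country.discount_rate
            if parts[0] == "adherence":
                return self.adherence.fraction(parts[1])
        except KeyError as exc:
            raise KeyError(f"unknown parameter path {path!r}") from exc
        raise KeyError(f"unknown parameter path {path!r}")

    def set_param(self, path: str, value: float) -> None:
        parts = path.split(".")
        if parts[0] == "rates":
            try:
                self.rates.set_mean(parts[1], parts[2], value)
            except KeyError as exc:
                raise KeyError(f"unknown parameter path {path!r}") from exc
            return
        if parts[0] == "costs":
            if parts[1] == "intervention" and parts[2] in self.costs.intervention:
                self.costs.intervention[parts[2]] = value
            elif parts[1] == "acute" and parts[2] in self.costs.acute:
                self.costs.acute[parts[2]] = value
            elif parts[1] == "chronic" and parts[2] in self.costs.chronic:
                self.costs.chronic[parts[2]] = value
            elif parts[1] == "background":
                self.costs.background = value
            else:
                raise KeyError(f"unknown parameter path {path!r}")
            self.costs.validate()
            return
        if parts[0] == "utilities":
            if parts[1] == "baseline":
                self.utilities.baseline = value
            elif parts[1] == "age_decrement":
                self.utilities.age_decrement = value
            elif parts[1] == "state" and parts[2] in self.utilities.state_decrement:
                self.utilities.state_decrement[parts[2]] = value
            elif parts[1] == "event" and parts[2] in self.utilities.event_decrement:
                _, weeks = self.utilities.event_decrement[parts[2]]
                self.utilities.event_decrement[parts[2]] = (value, weeks)
            else:
                raise KeyError(f"unknown parameter path {path!r}")
            self.utilities.validate()
            return
        if parts[0] == "country" and parts[1] == "discount_rate":
            self.country.discount_rate = value
            self.country.validate()
            return
        if parts[0] == "adherence" and parts[1] in ARMS:
            setattr(self.adherence, parts[1], value)
            return
        raise KeyError(f"unknown parameter path {path!r}")

    # -- serialization -----------------------------------------------------

    def to_config_dict(self) -> dict:
        """Numeric content as a plain dict (used for hashing and YAML)."""
        return {
            "country": {
                "code": self.country.country,
                "currency": self.country.currency,
                "start_age": self.country.start_age,
                "terminal_age": self.country.terminal_age,
                "ppp_to_usd": self.country.ppp_to_usd,
            },
            "discount": {"rate": self.country.discount_rate},
            "wtp": {"lower": self.country.wtp_lower, "upper": self.country.wtp_upper},
            "adherence": {
                "name": self.adherence.name,
                "intensive": self.adherence.intensive,
                "standard": self.adherence.standard,
            },
            "options": {
                "trial_years": self.options.trial_years,
                "trial_attainment": {
                    "intensive": self.options.trial_attainment_intensive,
                    "standard": self.options.trial_attainment_standard,
                },
                "repeated_cvd_multiplier": self.options.repeated_cvd_multiplier,
                "chronic_cv_death_multiplier": self.options.chronic_cv_death_multiplier,
                "treatment_effect_hr": self.options.treatment_effect_hr,
                "post_trial_risk_scale": self.options.post_trial_risk_scale,
                "half_cycle_correction": self.options.half_cycle_correction,
            },
            "costs": {
                "currency": self.costs.currency,
                "intervention": dict(self.costs.intervention),
                "acute": dict(self.costs.acute),
                "chronic": dict(self.costs.chronic),
                "background": self.costs.background,
            },
            "utilities": {
                "baseline": self.utilities.baseline,
                "age_decrement": self.utilities.age_decrement,
                "anchor_age": self.utilities.anchor_age,
                "state_decrement": dict(self.utilities.state_decrement),
                "event_decrement": {k: list(v) for k, v in self.utilities.event_decrement.items()},
            },
            "risk_profiles": {arm: p.to_dict() for arm, p in self.risk_profiles.items()},
        }

    def content_hash(self) -> str:
        """SHA-256 over every numeric field (tables included)."""
        payload = {
            "config": self.to_config_dict(),
            "rates": self.rates.to_dataframe().to_dict("records"),
            "life_table": self.life_table.to_dataframe().to_dict("records"),
            "risk": {
                "name": self.risk_coefficients.name,
                "covariates": list(self.risk_coefficients.covariates),
                "betas": list(self.risk_coefficients.betas),
                "means": list(self.risk_coefficients.means),
                "s0": self.risk_coefficients.s0,
                "scale": self.risk_coefficients.scale,
            },
        }
        blob = json.dumps(payload, sort_keys=True, default=float).encode()
        return hashlib.sha256(blob).hexdigest()

    def save(self, directory: str | Path) -> Path:
        """Write the bundle as config.yaml + three CSV tables; returns the config path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.rates.to_csv(directory / "rates.csv")
        self.life_table.to_csv(directory / "life_table.csv")
        self.risk_coefficients.to_csv(directory / "risk_coefficients.csv")
        config = self.to_config_dict()
        config["files"] = {
            "rates": "rates.csv",
            "life_table": "life_table.csv",
            "risk_coefficients": "risk_coefficients.csv",
        }
        config_path = directory / "config.yaml"
        with open(config_path, "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)
        return config_path


def load_model_inputs(config_path: str | Path) -> ModelInputs:
    """Load and validate a full :class:`ModelInputs` bundle from a YAML config.

    File paths in the ``files`` section are resolved relative to the config.
    Missing optional cost entries default to 0 with a logged warning;
    malformed rows raise :class:`ValueError` naming the offender.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent

    files = cfg.get("files", {})
    for key in ("rates", "life_table", "risk_coefficients"):
        if key not in files:
            raise ValueError(f"config is missing files.{key}")
    rates = EventRateTable.from_csv(base / files["rates"])
    life_table = LifeTable.from_csv(base / files["life_table"])
    risk = RiskCoefficients.from_csv(base / files["risk_coefficients"])

    ccfg = cfg["country"]
    country = CountryProfile(
        country=ccfg["code"],
        currency=ccfg["currency"],
        discount_rate=float(cfg["discount"]["rate"]),
        wtp_lower=float(cfg["wtp"]["lower"]),
        wtp_upper=float(cfg["wtp"]["upper"]),
        ppp_to_usd=float(ccfg.get("ppp_to_usd", 1.0)),
        start_age=int(ccfg.get("start_age", 66)),
        terminal_age=int(ccfg.get("terminal_age", 100)),
    )

    cost_cfg = cfg.get("costs", {})
    for section in ("intervention", "acute", "chronic"):
        if section not in cost_cfg:
            logger.warning("costs.%s missing from config; defaulting to 0", section)
    intervention = {arm: float(cost_cfg.get("intervention", {}).get(arm, 0.0)) for arm in ARMS}
    costs = CostSet(
        currency=cost_cfg.get("currency", country.currency),
        intervention=intervention,
        acute={k: float(v) for k, v in cost_cfg.get("acute", {}).items()},
        chronic={k: float(v) for k, v in cost_cfg.get("chronic", {}).items()},
        background=float(cost_cfg.get("background", 0.0)),
    )

    ucfg = cfg["utilities"]
    utilities = UtilitySet(
        baseline=float(ucfg["baseline"]),
        age_decrement=float(ucfg.get("age_decrement", 0.0)),
        anchor_age=float(ucfg.get("anchor_age", country.start_age)),
        state_decrement={k: float(v) for k, v in ucfg.get("state_decrement", {}).items()},
        event_decrement={k: (float(v[0]), float(v[1]))
                         for k, v in ucfg.get("event_decrement", {}).items()},
    )

    acfg = cfg.get("adherence", {"name": "base"})
    if "intensive" in acfg:
        adherence = AdherenceScenario(acfg.get("name", "custom"),
                                      float(acfg["intensive"]), float(acfg["standard"]))
    else:
        adherence = AdherenceScenario.named(acfg.get("name", "base"))

    ocfg = cfg.get("options", {})
    attain = ocfg.get("trial_attainment", {})
    options = ModelOptions(
        trial_years=int(ocfg.get("trial_years", 4)),
        trial_attainment_intensive=float(attain.get("intensive", 0.70)),
        trial_attainment_standard=float(attain.get("standard", 0.75)),
        repeated_cvd_multiplier=float(ocfg.get("repeated_cvd_multiplier", 1.0)),
        chronic_cv_death_multiplier=float(ocfg.get("chronic_cv_death_multiplier", 4.0)),
        treatment_effect_hr=(None if ocfg.get("treatment_effect_hr") is None
                             else float(ocfg["treatment_effect_hr"])),
        post_trial_risk_scale=float(ocfg.get("post_trial_risk_scale", 1.0)),
        half_cycle_correction=bool(ocfg.get("half_cycle_correction", False)),
    )

    profiles = {arm: RiskProfile.from_dict(p)
                for arm, p in cfg.get("risk_profiles", {}).items()}

    inputs = ModelInputs(
        rates=rates, costs=costs, utilities=utilities, adherence=adherence,
        country=country, life_table=life_table, risk_coefficients=risk,
        risk_profiles=profiles, options=options,
    )
    inputs.validate()
    return inputs
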