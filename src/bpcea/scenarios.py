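"""Declarative scenario and subgroup runners.

A :class:`ScenarioSpec` is a named bundle of overrides (discount rate,
adherence, repeated-CVD multiplier, horizon, trial-period hazard ratio,
post-trial risk scaling, cost multipliers, generic parameter paths) applied
to a deep copy of the base inputs; the full pipeline is then rerun.  A
:class:`SubgroupSpec` swaps in a stratum-specific event-rate table, start
age and risk profile.  Base inputs are never mutated.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .econ import CEResult, compute_ce
from .markov import run_cohort
from .params import ARMS, AdherenceScenario, EventRateTable, ModelInputs
from .synthetic import SUBGROUP_DEFS, SyntheticProfile, generate_inputs, generate_subgroup_rates


@dataclass
class ScenarioSpec:
    """Overrides for one scenario analysis; unset fields inherit the base case."""

    name: str
    discount_rate: float | None = None
    adherence: str | tuple[float, float] | None = None
    repeated_cvd_multiplier: float | None = None
    horizon: int | str | None = None
    treatment_effect_hr: float | None = None
    post_trial_risk_scale: float | None = None
    cost_multipliers: dict[str, float] = field(default_factory=dict)
    overrides: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        adherence = d.get("adherence")
        if isinstance(adherence, (list, tuple)):
            adherence = (float(adherence[0]), float(adherence[1]))
        return cls(
            name=d["name"],
            discount_rate=d.get("discount_rate"),
            adherence=adherence,
            repeated_cvd_multiplier=d.get("repeated_cvd_multiplier"),
            horizon=d.get("horizon"),
            treatment_effect_hr=d.get("treatment_effect_hr"),
            post_trial_risk_scale=d.get("post_trial_risk_scale"),
            cost_multipliers=dict(d.get("cost_multipliers", {})),
            overrides=dict(d.get("overrides", {})),
        )

    def apply(self, base: ModelInputs) -> tuple[ModelInputs, int | str]:
        """Deep-copied inputs with the overrides applied, plus the horizon."""
        inputs = base.copy()
        if self.discount_rate is not None:
            inputs.country.discount_rate = float(self.discount_rate)
        if self.adherence is not None:
            if isinstance(self.adherence, str):
                inputs.adherence = AdherenceScenario.named(self.adherence)
            else:
                i, s = self.adherence
                inputs.adherence = AdherenceScenario("custom", i, s)
        if self.repeated_cvd_multiplier is not None:
            inputs.options.repeated_cvd_multiplier = float(self.repeated_cvd_multiplier)
        if self.treatment_effect_hr is not None:
            inputs.options.treatment_effect_hr = float(self.treatment_effect_hr)
        if self.post_trial_risk_scale is not None:
            inputs.options.post_trial_risk_scale = float(self.post_trial_risk_scale)
        for prefix, factor in self.cost_multipliers.items():
            matched = [p for p in inputs.param_paths()
                       if p.startswith(f"costs.{prefix}")]
            if not matched:
                raise KeyError(f"cost multiplier prefix {prefix!r} matches no parameter")
            for p in matched:
                inputs.set_param(p, inputs.get_param(p) * factor)
        for path, value in self.overrides.items():
            inputs.set_param(path, float(value))  # raises KeyError naming the path
        inputs.validate()
        return inputs, (self.horizon if self.horizon is not None else "lifetime")


def run_scenario(base: ModelInputs, spec: ScenarioSpec) -> CEResult:
    """Rerun the full pipeline under one scenario; ``base`` is untouched."""
    inputs, horizon = spec.apply(base)
    return compute_ce(run_cohort(inputs, "intensive", horizon),
                      run_cohort(inputs, "standard", horizon),
                      inputs.country)


@dataclass
class SubgroupSpec:
    """One stratum: its rate table, start age and risk-profile tweaks."""

    name: str
    rates: EventRateTable
    start_age: int = 66
    sbp_shift: float = 0.0
    diabetes: float | None = None
    sex: float | None = None

    @classmethod
    def synthetic(cls, name: str) -> "SubgroupSpec":
        if name not in SUBGROUP_DEFS:
            raise KeyError(f"unknown subgroup {name!r}; choose from {sorted(SUBGROUP_DEFS)}")
        d = SUBGROUP_DEFS[name]
        return cls(name=name,
                   rates=generate_subgroup_rates(d["rate_scale"]),
                   start_age=d["start_age"],
                   sbp_shift=d["sbp_shift"],
                   diabetes=d["diabetes"],
                   sex=d.get("sex"))

    def apply(self, base: ModelInputs) -> ModelInputs:
        inputs = base.copy()
        inputs.rates = self.rates.copy()
        inputs.country.start_age = self.start_age
        for arm in ARMS:
            p = inputs.risk_profiles[arm]
            p = replace(p, age=float(self.start_age), sbp=p.sbp + self.sbp_shift)
            if self.diabetes is not None:
                p = replace(p, diabetes=self.diabetes)
            if self.sex is not None:
                p = replace(p, sex=self.sex)
            inputs.risk_profiles[arm] = p
        inputs.utilities.anchor_age = float(self.start_age)
        inputs.validate()
        return inputs


def run_subgroup(base: ModelInputs, spec: SubgroupSpec,
                 horizon: int | str = "lifetime") -> CEResult:
    """Rerun the full pipeline for one subgroup; ``base`` is untouched."""
    inputs = spec.apply(base)
    return compute_ce(run_cohort(inputs, "intensive", horizon),
                      run_cohort(inputs, "standard", horizon),
                      inputs.country)


# --------------------------------------------------------------------------
# Batteries
# --------------------------------------------------------------------------

def load_scenario_battery(path: str | Path | None = None) -> list[ScenarioSpec]:
    """The packaged (or a user-supplied) scenario battery YAML."""
    if path is None:
        ref = importlib.resources.files("bpcea").joinpath("data/scenarios.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return [ScenarioSpec.from_dict(d) for d in raw["scenarios"]]


def _result_row(name: str, country: str, result: CEResult) -> dict:
    return {"scenario": name, "country": country,
            "delta_cost": result.delta_cost, "delta_qaly": result.delta_qaly,
            "icer": result.icer, "dominance": result.dominance,
            "events_averted_per_1000": result.events_averted_per_1000}


def run_scenario_battery(countries: tuple[str, ...] = ("CN", "US", "UK"),
                         seed: int = 0,
                         battery_path: str | Path | None = None,
                         base_inputs: dict[str, ModelInputs] | None = None
                         ) -> pd.DataFrame:
    """Run every battery scenario for every country (36 rows by default)."""
    specs = load_scenario_battery(battery_path)
    rows = []
    for country in countries:
        base = (base_inputs[country] if base_inputs is not None
                else generate_inputs(SyntheticProfile(country=country, seed=seed)))
        for spec in specs:
            rows.append(_result_row(spec.name, country, run_scenario(base, spec)))
    return pd.DataFrame(rows)


def run_subgroup_battery(base: ModelInputs,
                         names: tuple[str, ...] | None = None,
                         horizon: int | str = "lifetime") -> pd.DataFrame:
    """Run the synthetic subgroup strata against one base input bundle."""
    names = names if names is not None else tuple(SUBGROUP_DEFS)
    rows = []
    for name in names:
        result = run_subgroup(base, SubgroupSpec.synthetic(name), horizon)
        rows.append(_result_row(name, base.country.country, result))
    return pd.DataFrame(rows)
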