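"""One-way (tornado) and probabilistic sensitivity analysis.

The tornado reruns the full pipeline with every scalar input perturbed by
±10% and ranks parameters by the width of the resulting ICER interval.
The PSA draws all inputs from moment-matched uncertainty distributions —
Beta for probabilities and utilities, Gamma for costs — reruns the model
per draw, and summarizes the joint uncertainty as a cost-effectiveness
acceptability curve (CEAC) and cost-effectiveness-plane quadrant tallies.
Draws are reproducible from the seed; parameters are sampled independently
(no correlation structure is imposed).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .econ import CEResult, compute_ce
from .markov import run_cohort
from .params import ARMS, TABLE_EVENTS, ModelInputs

logger = logging.getLogger("bpcea")


# --------------------------------------------------------------------------
# Moment-matched samplers
# --------------------------------------------------------------------------

def _beta_moment_params(mean: float, sd: float) -> tuple[float, float] | None:
    """Beta(alpha, beta) with the given moments; ``None`` if unsupportable."""
    if mean <= 0.0 or mean >= 1.0:
        return None
    var = sd * sd
    if var >= mean * (1.0 - mean):
        return None
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def sample_beta(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Moment-matched Beta draw; degenerate at the mean when ``sd == 0``;
    clipped-normal fallback (with a warning) when the SD is incompatible
    with the Beta support."""
    if sd == 0.0:
        return mean
    params = _beta_moment_params(mean, sd)
    if params is None:
        logger.warning("Beta moment match impossible for mean=%g sd=%g; "
                       "falling back to a clipped normal", mean, sd)
        return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))
    return float(rng.beta(*params))


def sample_gamma(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Moment-matched Gamma draw with coefficient of variation ``cv``."""
    if mean == 0.0 or cv == 0.0:
        return mean
    shape = 1.0 / (cv * cv)
    return float(rng.gamma(shape, mean / shape))


def sample_lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Moment-matched log-normal draw."""
    if sd == 0.0 or mean <= 0.0:
        return mean
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


# --------------------------------------------------------------------------
# Parameter drawing
# --------------------------------------------------------------------------

def draw_parameters(inputs: ModelInputs, seed: int, n: int,
                    cost_cv: float = 0.20,
                    utility_sd: float = 0.03) -> list[ModelInputs]:
    """``n`` sampled copies of ``inputs``, reproducible from ``seed``.

    Event probabilities use their tabulated (mean, SD) pairs — Beta rows as
    Beta, log-normal rows moment-matched log-normal clipped to [0, 1).
    Costs are Gamma with coefficient of variation ``cost_cv``; the baseline
    utility and every decrement are Beta with SD ``utility_sd`` (for the
    baseline) or 20% relative (for decrements).
    """
    if n < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n):
        s = inputs.copy()
        for arm in ARMS:
            for event in TABLE_EVENTS:
                er = s.rates[(arm, event)]
                if er.distribution == "log_normal":
                    value = min(sample_lognormal(rng, er.mean, er.sd), 1.0 - 1e-12)
                else:
                    value = sample_beta(rng, er.mean, er.sd)
                s.rates.set_mean(arm, event, value)
        for name, value in list(s.costs.iter_items()):
            s.set_param(f"costs.{name}", sample_gamma(rng, value, cost_cv))
        u = s.utilities
        u.baseline = sample_beta(rng, u.baseline, utility_sd)
        dec_rel_sd = 0.2 if utility_sd > 0 else 0.0  # decrements: 20% relative
        for st, d in list(u.state_decrement.items()):
            u.state_decrement[st] = sample_beta(rng, d, dec_rel_sd * d)
        for ev, (d, weeks) in list(u.event_decrement.items()):
            u.event_decrement[ev] = (sample_beta(rng, d, dec_rel_sd * d), weeks)
        draws.append(s)
    return draws


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# --------------------------------------------------------------------------

@dataclass
class PSASample:
    """One Monte Carlo draw's incremental outcomes."""

    index: int
    seed: int
    delta_cost: float
    delta_qaly: float
    nmb: dict[float, float]


@dataclass
class PSAResult:
    """Samples, acceptability curve and plane summary of one PSA run."""

    samples: list[PSASample]
    ceac: pd.DataFrame            # columns: wtp, probability
    quadrants: dict[str, int]     # NE / SE / NW / SW tallies
    n_requested: int
    n_failed: int
    seed: int

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"draw": s.index, "delta_cost": s.delta_cost,
             "delta_qaly": s.delta_qaly,
             **{f"nmb_{w:g}": v for w, v in s.nmb.items()}}
            for s in self.samples
        ])

    def probability_cost_effective(self, wtp: float) -> float:
        """Fraction of retained draws with positive net monetary benefit
        (ties count as not cost-effective)."""
        dc = np.array([s.delta_cost for s in self.samples])
        de = np.array([s.delta_qaly for s in self.samples])
        return float(np.mean(wtp * de - dc > 0.0)) if len(dc) else float("nan")


def run_psa(inputs: ModelInputs, n: int = 1000, seed: int = 0,
            horizon: int | str = "lifetime",
            cost_cv: float = 0.20, utility_sd: float = 0.03) -> PSAResult:
    """Monte Carlo PSA: ``n`` full model reruns under sampled inputs.

    The CEAC is evaluated on 101 evenly spaced WTP points from 0 to 1.5x
    the country's upper threshold plus the two exact thresholds.  Draws
    whose sampled inputs fail validation are excluded (not resampled) and
    counted.
    """
    if n < 2:
        raise ValueError("PSA needs at least 2 draws")
    country = inputs.country
    draws = draw_parameters(inputs, seed, n, cost_cv, utility_sd)
    samples: list[PSASample] = []
    failed = 0
    for i, sampled in enumerate(draws):
        try:
            sampled.validate()
            t_int = run_cohort(sampled, "intensive", horizon)
            t_std = run_cohort(sampled, "standard", horizon)
        except (ValueError, RuntimeError) as exc:
            logger.warning("PSA draw %d failed validation: %s", i, exc)
            failed += 1
            continue
        dc = t_int.total_cost - t_std.total_cost
        de = t_int.total_qaly - t_std.total_qaly
        nmb = {w: w * de - dc for w in (country.wtp_lower, country.wtp_upper)}
        samples.append(PSASample(i, seed, dc, de, nmb))

    dc = np.array([s.delta_cost for s in samples])
    de = np.array([s.delta_qaly for s in samples])
    grid = np.union1d(np.linspace(0.0, 1.5 * country.wtp_upper, 101),
                      [country.wtp_lower, country.wtp_upper])
    ceac = pd.DataFrame({
        "wtp": grid,
        "probability": [float(np.mean(w * de - dc > 0.0)) for w in grid],
    })
    quadrants = {
        "NE": int(np.sum((de > 0) & (dc >= 0))),
        "SE": int(np.sum((de > 0) & (dc < 0))),
        "NW": int(np.sum((de <= 0) & (dc >= 0))),
        "SW": int(np.sum((de <= 0) & (dc < 0))),
    }
    return PSAResult(samples, ceac, quadrants, n, failed, seed)


# --------------------------------------------------------------------------
# One-way (tornado) analysis
# --------------------------------------------------------------------------

@dataclass
class TornadoBar:
    parameter: str
    value_low: float
    value_high: float
    icer_low: float
    icer_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _icer_for(inputs: ModelInputs, horizon: int | str) -> float | None:
    result = compute_ce(run_cohort(inputs, "intensive", horizon),
                        run_cohort(inputs, "standard", horizon),
                        inputs.country)
    return result.icer


def one_way_tornado(inputs: ModelInputs, fraction: float = 0.10,
                    horizon: int | str = "lifetime",
                    parameters: list[str] | None = None) -> pd.DataFrame:
    """Rerun the pipeline with each scalar input at (1 ± fraction) x base.

    Probabilities and utilities are capped at their natural bounds;
    perturbations that still produce invalid inputs are skipped with a
    warning.  Returns a DataFrame sorted by descending ICER interval width
    (columns: parameter, value_low, value_high, icer_low, icer_high, width).
    """
    paths = parameters if parameters is not None else inputs.param_paths()
    bars: list[TornadoBar] = []
    for path in paths:
        base_value = inputs.get_param(path)
        icers = []
        values = []
        ok = True
        for factor in (1.0 - fraction, 1.0 + fraction):
            value = base_value * factor
            if path.startswith(("rates.", "utilities.")):
                value = min(value, 1.0)
            perturbed = inputs.copy()
            try:
                perturbed.set_param(path, value)
                perturbed.validate()
                icers.append(_icer_for(perturbed, horizon))
            except (ValueError, KeyError, RuntimeError) as exc:
                logger.warning("tornado: skipping %s (%s)", path, exc)
                ok = False
                break
            values.append(value)
        if not ok or None in icers:
            continue
        bars.append(TornadoBar(path, values[0], values[1], icers[0], icers[1]))
    bars.sort(key=lambda b: b.width, reverse=True)
    return pd.DataFrame([
        {"parameter": b.parameter, "value_low": b.value_low,
         "value_high": b.value_high, "icer_low": b.icer_low,
         "icer_high": b.icer_high, "width": b.width}
        for b in bars
    ])
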