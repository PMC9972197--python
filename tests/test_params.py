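"""Probability/rate calculus, table ingestion and input-bundle round trips."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import bpcea
from bpcea import (
    EventRateTable,
    LifeTable,
    AdherenceScenario,
    load_model_inputs,
    prob_to_rate,
    rate_to_prob,
    rescale_probability,
)

PROBS = st.floats(min_value=0.0, max_value=1.0 - 1e-9, allow_nan=False)


class TestRateCalculus:
    @pytest.mark.parametrize("p, t, expected", [
        (0.0, 1.0, 0.0),
        (0.5, 1.0, math.log(2)),
        # high-precision evaluation of -ln(1-p) on the standard-arm
        # primary-composite yearly probability
        (0.011683970, 1.0, 0.0117527),
    ])
    def test_prob_to_rate_values(self, p, t, expected):
        assert prob_to_rate(p, t) == pytest.approx(expected, abs=1e-7)

    @pytest.mark.parametrize("r, t, expected", [
        (0.0, 5.0, 0.0),
        (math.log(2), 1.0, 0.5),
    ])
    def test_rate_to_prob_values(self, r, t, expected):
        assert rate_to_prob(r, t) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad_call", [
        lambda: prob_to_rate(1.0),
        lambda: prob_to_rate(-0.1),
        lambda: prob_to_rate(0.5, 0.0),
        lambda: rate_to_prob(-0.01),
        lambda: rate_to_prob(0.1, -1.0),
    ])
    def test_domain_errors(self, bad_call):
        with pytest.raises(ValueError):
            bad_call()

    @given(PROBS)
    def test_round_trip_identity(self, p):
        assert rate_to_prob(prob_to_rate(p, 1.0), 1.0) == pytest.approx(p, abs=1e-12)

    def test_rescale_identity_and_closed_form(self):
        assert rescale_probability(0.3, 10.0, 10.0) == pytest.approx(0.3, abs=1e-12)
        assert rescale_probability(0.0, 3.0, 7.0) == 0.0
        # 1 - exp(ln(0.9)/10)
        assert rescale_probability(0.10, 10.0, 1.0) == pytest.approx(0.0104808, abs=1e-7)

    @given(st.tuples(PROBS, PROBS), st.floats(0.1, 50), st.floats(0.1, 50))
    def test_rescale_monotone_in_p(self, ps, ft, tt):
        lo, hi = sorted(ps)
        assert rescale_probability(lo, ft, tt) <= rescale_probability(hi, ft, tt) + 1e-15

    @given(PROBS, st.tuples(st.floats(0.1, 50), st.floats(0.1, 50)))
    def test_rescale_monotone_in_duration(self, p, ts):
        lo, hi = sorted(ts)
        assert (rescale_probability(p, 10.0, lo)
                <= rescale_probability(p, 10.0, hi) + 1e-15)


class TestEventRateTable:
    def test_out_of_range_probability_names_the_row(self, cn_inputs):
        df = cn_inputs.rates.to_dataframe()
        df.loc[df.index[3], "mean"] = 1.2
        offender = f"({df.loc[df.index[3], 'arm']}, {df.loc[df.index[3], 'event']})"
        with pytest.raises(ValueError, match="1.2"):
            try:
                EventRateTable.from_dataframe(df)
            except ValueError as exc:
                assert df.loc[df.index[3], "event"] in str(exc)
                raise

    def test_unknown_distribution_rejected(self, cn_inputs):
        df = cn_inputs.rates.to_dataframe()
        df.loc[0, "distribution"] = "weibull"
        with pytest.raises(ValueError, match="weibull"):
            EventRateTable.from_dataframe(df)

    def test_missing_row_rejected(self, cn_inputs):
        df = cn_inputs.rates.to_dataframe().iloc[1:]
        with pytest.raises(ValueError, match="missing"):
            EventRateTable.from_dataframe(df)


class TestLifeTable:
    def test_terminal_rule_beyond_range(self):
        lt = LifeTable(range(60, 101), np.linspace(0.01, 1.0, 41))
        assert lt.qx_at(100) == 1.0
        assert lt.qx_at(150) == 1.0
        with pytest.raises(ValueError):
            lt.qx_at(40)

    def test_rejects_invalid_probabilities(self):
        with pytest.raises(ValueError):
            LifeTable(range(60, 63), [0.1, 1.5, 0.2])


class TestAdherence:
    @pytest.mark.parametrize("name, expected", [
        ("base", (0.70, 0.75)), ("worst", (0.0, 1.0)), ("best", (1.00, 0.75)),
    ])
    def test_named_scenarios(self, name, expected):
        s = AdherenceScenario.named(name)
        assert (s.intensive, s.standard) == expected

    def test_unknown_name_and_bad_fraction(self):
        with pytest.raises(ValueError):
            AdherenceScenario.named("middling")
        with pytest.raises(ValueError):
            AdherenceScenario("custom", 1.2, 0.5)


class TestModelInputsIO:
    def test_round_trip_is_lossless(self, cn_inputs, tmp_path):
        config = cn_inputs.save(tmp_path / "a")
        reloaded = load_model_inputs(config)
        assert reloaded.content_hash() == cn_inputs.content_hash()
        # and a second generation pass is byte-identical on disk
        reloaded.save(tmp_path / "b")
        for name in ("config.yaml", "rates.csv", "life_table.csv",
                     "risk_coefficients.csv"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())

    def test_loaded_rates_match_trial_table(self, cn_inputs, tmp_path):
        config = cn_inputs.save(tmp_path / "fix")
        inputs = load_model_inputs(config)
        assert inputs.rates.prob("intensive", "primary_composite") == 0.008776182

    def test_missing_costs_default_to_zero_with_warning(self, cn_inputs, tmp_path, caplog):
        import yaml
        config = cn_inputs.save(tmp_path / "fix")
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
        del cfg["costs"]["acute"]
        with open(config, "w") as fh:
            yaml.safe_dump(cfg, fh)
        with caplog.at_level("WARNING", logger="bpcea"):
            inputs = load_model_inputs(config)
        assert inputs.costs.acute_cost("stroke") == 0.0
        assert any("acute" in rec.message for rec in caplog.records)

    def test_param_paths_get_set(self, cn_inputs):
        inputs = cn_inputs.copy()
        for path in inputs.param_paths():
            value = inputs.get_param(path)
            inputs.set_param(path, value)
            assert inputs.get_param(path) == value
        with pytest.raises(KeyError, match="no.such.path"):
            inputs.get_param("no.such.path")
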