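"""Risk-equation evaluation, composite splitting, adherence blending and
competing non-CVD mortality."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bpcea import (
    LifeTable,
    RiskCoefficients,
    RiskProfile,
    annualize_composite_risk,
    blend_adherence,
    noncvd_death_prob,
    prob_to_rate,
    ten_year_cvd_risk,
)
from bpcea.params import CV_EVENTS
from bpcea.synthetic import TRIAL_EVENT_RATES


def make_coefficients(betas=(0.02,), covariates=("sbp",), means=(140.0,),
                      s0=0.9, scale=1.0):
    return RiskCoefficients("toy", covariates, betas, means, s0, scale)


class TestTenYearRisk:
    def test_risk_at_means_is_one_minus_s0(self):
        coef = make_coefficients()
        profile = RiskProfile(age=70, sbp=140.0)
        assert ten_year_cvd_risk(profile, coef) == pytest.approx(1 - 0.9, abs=1e-12)

    def test_s0_one_means_no_risk(self):
        coef = make_coefficients(s0=1.0)
        assert ten_year_cvd_risk(RiskProfile(age=70, sbp=180.0), coef) == 0.0

    def test_sbp_ten_above_mean_closed_form(self):
        # 1 - 0.9 ** exp(0.02 * 10)
        coef = make_coefficients()
        risk = ten_year_cvd_risk(RiskProfile(age=70, sbp=150.0), coef)
        assert risk == pytest.approx(1.0 - 0.9 ** math.exp(0.2), abs=1e-12)
        assert risk == pytest.approx(0.1207, abs=1e-3)

    def test_missing_covariate_named_in_error(self):
        coef = make_coefficients(covariates=("sbp", "egfr"), betas=(0.02, -0.01),
                                 means=(140.0, 70.0))
        with pytest.raises(ValueError, match="egfr"):
            ten_year_cvd_risk(RiskProfile(age=70, sbp=150.0), coef)

    def test_doubled_scale_never_reduces_risk(self):
        for sbp in (110, 130, 150, 180):
            lo = ten_year_cvd_risk(RiskProfile(age=70, sbp=sbp), make_coefficients())
            hi = ten_year_cvd_risk(RiskProfile(age=70, sbp=sbp),
                                   make_coefficients(scale=2.0))
            assert hi >= lo


class TestAnnualizeComposite:
    def test_zero_risk_gives_zero_everywhere(self):
        probs = annualize_composite_risk(0.0, {"stroke": 0.4, "acs": 0.6})
        assert all(v == 0.0 for v in probs.values())

    def test_single_event_equals_rescaled_probability(self):
        probs = annualize_composite_risk(0.10, {"stroke": 1.0})
        assert probs["stroke"] == pytest.approx(0.0104808, abs=1e-7)

    def test_trial_mix_shares_preserved_in_rate_space(self):
        rates = {e: prob_to_rate(TRIAL_EVENT_RATES[("standard", e)][0])
                 for e in CV_EVENTS}
        total = sum(rates.values())
        mix = {e: r / total for e, r in rates.items()}
        for risk in (0.05, 0.20, 0.50):
            probs = annualize_composite_risk(risk, mix)
            out_rates = {e: prob_to_rate(p) for e, p in probs.items()}
            composite = prob_to_rate(risk, 10.0)
            assert sum(out_rates.values()) == pytest.approx(composite, abs=1e-12)
            for e in CV_EVENTS:
                assert out_rates[e] / composite == pytest.approx(mix[e], abs=1e-12)

    def test_bad_shares_rejected(self):
        with pytest.raises(ValueError):
            annualize_composite_risk(0.1, {"stroke": 0.5, "acs": 0.4})
        with pytest.raises(ValueError):
            annualize_composite_risk(0.1, {"stroke": 1.5, "acs": -0.5})


class TestAdherenceBlending:
    def test_endpoints(self):
        assert blend_adherence(0.02, 0.05, 1.0) == pytest.approx(0.02, abs=1e-15)
        assert blend_adherence(0.02, 0.05, 0.0) == pytest.approx(0.05, abs=1e-15)

    def test_rate_space_blend_value(self):
        # 1 - exp(-(0.7 r_on + 0.3 r_off))
        got = blend_adherence(0.0088, 0.0117, 0.70)
        r = 0.7 * -math.log(1 - 0.0088) + 0.3 * -math.log(1 - 0.0117)
        assert got == pytest.approx(1 - math.exp(-r), abs=1e-15)
        assert got == pytest.approx(0.00967, abs=1e-5)

    @given(st.floats(0, 0.99), st.floats(0, 0.99), st.floats(0, 1))
    def test_blend_bounded_by_anchors(self, p_on, p_off, a):
        blended = blend_adherence(p_on, p_off, a)
        lo, hi = sorted((p_on, p_off))
        assert lo - 1e-12 <= blended <= hi + 1e-12

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_blend_monotone_in_adherence(self, a1, a2):
        lo, hi = sorted((a1, a2))
        assert (blend_adherence(0.01, 0.03, lo)
                >= blend_adherence(0.01, 0.03, hi) - 1e-15)


class TestCompetingMortality:
    @pytest.fixture
    def table(self):
        return LifeTable(range(60, 101), [0.02] * 41)

    def test_no_cv_death_returns_life_table_exactly(self, table):
        assert noncvd_death_prob(66, table, 0.0) == pytest.approx(0.02, abs=1e-15)

    def test_rate_space_subtraction(self, table):
        # 1 - exp(-(r(0.02) - r(0.0015)))
        expected = 1 - math.exp(-(-math.log(0.98) + math.log(1 - 0.0015)))
        got = noncvd_death_prob(66, table, 0.0015)
        assert got == pytest.approx(expected, abs=1e-15)
        assert got == pytest.approx(0.018531, abs=1e-5)

    def test_floor_at_zero_with_warning(self, table, caplog):
        with caplog.at_level("WARNING", logger="bpcea"):
            assert noncvd_death_prob(66, table, 0.05) == 0.0
        assert any("floor" in rec.message for rec in caplog.records)
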