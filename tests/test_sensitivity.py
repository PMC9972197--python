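"""Parameter sampling, PSA mechanics and the one-way tornado."""
import numpy as np
import pytest

import bpcea
from bpcea import draw_parameters, one_way_tornado, run_psa
from bpcea.sensitivity import sample_beta, sample_gamma
from bpcea.params import ARMS, TABLE_EVENTS


def freeze_all_sds(inputs):
    frozen = inputs.copy()
    for arm in ARMS:
        for event in TABLE_EVENTS:
            er = frozen.rates[(arm, event)]
            frozen.rates._rates[(arm, event)] = type(er)(er.mean, 0.0, er.distribution)
    return frozen


class TestSamplers:
    def test_beta_moment_match_recovers_mean(self):
        rng = np.random.default_rng(7)
        mean, sd = 0.0117, 0.00164
        draws = np.array([sample_beta(rng, mean, sd) for _ in range(10_000)])
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - mean) <= 3 * se
        assert draws.std() == pytest.approx(sd, rel=0.1)

    def test_zero_sd_is_degenerate(self):
        rng = np.random.default_rng(0)
        assert sample_beta(rng, 0.3, 0.0) == 0.3
        assert sample_gamma(rng, 100.0, 0.0) == 100.0

    def test_incompatible_sd_falls_back_to_clipped_normal(self, caplog):
        rng = np.random.default_rng(0)
        with caplog.at_level("WARNING", logger="bpcea"):
            draws = [sample_beta(rng, 0.5, 0.6) for _ in range(50)]
        assert all(0.0 <= d <= 1.0 for d in draws)
        assert any("clipped normal" in rec.message for rec in caplog.records)


class TestDrawParameters:
    def test_same_seed_gives_identical_draws(self, cn_inputs):
        a = draw_parameters(cn_inputs, seed=5, n=3)
        b = draw_parameters(cn_inputs, seed=5, n=3)
        for x, y in zip(a, b):
            assert x.content_hash() == y.content_hash()

    def test_single_free_parameter_mean_recovery(self, cn_inputs):
        # every SD frozen to zero except the standard-arm primary composite
        frozen = freeze_all_sds(cn_inputs)
        er = frozen.rates[("standard", "primary_composite")]
        frozen.rates._rates[("standard", "primary_composite")] = type(er)(
            er.mean, 0.001644868, "beta")
        draws = draw_parameters(frozen, seed=11, n=500, cost_cv=0.0, utility_sd=0.0)
        values = np.array([d.rates.prob("standard", "primary_composite")
                           for d in draws])
        se = values.std() / np.sqrt(values.size)
        assert abs(values.mean() - er.mean) <= 3 * se
        # everything else identical to the base inputs
        assert draws[0].rates.prob("intensive", "stroke") == cn_inputs.rates.prob(
            "intensive", "stroke")
        assert draws[0].costs.background == cn_inputs.costs.background


class TestRunPSA:
    def test_degenerate_inputs_make_a_step_ceac(self, cn_inputs, cn_ce):
        frozen = freeze_all_sds(cn_inputs)
        psa = run_psa(frozen, n=3, seed=0, cost_cv=0.0, utility_sd=0.0)
        dcs = {round(s.delta_cost, 6) for s in psa.samples}
        assert len(dcs) == 1  # all samples identical
        below = psa.ceac[psa.ceac.wtp < cn_ce.icer]["probability"]
        above = psa.ceac[psa.ceac.wtp > cn_ce.icer]["probability"]
        assert (below == 0.0).all() and (above == 1.0).all()

    def test_ceac_is_fraction_of_positive_nmb(self, cn_inputs):
        psa = run_psa(cn_inputs, n=40, seed=3)
        dc = np.array([s.delta_cost for s in psa.samples])
        de = np.array([s.delta_qaly for s in psa.samples])
        for _, row in psa.ceac.iloc[::25].iterrows():
            frac = np.mean(row.wtp * de - dc > 0.0)
            assert row.probability == frac
        assert sum(psa.quadrants.values()) == psa.n_requested - psa.n_failed

    def test_needs_two_draws(self, cn_inputs):
        with pytest.raises(ValueError):
            run_psa(cn_inputs, n=1, seed=0)


@pytest.fixture(scope="module")
def tornado(cn_inputs):
    return one_way_tornado(cn_inputs)


class TestTornado:
    def test_inert_parameter_has_zero_width(self, tornado):
        # the composite row feeds no transition (components do), so +-10%
        # moves nothing
        row = tornado[tornado.parameter == "rates.standard.primary_composite.mean"]
        assert float(row.width.iloc[0]) == pytest.approx(0.0, abs=1e-9)

    def test_intervention_cost_moves_icer_up(self, tornado, cn_ce):
        row = tornado[tornado.parameter == "costs.intervention.intensive"].iloc[0]
        assert row.icer_high > cn_ce.icer > row.icer_low

    def test_treatment_cost_among_top_drivers(self, tornado):
        top3 = list(tornado.parameter.iloc[:3])
        assert "costs.intervention.intensive" in top3

    def test_intervals_ordered_by_width(self, tornado):
        widths = tornado.width.to_numpy()
        assert np.all(np.diff(widths) <= 1e-12)
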