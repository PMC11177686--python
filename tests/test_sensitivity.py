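"""One-way DSA, Monte-Carlo PSA and acceptability curves."""

import numpy as np
import pytest

import markovcea as m
from markovcea.params import InvalidInputError
from markovcea.sensitivity import (
    PSADraw,
    ceac,
    default_ranges,
    not_cost_effective_fraction,
    one_way_dsa,
    run_psa,
    sample_params,
)


class TestDefaultRanges:
    def test_probability_ranges_come_from_published_limits(self, fixture_config):
        ranges = {r.name: r for r in default_ranges(fixture_config)}
        r = ranges["comparator.p_pfs_pd"]
        assert (r.low, r.high) == (0.30, 0.44)
        assert 0.30 <= r.base <= 0.44
        # costs/utilities lacking published limits get +/-20%
        c = ranges["intervention.cost_pfs_per_cycle"]
        assert c.low == pytest.approx(0.8 * c.base)
        assert c.high == pytest.approx(1.2 * c.base)
        u = ranges["utility_pfs"]
        assert u.high <= 1.0

    def test_every_parameter_has_a_range(self, fixture_config):
        from markovcea.pipeline import parameter_names

        names = {r.name for r in default_ranges(fixture_config)}
        assert names == set(parameter_names(fixture_config))
        assert len(names) == 12  # 6 probabilities + 4 costs + 2 utilities


class TestOneWayDSA:
    def test_base_case_unchanged_after_dsa(self, fixture_config):
        """Re-running the base case after a full DSA reproduces it exactly."""
        before = m.evaluate(fixture_config).comparison
        one_way_dsa(fixture_config)
        after = m.evaluate(fixture_config).comparison
        assert before == after

    def test_degenerate_ranges_have_zero_span(self, fixture_config):
        base = m.evaluate(fixture_config).comparison
        ranges = [
            m.ParamRange(name="utility_pd", base=0.74, low=0.74, high=0.74),
            m.ParamRange(name="comparator.p_pfs_pd", base=0.3700394750525634,
                         low=0.3700394750525634, high=0.3700394750525634),
        ]
        rows = one_way_dsa(fixture_config, ranges=ranges)
        for row in rows:
            assert row.nmb_span == pytest.approx(0.0, abs=1e-9)
            assert row.icer_at_low == pytest.approx(base.icer, rel=1e-12)

    def test_shared_parameter_with_identical_arms_has_zero_span(self, identical_arms_config):
        rows = one_way_dsa(
            identical_arms_config,
            ranges=[m.ParamRange(name="utility_pd", base=0.74, low=0.6, high=0.88)],
        )
        assert rows[0].nmb_span == pytest.approx(0.0, abs=1e-9)

    def test_perturbing_a_probability_moves_the_result(self, fixture_config):
        rows = one_way_dsa(
            fixture_config,
            ranges=[m.ParamRange(name="comparator.p_pfs_pd",
                                 base=0.3700394750525634, low=0.30, high=0.44)],
        )
        assert rows[0].nmb_span > 0
        # oracle re-run equality: evaluating at the bound reproduces the row
        low_run = m.evaluate(fixture_config, overrides={"comparator.p_pfs_pd": 0.30})
        assert rows[0].nmb_at_low == pytest.approx(low_run.comparison.incremental_nmb)
        assert rows[0].icer_at_low == pytest.approx(low_run.comparison.icer)

    def test_rows_sorted_by_nmb_span(self, fixture_config):
        rows = one_way_dsa(fixture_config)
        spans = [r.nmb_span for r in rows]
        assert spans == sorted(spans, reverse=True)

    def test_exit_mass_overflow_is_clamped_and_flagged(self, fixture_config):
        rows = one_way_dsa(
            fixture_config,
            ranges=[m.ParamRange(name="comparator.p_pfs_pd",
                                 base=0.3700394750525634, low=0.30, high=0.99)],
        )
        assert any("rescaled" in note for note in rows[0].notes)
        assert np.isfinite(rows[0].nmb_at_high)


class TestSampleParams:
    def test_degenerate_policy_returns_base(self, fixture_config):
        from markovcea.pipeline import base_parameter_values

        rng = np.random.default_rng(0)
        draw = sample_params(fixture_config, rng, dist_policy="degenerate")
        assert draw == base_parameter_values(fixture_config)

    def test_probabilities_and_utilities_stay_in_unit_interval(self, fixture_config):
        rng = np.random.default_rng(3)
        for _ in range(200):
            draw = sample_params(fixture_config, rng)
            for name, value in draw.items():
                leaf = name.rsplit(".", 1)[-1]
                if leaf.startswith("p_") or leaf.startswith("utility_"):
                    assert 0.0 <= value <= 1.0, name
                else:
                    assert value >= 0.0, name

    def test_same_seed_same_sequence(self, fixture_config):
        a = [sample_params(fixture_config, np.random.default_rng(9)) for _ in range(1)][0]
        b = [sample_params(fixture_config, np.random.default_rng(9)) for _ in range(1)][0]
        assert a == b

    def test_unknown_policy_rejected(self, fixture_config):
        with pytest.raises(InvalidInputError, match="dist_policy"):
            sample_params(fixture_config, np.random.default_rng(0), dist_policy="cauchy")


class TestRunPSA:
    def test_degenerate_distributions_reproduce_base_bit_identically(self, fixture_config):
        base = m.evaluate(fixture_config).comparison
        result = run_psa(fixture_config, n_iter=3, rng_seed=5, dist_policy="degenerate")
        for draw in result.draws:
            assert draw.delta_cost == base.delta_cost
            assert draw.delta_qalys == base.delta_qalys
            assert draw.icer == base.icer

    def test_seeded_reproducibility(self, fixture_config):
        a = run_psa(fixture_config, n_iter=40, rng_seed=17)
        b = run_psa(fixture_config, n_iter=40, rng_seed=17)
        assert a.draws == b.draws
        c = run_psa(fixture_config, n_iter=40, rng_seed=18)
        assert a.draws != c.draws

    def test_seed_is_mandatory(self, fixture_config):
        with pytest.raises(InvalidInputError, match="seed"):
            run_psa(fixture_config, n_iter=5)

    def test_draws_carry_sampled_parameters_and_increments(self, fixture_config):
        result = run_psa(fixture_config, n_iter=10, rng_seed=2)
        assert len(result.draws) == 10
        for d in result.draws:
            assert set(d.sampled_params) == {r.name for r in default_ranges(fixture_config)}
            assert np.isfinite(d.delta_cost)
            assert np.isfinite(d.delta_qalys)

    def test_two_seeds_agree_within_monte_carlo_error(self, fixture_config):
        """CEAC estimates from independent seeds differ by at most binomial noise."""
        n = 400
        grid = [0.0, 35_906.0, 75_000.0, 150_000.0]
        curves = []
        for seed in (101, 202):
            draws = run_psa(fixture_config, n_iter=n, rng_seed=seed).draws
            curves.append([p.prob_cost_effective for p in ceac(draws, grid)])
        for p1, p2 in zip(*curves):
            p_bar = 0.5 * (p1 + p2)
            se = np.sqrt(max(2 * p_bar * (1 - p_bar) / n, 1e-12))
            assert abs(p1 - p2) <= max(4 * se, 0.02)


class TestCEAC:
    def synthetic_draws(self, de, dc):
        return [
            PSADraw(draw_index=i, sampled_params={}, delta_cost=c, delta_qalys=e,
                    icer=c / e if e else float("inf"), decision="")
            for i, (e, c) in enumerate(zip(de, dc))
        ]

    def test_probabilities_bounded_and_monotone_for_positive_effect(self):
        rng = np.random.default_rng(21)
        draws = self.synthetic_draws(rng.uniform(0.05, 0.5, 200), rng.uniform(0, 2e4, 200))
        points = ceac(draws, list(np.linspace(0, 2e5, 41)))
        probs = [p.prob_cost_effective for p in points]
        assert all(0.0 <= p <= 1.0 for p in probs)
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))

    def test_zero_wtp_counts_cost_saving_draws(self):
        draws = self.synthetic_draws([0.1, 0.2, -0.1, 0.3], [100.0, -50.0, -10.0, 200.0])
        point = ceac(draws, [0.0])[0]
        assert point.prob_cost_effective == pytest.approx(2 / 4)

    def test_large_wtp_limit_is_positive_effect_fraction(self):
        de = [0.1, 0.2, -0.1, 0.3]
        draws = self.synthetic_draws(de, [100.0, -50.0, -10.0, 200.0])
        point = ceac(draws, [1e12])[0]
        assert point.prob_cost_effective == pytest.approx(3 / 4)

    def test_fixture_curve_is_flat_near_zero(self, fixture_config):
        """At the configured threshold the combination is essentially never accepted."""
        draws = run_psa(fixture_config, n_iter=200, rng_seed=33).draws
        point = ceac(draws, [fixture_config.wtp])[0]
        assert point.prob_cost_effective <= 0.05
        assert not_cost_effective_fraction(draws, fixture_config.wtp) >= 0.95

    def test_empty_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            ceac([], [1000.0])
        draws = self.synthetic_draws([0.1], [10.0])
        with pytest.raises(InvalidInputError):
            ceac(draws, [])
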