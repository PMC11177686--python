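"""Cohort propagation and discounted accrual."""

import numpy as np
import pytest

import markovcea as m
from markovcea.engine import discount_factors
from markovcea.params import InvalidInputError

from conftest import random_chain


def identity_matrix() -> m.TransitionMatrix:
    return m.TransitionMatrix(entries=np.eye(3))


class TestRunCohort:
    def test_identity_matrix_constant_trace(self):
        trace = m.run_cohort(identity_matrix(), n_cycles=12)
        assert trace.occupancy.shape == (13, 3)
        np.testing.assert_array_equal(trace.occupancy, np.tile([1.0, 0.0, 0.0], (13, 1)))

    def test_first_cycle_pfs_equals_stay_probability(self, lom_arm):
        tp = m.derive_arm_transitions(lom_arm)
        trace = m.run_cohort(m.build_matrix(tp), n_cycles=120)
        assert trace.pfs[1] == pytest.approx(tp.p_pfs_pfs, abs=1e-15)

    def test_starts_fully_progression_free(self, lom_arm):
        trace = m.run_cohort(m.build_matrix(m.derive_arm_transitions(lom_arm)))
        np.testing.assert_array_equal(trace.occupancy[0], [1.0, 0.0, 0.0])

    def test_occupancy_conservation_and_monotonicity(self):
        """Rows sum to 1; PFS never re-entered; Death never left."""
        rng = np.random.default_rng(20240530)
        for _ in range(200):
            trace = m.run_cohort(random_chain(rng), n_cycles=60)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(np.diff(trace.pfs) <= 1e-15)
            assert np.all(np.diff(trace.death) >= -1e-15)

    def test_invalid_init_rejected(self):
        with pytest.raises(InvalidInputError, match="init"):
            m.run_cohort(identity_matrix(), n_cycles=5, init=[0.5, 0.2, 0.2])

    def test_invalid_n_cycles_rejected(self):
        with pytest.raises(InvalidInputError, match="n_cycles"):
            m.run_cohort(identity_matrix(), n_cycles=0)


class TestAccrue:
    def test_ten_years_alive_at_full_utility(self):
        econ = m.EconomicInputs(cost_pfs_per_cycle=0.0, cost_pd_per_cycle=0.0,
                                utility_pfs=1.0, annual_discount_rate=0.0)
        trace = m.run_cohort(identity_matrix(), n_cycles=120)
        result = m.accrue(trace, econ)
        assert result.total_qalys == pytest.approx(10.0, abs=1e-12)

    def test_pfs_person_months_match_geometric_series(self, lom_arm):
        # undiscounted person-months in PFS over cycles 1..N = sum p^t = p/(1-p)
        tp = m.derive_arm_transitions(lom_arm)
        trace = m.run_cohort(m.build_matrix(tp), n_cycles=120)
        econ = m.EconomicInputs(cost_pfs_per_cycle=1.0, cost_pd_per_cycle=0.0,
                                annual_discount_rate=0.0)
        result = m.accrue(trace, econ)
        p = tp.p_pfs_pfs
        assert result.total_cost == pytest.approx(p / (1 - p), abs=1e-9)
        assert result.total_cost == pytest.approx(1.2347594354883304, abs=1e-9)

    def test_discounting_never_increases_totals(self, fixture_config):
        res = m.evaluate(fixture_config)
        trace = res.comparator.trace
        econ = fixture_config.economic_inputs("comparator")
        undiscounted = m.accrue(
            trace,
            m.EconomicInputs(
                cost_pfs_per_cycle=econ.cost_pfs_per_cycle,
                cost_pd_per_cycle=econ.cost_pd_per_cycle,
                annual_discount_rate=0.0,
            ),
        )
        discounted = m.accrue(trace, econ)
        assert discounted.total_cost <= undiscounted.total_cost
        assert discounted.total_qalys <= undiscounted.total_qalys

    def test_half_cycle_averages_entry_and_exit_occupancy(self, lom_arm):
        tp = m.derive_arm_transitions(lom_arm)
        trace = m.run_cohort(m.build_matrix(tp), n_cycles=3)
        econ = m.EconomicInputs(cost_pfs_per_cycle=1.0, cost_pd_per_cycle=0.0,
                                annual_discount_rate=0.0)
        result = m.accrue(trace, econ, half_cycle=True)
        occ = trace.pfs
        expected = sum(0.5 * (occ[t - 1] + occ[t]) for t in (1, 2, 3))
        assert result.total_cost == pytest.approx(expected, abs=1e-12)

    def test_totals_equal_sum_of_state_components(self, fixture_config):
        res = m.evaluate(fixture_config)
        for arm in (res.intervention.result, res.comparator.result):
            assert arm.total_cost == pytest.approx(sum(arm.cost_by_state.values()), abs=1e-9)
            assert arm.total_qalys == pytest.approx(sum(arm.qalys_by_state.values()), abs=1e-9)

    def test_deterministic_given_identical_inputs(self, fixture_config):
        a = m.evaluate(fixture_config)
        b = m.evaluate(fixture_config)
        assert a.comparison == b.comparison

    def test_horizon_tail_mass_is_small(self, fixture_config):
        """Extending 120 -> 600 cycles changes undiscounted QALYs only in the tail."""
        tp = m.derive_arm_transitions(fixture_config.comparator.clinical_inputs())
        matrix = m.build_matrix(tp)
        econ = m.EconomicInputs(cost_pfs_per_cycle=0.0, cost_pd_per_cycle=0.0,
                                utility_pfs=0.89, utility_pd=0.74,
                                annual_discount_rate=0.0)
        q120 = m.accrue(m.run_cohort(matrix, 120), econ).total_qalys
        q600 = m.accrue(m.run_cohort(matrix, 600), econ).total_qalys
        assert q600 >= q120
        assert q600 - q120 < 0.01  # reportable tail, converged at 10 years


class TestClosedFormOracle:
    def test_pfs_infinite_horizon_geometric(self, lom_arm):
        tp = m.derive_arm_transitions(lom_arm)
        matrix = m.build_matrix(tp)
        p = tp.p_pfs_pfs
        assert m.expected_state_time_closed_form(matrix, "PFS") == pytest.approx(
            p / (1 - p), abs=1e-12
        )

    def test_pd_matches_trace_summation(self, lom_arm):
        tp = m.derive_arm_transitions(lom_arm)
        matrix = m.build_matrix(tp)
        trace = m.run_cohort(matrix, n_cycles=120)
        assert m.expected_state_time_closed_form(
            matrix, "PD", n_cycles=120
        ) == pytest.approx(trace.pd[1:].sum(), abs=1e-9)

    def test_discounted_equivalence_on_random_chains(self):
        """Analytic occupancy sums equal trace-based accrual, state by state."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            matrix = random_chain(rng)
            rate = rng.uniform(0.0, 0.1)
            delta = (1 + rate) ** (-1 / 12)
            trace = m.run_cohort(matrix, n_cycles=120)
            d = discount_factors(120, rate)
            for idx, state in enumerate(m.STATES):
                expected = float((trace.occupancy[1:, idx] * d).sum())
                got = m.expected_state_time_closed_form(
                    matrix, state, monthly_discount=delta, n_cycles=120
                )
                assert got == pytest.approx(expected, abs=1e-9), state

    def test_equal_stay_probabilities_degenerate_branch(self):
        tp = m.TransitionProbabilities.from_exit_probs(0.15, 0.05, 0.20)
        # stay_pfs = stay_pd = 0.8 exactly: PD(t) = f * t * p**(t-1)
        matrix = m.build_matrix(tp)
        trace = m.run_cohort(matrix, n_cycles=80)
        assert m.expected_state_time_closed_form(
            matrix, "PD", n_cycles=80
        ) == pytest.approx(trace.pd[1:].sum(), abs=1e-9)

    def test_death_requires_discount_or_finite_horizon(self):
        matrix = m.build_matrix(m.TransitionProbabilities.from_exit_probs(0.2, 0.1, 0.3))
        with pytest.raises(m.UnsupportedStructureError):
            m.expected_state_time_closed_form(matrix, "Death", monthly_discount=1.0)
        finite = m.expected_state_time_closed_form(matrix, "Death", monthly_discount=0.99)
        assert np.isfinite(finite)

    def test_topology_check(self):
        bad = np.array([[0.8, 0.1, 0.1], [0.05, 0.85, 0.1], [0.0, 0.0, 1.0]])
        with pytest.raises(m.UnsupportedStructureError):
            # bypass TransitionMatrix validation to probe the oracle's own check
            matrix = m.TransitionMatrix.__new__(m.TransitionMatrix)
            matrix.entries = bad
            matrix.states = m.STATES
            matrix.notes = []
            m.expected_state_time_closed_form(matrix, "PFS")
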