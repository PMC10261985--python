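"""Unit and property tests for the CTMC engine and its deterministic oracle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import fibrosim as fs
from fibrosim.model import (
    AbsorbingStateError,
    NoTransitionError,
    PatientTrajectory,
    RateParameters,
    simulate_final_stages,
)


def tabled(tf=(5.7, 86, 97, 116), tb=(10, 51, 208, 526), p0=0.64):
    return RateParameters.from_tau(tf, tb, p0)


# ---------------------------------------------------------------------------
# waiting times


class TestWaitingTime:
    def test_inversion_closed_form(self):
        # tau = (1/rate) ln(1/u): u = e^-1 gives exactly the mean time
        assert fs.sample_waiting_time(0.1, math.exp(-1)) == pytest.approx(10.0)
        # u -> 1 gives a vanishing waiting time
        assert fs.sample_waiting_time(1.0, 1 - 1e-12) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("rate", [0.0, -0.5])
    def test_disabled_transition_signals(self, rate):
        with pytest.raises(NoTransitionError):
            fs.sample_waiting_time(rate, 0.5)

    @pytest.mark.parametrize("u", [0.0, 1.0, -0.1, 1.5])
    def test_uniform_domain(self, u):
        with pytest.raises(ValueError):
            fs.sample_waiting_time(1.0, u)

    def test_monte_carlo_mean_matches_analytic(self, rng):
        # mean of 1e5 draws at rate 1/5.7 within 3 standard errors of 5.7
        rate = 1 / 5.7
        draws = np.array([fs.sample_waiting_time(rate, u) for u in rng.random(100_000)])
        se = 5.7 / math.sqrt(draws.size)
        assert draws.mean() == pytest.approx(5.7, abs=3 * se)

    def test_exponential_law_ks(self, rng):
        rate = 0.25
        draws = np.array([fs.sample_waiting_time(rate, u) for u in rng.random(10_000)])
        res = stats.kstest(draws, "expon", args=(0, 1 / rate))
        assert res.pvalue > 0.001


# ---------------------------------------------------------------------------
# single steps


class TestStepPatient:
    def test_boundary_stages_have_one_clock(self, rng):
        params = tabled()
        assert fs.step_patient(0, params, rng)[0] == 1
        assert fs.step_patient(4, params, rng)[0] == 3

    def test_absorbing_state_signals(self, rng):
        frozen = RateParameters(0.64, np.zeros(4), np.zeros(4))
        with pytest.raises(AbsorbingStateError):
            fs.step_patient(2, frozen, rng)

    def test_competing_clocks_split(self, rng):
        # from F1 the regression clock (rate 1/10) wins against progression
        # (rate 1/86) with probability 0.1 / (0.1 + 1/86) = 0.8958
        params = tabled()
        n = 100_000
        down = sum(fs.step_patient(1, params, rng)[0] == 0 for _ in range(n))
        assert down / n == pytest.approx(0.8958, abs=0.003)


# ---------------------------------------------------------------------------
# whole trajectories


class TestSimulatePatient:
    def test_non_progressors_never_move(self, rng):
        params = tabled(p0=0.0)
        traj = fs.simulate_patient(0, params, 1000.0, rng)
        assert traj.events == [] and traj.final_stage == 0 and not traj.is_progressor

    def test_monotone_ascent_without_reverse_rates(self, rng):
        params = RateParameters(1.0, np.array([0.5] * 4), np.zeros(4))
        traj = fs.simulate_patient(1, params, 1e6, rng)
        stages = [1] + [s for _, s in traj.events]
        assert stages == sorted(stages) and traj.final_stage == 4

    def test_negative_horizon_rejected(self, rng):
        with pytest.raises(ValueError):
            fs.simulate_patient(0, tabled(), -1.0, rng)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_trajectory_invariants(self, seed):
        rng = np.random.default_rng(seed)
        params = tabled()
        traj = fs.simulate_patient(int(rng.integers(0, 5)), params, 60.0, rng)
        times = [t for t, _ in traj.events]
        stages = [traj.initial_stage] + [s for _, s in traj.events]
        assert times == sorted(times)
        assert all(t > 0 for t in times)
        assert all(abs(b - a) == 1 for a, b in zip(stages, stages[1:]))
        if not traj.is_progressor:
            assert traj.initial_stage == 0 and traj.events == []

    def test_trajectory_validation_rejects_jumps(self):
        with pytest.raises(ValueError):
            PatientTrajectory(0, True, events=[(1.0, 2)])
        with pytest.raises(ValueError):
            PatientTrajectory(0, False, events=[(1.0, 1)])

    def test_endpoint_matches_oracle_from_f1(self, fitted, rng):
        # P(final < F1 at 12 months) across 1e4 patients vs the matrix entry
        n = 10_000
        finals = simulate_final_stages(np.ones(n, dtype=int), fitted, 12.0, rng)
        p = fs.transition_probability_matrix(fitted, 12.0)[1, 0]
        se = math.sqrt(p * (1 - p) / n)
        assert (finals == 0).mean() == pytest.approx(p, abs=3 * se)


# ---------------------------------------------------------------------------
# cohorts


class TestSimulateCohort:
    def test_conservation_and_row_sums(self, fitted, rng):
        initial = fs.CohortDistribution(np.array([20, 22, 4, 5, 0]))
        table = fs.simulate_cohort(initial, fitted, 18.0, rng)
        assert table.grand_total == initial.total
        np.testing.assert_array_equal(table.counts.sum(axis=1), initial.counts)

    def test_zero_horizon_is_diagonal(self, fitted, rng):
        initial = fs.CohortDistribution(np.array([3, 4, 5, 6, 7]))
        table = fs.simulate_cohort(initial, fitted, 0.0, rng)
        np.testing.assert_array_equal(table.counts, np.diag(initial.counts))

    def test_empty_cohort_rejected(self, fitted, rng):
        with pytest.raises(ValueError):
            fs.simulate_cohort(fs.CohortDistribution(np.zeros(5)), fitted, 12.0, rng)

    def test_reproducible_under_fixed_seed(self, fitted):
        initial = fs.CohortDistribution(np.array([20, 22, 4, 5, 0]))
        t1 = fs.simulate_cohort(initial, fitted, 18.0, np.random.default_rng(42))
        t2 = fs.simulate_cohort(initial, fitted, 18.0, np.random.default_rng(42))
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_monotone_cohort_without_forward_rates(self, rng):
        params = RateParameters(1.0, np.zeros(4), np.array([0.1] * 4))
        finals = simulate_final_stages(np.full(2000, 3), params, 200.0, rng)
        assert (finals <= 3).all()


# ---------------------------------------------------------------------------
# deterministic oracle


class TestTransitionMatrix:
    def test_identity_at_t0(self, fitted):
        np.testing.assert_allclose(
            fs.transition_probability_matrix(fitted, 0.0), np.eye(5), atol=1e-12
        )

    def test_identity_for_all_zero_rates(self):
        frozen = RateParameters(0.5, np.zeros(4), np.zeros(4))
        np.testing.assert_allclose(
            fs.transition_probability_matrix(frozen, 37.0), np.eye(5), atol=1e-12
        )

    def test_two_state_closed_form(self):
        # only F0<->F1 enabled, pure progressors: P(F0->F0 at t) has the
        # classic two-state solution (b + a e^{-(a+b)t}) / (a+b)
        a, b, t = 1 / 5.7, 1 / 10, 12.0
        params = RateParameters(1.0, np.array([a, 0, 0, 0]), np.array([b, 0, 0, 0]))
        expected = (b + a * math.exp(-(a + b) * t)) / (a + b)
        m = fs.transition_probability_matrix(params, t)
        assert m[0, 0] == pytest.approx(expected, rel=1e-10)
        assert m[0, 1] == pytest.approx(1 - expected, rel=1e-10)

    def test_rows_are_distributions(self, fitted):
        for t in (0.5, 12, 156):
            m = fs.transition_probability_matrix(fitted, t)
            assert (m >= 0).all()
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_chapman_kolmogorov_for_progressor_chain(self):
        params = tabled(p0=1.0)  # pure progressors: the F0 mixture is trivial
        m6 = fs.transition_probability_matrix(params, 6.0)
        m18 = fs.transition_probability_matrix(params, 18.0)
        m24 = fs.transition_probability_matrix(params, 24.0)
        np.testing.assert_allclose(m6 @ m18, m24, atol=1e-10)

    def test_negative_time_rejected(self, fitted):
        with pytest.raises(ValueError):
            fs.transition_probability_matrix(fitted, -1.0)

    def test_progressor_mixture_on_f0_row(self, fitted):
        m = fs.transition_probability_matrix(fitted, 24.0)
        pure = fs.transition_probability_matrix(
            RateParameters(1.0, fitted.forward, fitted.reverse), 24.0
        )
        p0 = fitted.progressor_fraction
        assert m[0, 0] == pytest.approx((1 - p0) + p0 * pure[0, 0], rel=1e-10)
        np.testing.assert_allclose(m[1:], pure[1:], atol=1e-12)


def test_simulator_agrees_with_oracle(fitted, rng):
    """Empirical endpoint frequencies match the matrix exponential.

    Each initial stage gets 1e4 patients; every cell must lie within four
    binomial standard errors of the oracle probability (plus one count of
    discreteness allowance).
    """
    n = 10_000
    t = 12.0
    m = fs.transition_probability_matrix(fitted, t)
    for stage in range(5):
        finals = simulate_final_stages(np.full(n, stage), fitted, t, rng)
        freq = np.bincount(finals, minlength=5) / n
        se = np.sqrt(m[stage] * (1 - m[stage]) / n)
        assert (np.abs(freq - m[stage]) <= 4 * se + 1 / n).all()


# ---------------------------------------------------------------------------
# parameters and scores


class TestRateParameters:
    def test_tau_round_trip(self, fitted):
        again = RateParameters.from_tau(
            fitted.tau_forward, fitted.tau_backward, fitted.progressor_fraction
        )
        np.testing.assert_allclose(again.forward, fitted.forward)
        np.testing.assert_allclose(again.reverse, fitted.reverse)

    def test_validation(self):
        with pytest.raises(ValueError):
            RateParameters(1.5, np.zeros(4), np.zeros(4))
        with pytest.raises(ValueError):
            RateParameters(0.5, -np.ones(4), np.zeros(4))
        with pytest.raises(ValueError):
            RateParameters.from_tau([0, 1, 1, 1], [1, 1, 1, 1], 0.5)

    def test_named_rate_lookup_interleaves(self, fitted):
        assert fitted.rate("p1") == pytest.approx(1 / 5.7)
        assert fitted.rate("p2") == pytest.approx(1 / 10)
        assert fitted.rate("p7") == pytest.approx(1 / 116)
        assert fitted.rate("p8") == pytest.approx(1 / 526)

    def test_scale_factor_composition(self, fitted):
        alpha = np.array([0.5, 2.0, 1.0, 4.0])
        beta = np.array([2.0, 3.0, 1.0, 1.0, 0.5, 1.0, 1.0, 2.0])
        eff = fitted.with_alpha(alpha).with_beta(beta)
        np.testing.assert_allclose(
            eff.forward, fitted.forward * alpha * beta[0::2]
        )
        np.testing.assert_allclose(eff.reverse, fitted.reverse * beta[1::2])

    def test_scale_factors_apply(self, fitted):
        sf = fs.ScaleFactors(alpha=np.ones(4) * 2.0)
        np.testing.assert_allclose(sf.apply(fitted).forward, fitted.forward * 2)
        np.testing.assert_allclose(sf.apply(fitted).reverse, fitted.reverse)


class TestAverageScore:
    def test_trial_baseline_value(self):
        dist = fs.CohortDistribution(np.array([20, 22, 4, 5, 0]))
        assert fs.average_fibrosis_score(dist) == pytest.approx(45 / 51)

    @pytest.mark.parametrize("stage,score", [(0, 0.0), (4, 4.0)])
    def test_degenerate_cohorts(self, stage, score):
        counts = np.zeros(5)
        counts[stage] = 7
        assert fs.average_fibrosis_score(fs.CohortDistribution(counts)) == score

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            fs.average_fibrosis_score(fs.CohortDistribution(np.zeros(5)))
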