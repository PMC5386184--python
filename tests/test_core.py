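"""Unit and property tests for the weighting engines and point prediction."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teadvice import (
    ExpertPanel,
    LossSpec,
    TimeSeries,
    WeightScheme,
    coefficient,
    init_state,
    point_predict,
    run_online,
    update,
)
from teadvice.regret import regret_of

from conftest import random_instance


class TestTypes:
    def test_timeseries_rejects_unsorted_times(self):
        with pytest.raises(ValueError):
            TimeSeries(np.array([1.0, 1.0]), np.array([0.0, 0.0]))

    def test_timeseries_rejects_nonfinite_values(self):
        with pytest.raises(ValueError):
            TimeSeries.from_values([0.0, np.nan])

    def test_panel_rejects_nonfinite_advice_within_horizon(self):
        with pytest.raises(ValueError):
            ExpertPanel(np.array([[1.0, np.nan]]), horizons=np.array([2]))

    def test_panel_allows_nan_beyond_horizon(self):
        panel = ExpertPanel(np.array([[1.0, np.nan]]), horizons=np.array([1]))
        assert panel.active(1).tolist() == [True]
        assert panel.active(2).tolist() == [False]

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            WeightScheme(variant="tea", lambda_=0.5)
        with pytest.raises(ValueError):
            WeightScheme(variant="cz", rho=1.5)
        with pytest.raises(ValueError):
            WeightScheme(variant="nope")

    def test_loss_warns_beyond_epsilon(self):
        with pytest.warns(RuntimeWarning):
            LossSpec(epsilon=1.0).loss(5.0, 0.0)


class TestInitState:
    @pytest.mark.parametrize("n", [1, 2, 4])
    def test_uniform_weights_and_zero_losses(self, n):
        panel = ExpertPanel(np.zeros((n, 3)))
        state = init_state(panel)
        assert state.t == 0
        assert state.predictor_loss == 0.0
        np.testing.assert_array_equal(state.expert_losses, np.zeros(n))
        np.testing.assert_allclose(state.weights, np.full(n, 1.0 / n))


class TestCoefficient:
    @pytest.mark.parametrize(
        "scheme, k, t, expected",
        [
            (WeightScheme("tea", lambda_=2.0), 1, 5, 1.0),
            (WeightScheme("tea", lambda_=2.0), 3, 5, 4.0),
            (WeightScheme("tea", lambda_=2.0, tea_exponent="k"), 3, 5, 8.0),
            (WeightScheme("standard"), 4, 9, 1.0),
            (WeightScheme("cz", rho=0.9), 5, 5, 1.0 / 0.9),
            (WeightScheme("cz", rho=0.9), 3, 5, 0.9),
        ],
    )
    def test_values(self, scheme, k, t, expected):
        assert coefficient(scheme, k, t) == pytest.approx(expected)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            coefficient(WeightScheme("standard"), 0, 5)
        with pytest.raises(ValueError):
            coefficient(WeightScheme("standard"), 6, 5)


class TestUpdate:
    def test_hand_evaluated_two_steps(self, two_expert_panel, abs_loss):
        """lambda=2, eta=1: losses (0,1) then (0,3); weights from exp(-L)."""
        scheme = WeightScheme("tea", lambda_=2.0, eta=1.0)
        state = init_state(two_expert_panel)
        state = update(state, two_expert_panel.advice_at(1), 0.0, abs_loss,
                       scheme, prediction=0.5)
        np.testing.assert_allclose(state.expert_losses, [0.0, 1.0])
        np.testing.assert_allclose(state.weights, [0.7311, 0.2689], atol=5e-5)
        state = update(state, two_expert_panel.advice_at(2), 0.0, abs_loss,
                       scheme, prediction=0.5)
        np.testing.assert_allclose(state.expert_losses, [0.0, 3.0])
        np.testing.assert_allclose(state.weights, [0.9526, 0.0474], atol=5e-5)
        assert state.t == 2

    def test_lambda_one_reduces_to_standard_bit_identically(self, rng):
        panel, target = random_instance(rng)
        r_tea = run_online(panel, target, WeightScheme("tea", lambda_=1.0, eta=0.7))
        r_std = run_online(panel, target, WeightScheme("standard", eta=0.7))
        for a, b in zip(r_tea.states, r_std.states):
            np.testing.assert_array_equal(a.log_weights, b.log_weights)
            np.testing.assert_array_equal(a.expert_losses, b.expert_losses)
        np.testing.assert_array_equal(r_tea.predictions, r_std.predictions)

    def test_cz_recursion_matches_direct_sum(self, rng):
        """Incremental L <- rho*L + l/rho equals sum_k rho^(t-k-1) l_k."""
        rho = 0.85
        panel, target = random_instance(rng)
        scheme = WeightScheme("cz", rho=rho, eta=1.0)
        result = run_online(panel, target, scheme)
        T = len(target)
        losses = np.abs(panel.advice[:, :T] - target.values)
        direct = sum(
            rho ** (T - k - 1) * losses[:, k - 1] for k in range(1, T + 1)
        )
        np.testing.assert_allclose(result.final_state.expert_losses, direct,
                                   rtol=1e-10)

    def test_nonfinite_observation_rejected(self, two_expert_panel, abs_loss):
        state = init_state(two_expert_panel)
        with pytest.raises(ValueError):
            update(state, two_expert_panel.advice_at(1), np.nan, abs_loss,
                   WeightScheme("standard", eta=1.0), 0.0)

    def test_coefficient_overflow_reported_with_horizon(self, two_expert_panel,
                                                        abs_loss):
        scheme = WeightScheme("tea", lambda_=1e300, eta=1.0)
        state = init_state(two_expert_panel)
        state = update(state, two_expert_panel.advice_at(1), 0.0, abs_loss,
                       scheme, 0.0)
        state = update(state, two_expert_panel.advice_at(2), 0.0, abs_loss,
                       scheme, 0.0)
        with pytest.raises(OverflowError, match="horizon"):
            update(state, two_expert_panel.advice_at(3), 0.0, abs_loss,
                   scheme, 0.0)


class TestPointPredict:
    def test_constant_advice_for_any_weights(self, rng):
        panel = ExpertPanel(np.full((4, 3), 5.0))
        state = init_state(panel)
        state = update(state, panel.advice_at(1), rng.uniform(), LossSpec(),
                       WeightScheme("standard", eta=2.0), 5.0)
        assert point_predict(state, panel, 1) == pytest.approx(5.0)

    def test_weighted_average(self, two_expert_panel, abs_loss):
        scheme = WeightScheme("tea", lambda_=2.0, eta=1.0)
        state = init_state(two_expert_panel)
        state = update(state, two_expert_panel.advice_at(1), 0.0, abs_loss,
                       scheme, 0.5)
        # weights (0.7311, 0.2689), advice at t+1 is (0, 1)
        assert point_predict(state, two_expert_panel, 1) == pytest.approx(
            0.2689, abs=5e-5
        )

    def test_single_expert_returns_its_advice(self):
        panel = ExpertPanel(np.array([[3.0, 7.0]]))
        assert point_predict(init_state(panel), panel, 2) == pytest.approx(7.0)

    def test_expired_experts_excluded_and_renormalized(self):
        panel = ExpertPanel(
            np.array([[1.0, np.nan], [3.0, 5.0]]), horizons=np.array([1, 2])
        )
        state = init_state(panel)
        assert point_predict(state, panel, 1) == pytest.approx(2.0)
        assert point_predict(state, panel, 2) == pytest.approx(5.0)

    def test_error_when_no_expert_survives(self):
        panel = ExpertPanel(np.array([[1.0, np.nan]]), horizons=np.array([1]))
        with pytest.raises(ValueError):
            point_predict(init_state(panel), panel, 2)


class TestRunOnline:
    def test_perfect_expert_dominates(self, rng):
        target = TimeSeries.from_values(rng.uniform(0, 1, size=8))
        advice = rng.uniform(0, 1, size=(3, 8))
        advice[1] = target.values
        panel = ExpertPanel(advice)
        result = run_online(panel, target, WeightScheme("tea", lambda_=1.3, eta=2.0))
        for state in result.states:
            assert np.argmax(state.weights) == 1
            assert state.expert_losses[1] == 0.0

    def test_eta_zero_predicts_unweighted_mean(self, rng):
        panel, target = random_instance(rng)
        result = run_online(panel, target, WeightScheme("standard", eta=0.0))
        T = len(target)
        means = panel.advice[:, :T].mean(axis=0)
        np.testing.assert_allclose(result.predictions, means, rtol=1e-12)

    def test_matches_hand_trace(self):
        """Step-by-step application of the coefficient/weight/average rules."""
        advice = np.array([[1.0, 2.0, 3.0], [0.0, 1.0, 0.0]])
        y = [0.5, 1.5, 1.0]
        lam, eta = 1.5, 0.8
        panel = ExpertPanel(advice)
        result = run_online(
            panel, TimeSeries.from_values(y),
            WeightScheme("tea", lambda_=lam, eta=eta),
        )
        L = np.zeros(2)
        w = np.array([0.5, 0.5])
        for t in range(1, 4):
            expected_pred = w @ advice[:, t - 1]
            assert result.states[t - 1].t == t
            assert result.predictions[t - 1] == pytest.approx(expected_pred)
            L += lam ** (t - 1) * np.abs(advice[:, t - 1] - y[t - 1])
            w = np.exp(-eta * L)
            w /= w.sum()
            np.testing.assert_allclose(result.states[t - 1].weights, w, rtol=1e-12)

    def test_burn_in_trims_emitted_predictions(self, rng):
        panel, target = random_instance(rng, t_max=10)
        T = len(target)
        if T < 3:
            pytest.skip("instance too short")
        result = run_online(panel, target, WeightScheme("standard", eta=1.0),
                            burn_in=2)
        assert result.steps[0] == 3 and len(result.predictions) == T - 2

    def test_target_shorter_than_burn_in_rejected(self, two_expert_panel):
        with pytest.raises(ValueError):
            run_online(two_expert_panel, TimeSeries.from_values([1.0, 2.0]),
                       WeightScheme("standard", eta=1.0), burn_in=2)


class TestInvariants:
    @pytest.mark.parametrize("scheme", [
        WeightScheme("standard", eta=1.3),
        WeightScheme("tea", lambda_=1.4, eta=0.6),
        WeightScheme("tea", lambda_=1.2, tea_exponent="k", eta=0.6),
        WeightScheme("cz", rho=0.9, eta=2.0),
    ])
    def test_weights_sum_to_one_after_every_update(self, scheme, rng):
        panel, target = random_instance(rng)
        result = run_online(panel, target, scheme)
        for state in result.states:
            assert abs(state.weights.sum() - 1.0) < 1e-12

    @pytest.mark.parametrize("scheme", [
        WeightScheme("standard", eta=0.8),
        WeightScheme("tea", lambda_=1.3, eta=0.8),
        WeightScheme("cz", rho=0.8, eta=0.8),
    ])
    def test_monotone_dominance(self, scheme, rng):
        """Per-step dominated losses imply a strictly smaller weight."""
        T = 6
        y = rng.uniform(0, 1, size=T)
        good = y + rng.uniform(0.0, 0.1, size=T)
        bad = y + rng.uniform(0.2, 0.5, size=T)
        panel = ExpertPanel(np.vstack([good, bad]))
        result = run_online(panel, TimeSeries.from_values(y), scheme)
        for state in result.states:
            assert state.weights[0] > state.weights[1]

    def test_permutation_equivariance(self, rng):
        panel, target = random_instance(rng)
        perm = rng.permutation(panel.n_experts)
        permuted = ExpertPanel(panel.advice[perm])
        scheme = WeightScheme("tea", lambda_=1.2, eta=1.0)
        r1 = run_online(panel, target, scheme)
        r2 = run_online(permuted, target, scheme)
        np.testing.assert_allclose(
            r1.final_state.weights[perm], r2.final_state.weights, rtol=1e-12
        )
        np.testing.assert_allclose(r1.predictions, r2.predictions, rtol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), rho=st.floats(0.5, 0.95))
    def test_weight_relation_tea_vs_cz(self, seed, rho):
        """With lambda = 1/rho and exponent k, TEA weights equal CZ weights
        raised to the power rho^-(t-1), renormalized."""
        rng = np.random.default_rng(seed)
        panel, target = random_instance(rng)
        eta = 0.9
        r_tea = run_online(
            panel, target,
            WeightScheme("tea", lambda_=1.0 / rho, tea_exponent="k", eta=eta),
        )
        r_cz = run_online(panel, target, WeightScheme("cz", rho=rho, eta=eta))
        T = len(target)
        powered = r_cz.final_state.weights ** (rho ** (-(T - 1)))
        powered /= powered.sum()
        np.testing.assert_allclose(r_tea.final_state.weights, powered,
                                   rtol=1e-7, atol=1e-12)

    def test_log_domain_survives_huge_accumulated_losses(self):
        """eta * lambda^(t-1) * loss far beyond exp range stays normalized."""
        panel = ExpertPanel(np.vstack([np.zeros(40), np.ones(40)]))
        target = TimeSeries.from_values(np.zeros(40))
        result = run_online(panel, target,
                            WeightScheme("tea", lambda_=1.5, eta=10.0))
        w = result.final_state.weights
        assert abs(w.sum() - 1.0) < 1e-12 and w[0] > 0.999
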