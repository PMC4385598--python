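"""Forward pass, error metrics, and the improved gradient-descent trainer."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shadematch import (
    Activation,
    FlatAreaConfig,
    NetworkConfig,
    NetworkWeights,
    TrainingConfig,
    init_weights,
    sample_error,
    total_mse,
    train_gd,
)
from shadematch.network import (
    ShapeMismatchError,
    batch_errors,
    flatten_weights,
    forward,
    total_error,
    unflatten_weights,
)
from shadematch.training import (
    TrainingState,
    adapt_learning_rate,
    flat_area_adjust,
    gradient,
    momentum_update,
)

from conftest import finite_difference_gradient


def zero_net(cfg):
    return NetworkWeights(
        np.zeros((cfg.n_hidden, cfg.n_in)),
        np.zeros((cfg.n_out, cfg.n_hidden)),
        np.zeros(cfg.n_hidden),
        np.zeros(cfg.n_out),
    )


class TestForward:
    def test_logistic_midpoint_for_zero_net_input(self):
        cfg = NetworkConfig(n_hidden=4, activation=Activation.LOGISTIC)
        out, hidden, nets = forward(zero_net(cfg), cfg, np.array([1.0, -2.0, 0.5]))
        np.testing.assert_allclose(hidden, 0.5)
        np.testing.assert_allclose(out, 0.5)
        np.testing.assert_allclose(nets["hidden"], 0.0)

    def test_large_gradient_factor_flattens_toward_midpoint(self):
        cfg = NetworkConfig(n_hidden=2, activation=Activation.LOGISTIC)
        w = init_weights(cfg, 0)
        x = np.array([0.3, -0.2, 0.9])
        outs = [forward(w, cfg, x, lam=lam)[0] for lam in (1.0, 4.0, 64.0, 1e6)]
        gaps = [np.max(np.abs(o - 0.5)) for o in outs]
        assert gaps == sorted(gaps, reverse=True)
        assert gaps[-1] < 1e-5

    def test_shape_mismatch_rejected(self):
        cfg = NetworkConfig(n_hidden=4)
        with pytest.raises(ShapeMismatchError):
            forward(zero_net(cfg), cfg, np.array([1.0, 2.0]))


class TestErrorMetrics:
    # per-sample errors for printed actual/expected recipe pairs,
    # frozen from independent exact decimal arithmetic
    PRINTED_ROWS = [
        ((0.1605, 0.0566, 0.0262, 0.0412, 0.0576), (0.24, 0.08, 0.08, 0, 0), 0.01477745),
        ((0.0009, 0.1468, 0.1755, 0.0317, 0.044), (0, 0, 0, 0.4, 0), 0.18993219),
        ((0.0045, 0.1113, 0.0952, 0.024, 0.0419), (0.16, 0.08, 0, 0.16, 0), 0.05447459),
        ((0.3388, 0.1398, 0.0169, 0.051, 0.0468), (0.16, 0.08, 0, 0, 0.16), 0.05124633),
        ((0.0208, 0.125, 0.3111, 0.2054, 0.1481), (0.08, 0, 0, 0.08, 0.24), 0.14008362),
    ]

    @pytest.mark.parametrize("actual,expected,value", PRINTED_ROWS)
    def test_sample_error_matches_hand_computation(self, actual, expected, value):
        assert sample_error(expected, actual) == pytest.approx(value, abs=1e-12)

    def test_sample_error_basics(self):
        assert sample_error([0.1, 0.2], [0.1, 0.2]) == 0.0
        assert sample_error([1, 0, 0, 0, 0], [0, 0, 0, 0, 0]) == 1.0
        with pytest.raises(ShapeMismatchError):
            sample_error([1.0], [1.0, 2.0])

    def test_total_mse_squares_per_sample_errors(self):
        assert total_mse([0.3]) == pytest.approx(0.09)
        assert total_mse([0.1, 0.3]) == pytest.approx(0.05)
        assert total_mse([0.0, 0.0]) == 0.0
        assert total_mse([0.1, 0.3], as_printed=False) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            total_mse([])


class TestGradient:
    @pytest.mark.parametrize("activation", [Activation.LOGISTIC, Activation.TANGENT])
    @pytest.mark.parametrize("lam", [1.0, 4.0])
    def test_backprop_matches_finite_differences(self, activation, lam):
        cfg = NetworkConfig(n_in=2, n_hidden=3, n_out=2,
                            activation=activation, lambda_factor=lam)
        rng = np.random.default_rng(17)
        w = init_weights(cfg, 29)
        X = rng.normal(size=(4, 2))
        D = rng.uniform(0, 0.4, size=(4, 2))
        g = gradient(w, cfg, X, D)
        fd = finite_difference_gradient(
            lambda v: total_error(unflatten_weights(v, cfg), cfg, X, D),
            flatten_weights(w),
        )
        np.testing.assert_allclose(g, fd, rtol=1e-6, atol=1e-9)

    def test_momentum_recursion_closed_form(self):
        """With a constant gradient, ΔW_t = −ηg(1 + α + α² + …)."""
        g = np.array([1.0, -2.0, 0.5])
        eta, alpha = 0.1, 0.5
        delta = np.zeros(3)
        for t in range(1, 6):
            delta = momentum_update(g, delta, eta, alpha)
            geometric = sum(alpha**k for k in range(t))
            np.testing.assert_allclose(delta, -eta * g * geometric, rtol=1e-12)


class TestAdaptiveLearning:
    def _state(self, eta):
        cfg = NetworkConfig(n_hidden=2)
        st_ = TrainingState.fresh(TrainingConfig(eta0=eta), cfg)
        st_.prev_delta = np.ones(cfg.n_params)
        return st_

    def test_error_rise_shrinks_eta_and_clears_momentum(self):
        tcfg = TrainingConfig(eta0=0.1, beta=0.7)
        state, accepted = adapt_learning_rate(self._state(0.1), 5.0, 4.0, tcfg)
        assert not accepted
        assert state.eta_t == pytest.approx(0.07)
        assert np.all(state.prev_delta == 0.0)

    def test_error_fall_grows_eta(self):
        tcfg = TrainingConfig(eta0=0.1, theta_up=1.05)
        state, accepted = adapt_learning_rate(self._state(0.1), 3.0, 4.0, tcfg)
        assert accepted
        assert state.eta_t == pytest.approx(0.105)

    @given(outcomes=st.lists(st.booleans(), min_size=1, max_size=60))
    def test_eta_bounded_by_growth_schedule(self, outcomes):
        tcfg = TrainingConfig(eta0=0.1, beta=0.7, theta_up=1.05)
        state = self._state(0.1)
        for fell in outcomes:
            err_now, err_prev = (3.0, 4.0) if fell else (5.0, 4.0)
            state, _ = adapt_learning_rate(state, err_now, err_prev, tcfg)
            assert 0.0 < state.eta_t <= 0.1 * tcfg.theta_up ** len(outcomes)


class TestFlatArea:
    def _state(self):
        cfg = NetworkConfig(n_hidden=2)
        return TrainingState.fresh(TrainingConfig(), cfg)

    def _tcfg(self):
        return TrainingConfig(
            flat_area=FlatAreaConfig(enabled=True, grad_tol=1e-6,
                                     residual_tol=0.1, lambda_boost=4.0)
        )

    def test_flat_with_large_residuals_boosts_lambda(self):
        state = flat_area_adjust(self._state(), 1e-8, np.array([0.3, -0.05]), self._tcfg())
        assert state.lambda_current == 4.0

    def test_leaving_flat_area_restores_lambda(self):
        state = self._state()
        state.lambda_current = 4.0
        state = flat_area_adjust(state, 0.5, np.array([0.3]), self._tcfg())
        assert state.lambda_current == 1.0

    def test_converged_network_keeps_lambda_at_one(self):
        state = flat_area_adjust(self._state(), 1e-8, np.array([0.01, -0.02]), self._tcfg())
        assert state.lambda_current == 1.0


def toy_problem(seed=3, n=8):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1, 1, size=(n, 3))
    D = rng.uniform(0, 0.4, size=(n, 5))
    return X, D


class TestTrainGD:
    def test_goal_error_already_met_stops_after_one_epoch(self):
        X, D = toy_problem()
        cfg = NetworkConfig(n_hidden=3)
        tcfg = TrainingConfig(goal_error=1e6, max_epochs=50)
        _, state = train_gd(X, D, cfg, tcfg, seed=0)
        assert state.epoch == 1
        assert len(state.error_history) == 1

    def test_training_reduces_error(self):
        X, D = toy_problem()
        cfg = NetworkConfig(n_hidden=3)
        w, state = train_gd(X, D, cfg, TrainingConfig(max_epochs=150), seed=1)
        hist = state.error_history
        assert hist[-1] < hist[0]
        # with the accept/reject rule the recorded error never rises
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_same_seed_reproduces_history_bitwise(self):
        X, D = toy_problem()
        cfg = NetworkConfig(n_hidden=4)
        _, s1 = train_gd(X, D, cfg, TrainingConfig(max_epochs=60), seed=5)
        _, s2 = train_gd(X, D, cfg, TrainingConfig(max_epochs=60), seed=5)
        assert s1.error_history == s2.error_history

    def test_reduces_to_vanilla_gradient_descent(self):
        """α=0, fixed η, λ=1 must track a textbook GD loop step for step.

        The oracle recomputes each step's gradient by central finite
        differences, independently of the backprop code.
        """
        X, D = toy_problem(seed=9, n=5)
        cfg = NetworkConfig(n_in=3, n_hidden=2, n_out=5)
        eta = 0.02
        tcfg = TrainingConfig(eta0=eta, alpha=0.0, adaptive_lr=False,
                              max_epochs=10, goal_error=0.0)
        init = init_weights(cfg, 13)
        _, state = train_gd(X, D, cfg, tcfg, init=init)

        vec = flatten_weights(init)
        oracle = []
        for _ in range(10):
            fd = finite_difference_gradient(
                lambda v: total_error(unflatten_weights(v, cfg), cfg, X, D), vec
            )
            vec = vec - eta * fd
            oracle.append(total_error(unflatten_weights(vec, cfg), cfg, X, D))
        np.testing.assert_allclose(state.error_history, oracle, rtol=1e-5)

    def test_explicit_init_makes_training_deterministic_without_seed(self):
        X, D = toy_problem()
        cfg = NetworkConfig(n_hidden=3)
        init = init_weights(cfg, 2)
        w1, _ = train_gd(X, D, cfg, TrainingConfig(max_epochs=30), init=init)
        w2, _ = train_gd(X, D, cfg, TrainingConfig(max_epochs=30), init=init)
        np.testing.assert_array_equal(flatten_weights(w1), flatten_weights(w2))


def test_batch_errors_matches_sample_error():
    cfg = NetworkConfig(n_hidden=3)
    w = init_weights(cfg, 0)
    X, D = toy_problem(seed=21, n=6)
    errs = batch_errors(w, cfg, X, D)
    expected = [sample_error(D[i], forward(w, cfg, X[i])[0]) for i in range(6)]
    np.testing.assert_allclose(errs, expected, rtol=1e-12)
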