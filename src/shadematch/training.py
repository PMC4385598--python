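"""Gradient-descent and Levenberg-Marquardt trainers.

The gradient-descent trainer implements three refinements of plain
backpropagation that together make small colour-matching networks train
reliably:

* **momentum** — a fraction α of the previous update is added to the
  current one, ΔW_t = −η·∇E + α·ΔW_{t−1}, damping oscillation across
  narrow valleys of the error surface;
* **adaptive learning efficiency** — after each full-batch pass, if the
  total error rose the step is rolled back and η shrinks by a factor
  β < 1; if it fell the step stands and η grows by a factor θ > 1;
* **gradient factor** — when the error change ΔE is nearly zero while
  residuals remain large (a flat area caused by saturated neurons), the
  activations' net inputs are divided by λ > 1 to restore slope; λ
  returns to 1 once the trajectory leaves the flat area.

Updates are full-batch: the adaptive-η rule compares *total* error
across passes, which is only coherent when every pass sees the whole
training set.

The Levenberg-Marquardt trainer is a damped Gauss-Newton method on the
stacked residual vector, used here as the inner trainer of the genetic
optimizer's fitness function.  It is written in-house because the
accept/reject trace (each accepted step must strictly reduce the sum of
squared errors) is part of this module's contract.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .network import (
    NetworkConfig,
    NetworkWeights,
    activate_deriv,
    flatten_weights,
    forward,
    init_weights,
    total_error,
    unflatten_weights,
)


class TrainingDivergedError(RuntimeError):
    """Training produced a non-finite error; carries the history so far."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


@dataclasses.dataclass(frozen=True)
class FlatAreaConfig:
    """Flat-area detection and gradient-factor boost settings.

    A flat area is declared when the per-epoch error change |ΔE| drops
    below ``grad_tol`` while the largest output residual still exceeds
    ``residual_tol``; the gradient factor is then set to
    ``lambda_boost`` until |ΔE| recovers.
    """

    enabled: bool = False
    grad_tol: float = 1e-6
    residual_tol: float = 0.1
    lambda_boost: float = 4.0

    def __post_init__(self) -> None:
        if self.lambda_boost <= 1.0:
            raise ValueError("lambda_boost must exceed 1")


@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the improved gradient-descent trainer.

    Parameters
    ----------
    eta0
        Initial learning efficiency η.
    alpha
        Momentum coefficient α in (0, 1); 0 disables momentum.
    beta
        Learning-efficiency decrease factor β < 1 applied on a rejected
        (error-increasing) pass.
    theta_up
        Learning-efficiency increase factor θ > 1 applied on an accepted
        pass.
    adaptive_lr
        Enable the accept/reject η schedule; when off, η stays at eta0
        and every step stands.
    max_epochs, goal_error
        Stopping rules: epoch budget, and a total-error target below
        which training halts early.
    """

    eta0: float = 0.1
    alpha: float = 0.9
    beta: float = 0.7
    theta_up: float = 1.05
    adaptive_lr: bool = True
    max_epochs: int = 200
    goal_error: float = 1e-6
    flat_area: FlatAreaConfig = dataclasses.field(default_factory=FlatAreaConfig)

    def __post_init__(self) -> None:
        if self.eta0 <= 0:
            raise ValueError("eta0 must be positive")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.theta_up <= 1.0:
            raise ValueError("theta_up must exceed 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.goal_error < 0:
            raise ValueError("goal_error must be >= 0")


@dataclasses.dataclass
class TrainingState:
    """Mutable per-run state of the gradient-descent trainer."""

    eta_t: float
    prev_delta: np.ndarray
    epoch: int = 0
    error_history: list[float] = dataclasses.field(default_factory=list)
    lambda_current: float = 1.0

    @classmethod
    def fresh(cls, tcfg: TrainingConfig, cfg: NetworkConfig) -> "TrainingState":
        return cls(
            eta_t=tcfg.eta0,
            prev_delta=np.zeros(cfg.n_params),
            lambda_current=cfg.lambda_factor,
        )


def gradient(
    w: NetworkWeights, cfg: NetworkConfig, X: np.ndarray, D: np.ndarray,
    lam: float | None = None,
) -> np.ndarray:
    """Gradient of the total squared error Σ_p Σ_k (d−o)² over a batch.

    Returned flat, in the (W, V, θ_h, θ_o) layout.  The gradient factor
    λ enters through the activation slope (see ``activate_deriv``).
    Thresholds are subtracted from the net input, so their partials
    carry a minus sign.
    """
    if lam is None:
        lam = cfg.lambda_factor
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    O, H, _ = forward(w, cfg, X, lam=lam)
    act = cfg.activation
    delta_out = 2.0 * (O - D) * activate_deriv(O, act, lam)  # dE/d(net_out)
    grad_V = delta_out.T @ H
    grad_theta_out = -delta_out.sum(axis=0)
    delta_hidden = (delta_out @ w.V) * activate_deriv(H, act, lam)
    grad_W = delta_hidden.T @ X
    grad_theta_hidden = -delta_hidden.sum(axis=0)
    return np.concatenate(
        [grad_W.ravel(), grad_V.ravel(), grad_theta_hidden, grad_theta_out]
    )


def momentum_update(
    grad: np.ndarray, prev_delta: np.ndarray, eta: float, alpha: float
) -> np.ndarray:
    """Weight-adjustment vector ΔW_t = −η·∇E + α·ΔW_{t−1}."""
    return -eta * grad + alpha * prev_delta


def backprop_step(
    w: NetworkWeights,
    cfg: NetworkConfig,
    tcfg: TrainingConfig,
    state: TrainingState,
    X: np.ndarray,
    D: np.ndarray,
) -> tuple[NetworkWeights, TrainingState]:
    """One full-batch momentum step; returns updated weights and state.

    The caller decides afterwards (via :func:`adapt_learning_rate`)
    whether the step stands or is rolled back.
    """
    g = gradient(w, cfg, X, D, lam=state.lambda_current)
    if not np.all(np.isfinite(g)):
        raise TrainingDivergedError(
            f"non-finite gradient at epoch {state.epoch}", list(state.error_history)
        )
    delta = momentum_update(g, state.prev_delta, state.eta_t, tcfg.alpha)
    new_vec = flatten_weights(w) + delta
    state.prev_delta = delta
    return unflatten_weights(new_vec, cfg), state


def adapt_learning_rate(
    state: TrainingState,
    total_error_now: float,
    total_error_prev: float,
    tcfg: TrainingConfig,
) -> tuple[TrainingState, bool]:
    """Accept or reject the last pass and reschedule η.

    If the total error increased, the pass is invalid: η shrinks by β,
    the momentum memory is cleared (the rejected adjustment must not
    echo into the next pass) and the caller restores the pre-step
    weights.  Otherwise η grows by θ and the step stands.  Returns the
    state and an ``accepted`` flag.
    """
    if total_error_now > total_error_prev:
        state.eta_t *= tcfg.beta
        state.prev_delta = np.zeros_like(state.prev_delta)
        return state, False
    state.eta_t *= tcfg.theta_up
    return state, True


def flat_area_adjust(
    state: TrainingState,
    delta_E: float,
    residuals: np.ndarray,
    tcfg: TrainingConfig,
) -> TrainingState:
    """Set or clear the gradient-factor boost.

    Enters the boosted regime (λ = lambda_boost) when |ΔE| ≈ 0 while
    some output residual d_k − o_k is still large; restores λ = 1 as
    soon as |ΔE| is appreciable again.  When both |ΔE| and the
    residuals are small the network has converged, not stalled, and λ
    stays at 1.
    """
    fa = tcfg.flat_area
    if abs(delta_E) < fa.grad_tol:
        if np.max(np.abs(residuals)) > fa.residual_tol:
            state.lambda_current = fa.lambda_boost
    else:
        state.lambda_current = 1.0
    return state


def train_gd(
    X: np.ndarray,
    D: np.ndarray,
    cfg: NetworkConfig,
    tcfg: TrainingConfig,
    init: NetworkWeights | None = None,
    seed: int | None = None,
) -> tuple[NetworkWeights, TrainingState]:
    """Train by improved full-batch gradient descent.

    ``X`` are normalized colour inputs (n, 3) and ``D`` the target
    recipes (n, 5).  Initial weights come either from ``init`` (the
    genetic-optimizer path) or from a seeded uniform draw.  Returns the
    best weights seen (lowest total error) and the final state with the
    per-epoch error history.  Deterministic given (init or seed).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    if init is None:
        if seed is None:
            raise ValueError("provide either init weights or a seed")
        w = init_weights(cfg, seed)
    else:
        w = init.copy()
    state = TrainingState.fresh(tcfg, cfg)

    err_prev = total_error(w, cfg, X, D, lam=state.lambda_current)
    if not np.isfinite(err_prev):
        raise TrainingDivergedError("non-finite initial error", [])
    resting_lam = cfg.lambda_factor
    # best-so-far is judged at the resting gradient factor so that model
    # quality is measured on one consistent metric across λ switches
    best_err = (
        err_prev if state.lambda_current == resting_lam
        else total_error(w, cfg, X, D, lam=resting_lam)
    )
    best_w = w.copy()
    err_last_accepted = err_prev

    for epoch in range(1, tcfg.max_epochs + 1):
        state.epoch = epoch
        if err_prev <= tcfg.goal_error:
            # goal already met; record and stop
            state.error_history.append(err_prev)
            break
        w_new, state = backprop_step(w, cfg, tcfg, state, X, D)
        err_new = total_error(w_new, cfg, X, D, lam=state.lambda_current)
        if not np.isfinite(err_new):
            raise TrainingDivergedError(
                f"total error diverged at epoch {epoch}", list(state.error_history)
            )
        if tcfg.adaptive_lr:
            state, accepted = adapt_learning_rate(state, err_new, err_prev, tcfg)
        else:
            accepted = True
        if accepted:
            w = w_new
            err_now = err_new
        else:
            err_now = err_prev  # weights stay; rejected step discarded

        # flat-area detection applies only to accepted moves: a rejected
        # step leaves the error unchanged by construction, which says
        # nothing about the slope of the error surface
        if tcfg.flat_area.enabled and accepted:
            O, _, _ = forward(w, cfg, X, lam=state.lambda_current)
            residuals = D - O
            lam_before = state.lambda_current
            state = flat_area_adjust(state, err_now - err_last_accepted, residuals, tcfg)
            if state.lambda_current != lam_before:
                # λ changed, so the error metric changed with it:
                # re-baseline before the next accept/reject comparison
                err_now = total_error(w, cfg, X, D, lam=state.lambda_current)
        if accepted:
            err_last_accepted = err_now

        err_prev = err_now
        state.error_history.append(err_now)
        if accepted:
            err_resting = (
                err_now if state.lambda_current == resting_lam
                else total_error(w, cfg, X, D, lam=resting_lam)
            )
            if err_resting < best_err:
                best_err, best_w = err_resting, w.copy()
        if err_now <= tcfg.goal_error:
            break

    # the model is used at the resting gradient factor
    state.lambda_current = cfg.lambda_factor
    return best_w, state


# ---------------------------------------------------------------------------
# Levenberg-Marquardt


@dataclasses.dataclass(frozen=True)
class LMConfig:
    """Damping schedule of the Levenberg-Marquardt trainer.

    Classic Marquardt scheme: μ starts at ``mu0``, is multiplied by
    ``mu_inc`` whenever a trial step fails to reduce the sum of squared
    errors and divided by ``mu_dec`` when it succeeds; the run stops on
    the iteration budget, a small gradient, or μ exceeding ``mu_max``.
    """

    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 10.0
    mu_max: float = 1e10
    max_iter: int = 100
    grad_tol: float = 1e-10


def residual_jacobian(
    w: NetworkWeights, cfg: NetworkConfig, X: np.ndarray, lam: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outputs and the Jacobian ∂o/∂params, stacked over the batch.

    Returns ``(O, H, J)`` with ``J`` of shape (P·n_out, n_params) in the
    flat (W, V, θ_h, θ_o) layout.  Feasible because colour-matching
    networks are small (113 parameters at h=12).
    """
    if lam is None:
        lam = cfg.lambda_factor
    X = np.atleast_2d(np.asarray(X, dtype=float))
    O, H, _ = forward(w, cfg, X, lam=lam)
    P, m, h, n = X.shape[0], cfg.n_out, cfg.n_hidden, cfg.n_in
    ap_o = activate_deriv(O, cfg.activation, lam)  # (P, m)
    ap_h = activate_deriv(H, cfg.activation, lam)  # (P, h)

    # chain through the hidden layer: s[p,k,j] = ap_o * V * ap_h
    s = np.einsum("pk,kj,pj->pkj", ap_o, w.V, ap_h)
    J_W = np.einsum("pkj,pi->pkji", s, X).reshape(P, m, h * n)
    J_th = -s  # ∂net_h/∂θ_h = −1
    J_V = np.einsum("pk,pj->pkj", ap_o, H)  # diagonal in k
    J_V_full = np.zeros((P, m, m, h))
    idx = np.arange(m)
    J_V_full[:, idx, idx, :] = J_V
    J_V_full = J_V_full.reshape(P, m, m * h)
    J_to = np.zeros((P, m, m))
    J_to[:, idx, idx] = -ap_o

    J = np.concatenate([J_W, J_V_full, J_th, J_to], axis=2).reshape(P * m, cfg.n_params)
    return O, H, J


def train_lm(
    X: np.ndarray,
    D: np.ndarray,
    cfg: NetworkConfig,
    init: NetworkWeights,
    lm: LMConfig | None = None,
) -> tuple[NetworkWeights, list[float]]:
    """Train by Levenberg-Marquardt (damped Gauss-Newton).

    Minimizes the sum of squared residuals r = d − o over all samples
    and outputs.  Each trial step solves (JᵀJ + μI)Δ = Jᵀr; a step is
    accepted only if it strictly reduces the SSE.  Returns the final
    weights and the SSE history over accepted states (strictly
    decreasing after the initial entry).
    """
    lm = lm or LMConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    w = init.copy()
    vec = flatten_weights(w)
    mu = lm.mu0
    O, _, J = residual_jacobian(w, cfg, X)
    r = (D - O).ravel()
    sse = float(r @ r)
    history = [sse]
    eye = np.eye(cfg.n_params)

    for _ in range(lm.max_iter):
        g = J.T @ r  # = −½ ∇SSE; small g means stationarity
        if np.max(np.abs(g)) < lm.grad_tol or sse == 0.0:
            break
        accepted = False
        while mu <= lm.mu_max:
            try:
                step = np.linalg.solve(J.T @ J + mu * eye, g)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError(
                    "singular Levenberg-Marquardt normal equations"
                ) from exc
            trial_vec = vec + step
            trial_w = unflatten_weights(trial_vec, cfg)
            O_t, _, J_t = residual_jacobian(trial_w, cfg, X)
            r_t = (D - O_t).ravel()
            sse_t = float(r_t @ r_t)
            if np.isfinite(sse_t) and sse_t < sse:
                vec, w, r, J, sse = trial_vec, trial_w, r_t, J_t, sse_t
                mu = max(mu / lm.mu_dec, 1e-20)
                history.append(sse)
                accepted = True
                break
            mu *= lm.mu_inc
        if not accepted:
            break  # damping exhausted: at (numerical) local minimum
    return w, history
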