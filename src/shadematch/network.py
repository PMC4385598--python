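"""Three-layer feed-forward network for colour-to-recipe prediction.

The network maps a normalized CIELAB triple through one hidden layer to
the five powder mass fractions.  Both layers use the same sigmoid-family
activation whose net input may be divided by a *gradient factor* λ ≥ 1:
flattening the activation this way pushes saturated neurons back toward
the responsive region and is used transiently during training to escape
flat areas of the error surface.

Parameters live in four blocks: the input-to-hidden weight matrix ``W``
(h × 3), the hidden-to-output weight matrix ``V`` (5 × h), and the two
threshold vectors.  A neuron's net input is the weighted sum of its
inputs *minus* its threshold.  The blocks flatten to a single real
vector (W row-major, then V row-major, then hidden thresholds, then
output thresholds), the layout shared with the genetic optimizer's
chromosomes.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np


class Activation(str, enum.Enum):
    LOGISTIC = "logistic"
    TANGENT = "tangent"
    #: identity activation; a test hook for closed-form comparisons,
    #: not part of the colour-matching configuration space
    LINEAR = "linear"


class ShapeMismatchError(ValueError):
    """Weight/parameter shapes are inconsistent with the configuration."""


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    """Structure and activation settings of the network.

    Parameters
    ----------
    n_hidden
        Hidden-layer width ``h``.
    activation
        Transfer function of both layers.
    lambda_factor
        Resting gradient factor λ ≥ 1 (1 leaves the activation
        unchanged; training may raise it transiently).
    """

    n_hidden: int
    n_in: int = 3
    n_out: int = 5
    activation: Activation = Activation.TANGENT
    lambda_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_in, self.n_hidden, self.n_out) < 1:
            raise ValueError("layer sizes must be >= 1")
        if self.lambda_factor < 1.0:
            raise ValueError("lambda_factor must be >= 1")
        object.__setattr__(self, "activation", Activation(self.activation))

    @property
    def n_params(self) -> int:
        """Total parameter count: n·h + h·m + h + m."""
        return (
            self.n_in * self.n_hidden
            + self.n_hidden * self.n_out
            + self.n_hidden
            + self.n_out
        )


@dataclasses.dataclass
class NetworkWeights:
    """The four parameter blocks of a three-layer network."""

    W: np.ndarray  # (h, n_in) input -> hidden
    V: np.ndarray  # (n_out, h) hidden -> output
    theta_hidden: np.ndarray  # (h,)
    theta_out: np.ndarray  # (n_out,)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.theta_hidden = np.asarray(self.theta_hidden, dtype=float)
        self.theta_out = np.asarray(self.theta_out, dtype=float)

    def validate(self, cfg: NetworkConfig) -> None:
        expected = {
            "W": (cfg.n_hidden, cfg.n_in),
            "V": (cfg.n_out, cfg.n_hidden),
            "theta_hidden": (cfg.n_hidden,),
            "theta_out": (cfg.n_out,),
        }
        for name, shape in expected.items():
            actual = getattr(self, name).shape
            if actual != shape:
                raise ShapeMismatchError(f"{name}: expected {shape}, got {actual}")
        for name in expected:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite entries")

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            self.W.copy(), self.V.copy(), self.theta_hidden.copy(), self.theta_out.copy()
        )


def flatten_weights(w: NetworkWeights) -> np.ndarray:
    """Concatenate the four blocks into one vector (W, V, θ_h, θ_o)."""
    return np.concatenate(
        [w.W.ravel(), w.V.ravel(), w.theta_hidden, w.theta_out]
    )


def unflatten_weights(vec: np.ndarray, cfg: NetworkConfig) -> NetworkWeights:
    """Inverse of :func:`flatten_weights`."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (cfg.n_params,):
        raise ShapeMismatchError(
            f"expected parameter vector of length {cfg.n_params}, got {vec.shape}"
        )
    h, n, m = cfg.n_hidden, cfg.n_in, cfg.n_out
    i = 0
    W = vec[i : i + h * n].reshape(h, n); i += h * n
    V = vec[i : i + m * h].reshape(m, h); i += m * h
    th = vec[i : i + h]; i += h
    to = vec[i : i + m]
    return NetworkWeights(W, V, th, to)


def init_weights(cfg: NetworkConfig, seed: int, scale: float = 0.5) -> NetworkWeights:
    """Random initial weights, uniform on [-scale, scale], seeded."""
    rng = np.random.default_rng(seed)
    return unflatten_weights(rng.uniform(-scale, scale, cfg.n_params), cfg)


def activate(net: np.ndarray, activation: Activation, lam: float = 1.0) -> np.ndarray:
    z = np.asarray(net, dtype=float) / lam
    if activation is Activation.LOGISTIC:
        # clip keeps exp() finite; the sigmoid saturates long before +-500
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))
    if activation is Activation.TANGENT:
        return np.tanh(z)
    return z


def activate_deriv(o: np.ndarray, activation: Activation, lam: float = 1.0) -> np.ndarray:
    """Activation derivative w.r.t. the net input, expressed via the output.

    The gradient factor divides the net input, so it also divides the
    slope: d/d(net) logistic(net/λ) = o(1-o)/λ, and likewise
    (1-o²)/λ for the hyperbolic tangent.
    """
    o = np.asarray(o, dtype=float)
    if activation is Activation.LOGISTIC:
        return o * (1.0 - o) / lam
    if activation is Activation.TANGENT:
        return (1.0 - o**2) / lam
    return np.full_like(o, 1.0 / lam)


def forward(
    w: NetworkWeights,
    cfg: NetworkConfig,
    x: np.ndarray,
    lam: float | None = None,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Propagate input(s) through the network.

    Accepts a single 3-vector or a batch with shape (n, 3).  Returns the
    output(s), the hidden activation(s) and the per-layer net inputs
    (needed by backpropagation).  ``lam`` overrides the configuration's
    resting gradient factor, which training uses while a flat-area
    boost is active.
    """
    if lam is None:
        lam = cfg.lambda_factor
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != cfg.n_in:
        raise ShapeMismatchError(f"expected {cfg.n_in} inputs, got {X.shape[1]}")
    w.validate(cfg)
    net_hidden = X @ w.W.T - w.theta_hidden
    hidden = activate(net_hidden, cfg.activation, lam)
    net_out = hidden @ w.V.T - w.theta_out
    out = activate(net_out, cfg.activation, lam)
    nets = {"hidden": net_hidden, "out": net_out}
    if single:
        return out[0], hidden[0], {k: v[0] for k, v in nets.items()}
    return out, hidden, nets


def sample_error(expected: np.ndarray, actual: np.ndarray) -> float:
    """Per-sample error E_p: the sum of squared componentwise differences."""
    expected = np.asarray(expected, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if expected.shape != actual.shape:
        raise ShapeMismatchError(
            f"expected/actual length mismatch: {expected.shape} vs {actual.shape}"
        )
    diff = expected - actual
    return float(diff @ diff)


def total_mse(errors, as_printed: bool = True) -> float:
    """Aggregate per-sample errors into the dataset-level MSE figure.

    With ``as_printed=True`` (default) this is the mean of the *squares*
    of the per-sample errors, (1/P)·Σ E_p² — note E_p is itself already
    a sum of squares, so the figure is fourth-order in the residuals.
    ``as_printed=False`` gives the conventional mean of E_p instead.
    Every report in this package states which variant it used.
    """
    errors = np.asarray(list(errors), dtype=float)
    if errors.size == 0:
        raise ValueError("need at least one per-sample error")
    if as_printed:
        return float(np.mean(errors**2))
    return float(np.mean(errors))


def batch_errors(
    w: NetworkWeights, cfg: NetworkConfig, X: np.ndarray, D: np.ndarray,
    lam: float | None = None,
) -> np.ndarray:
    """Vector of per-sample errors E_p over a normalized batch."""
    O, _, _ = forward(w, cfg, X, lam=lam)
    diff = np.atleast_2d(D) - np.atleast_2d(O)
    return np.sum(diff**2, axis=1)


def total_error(
    w: NetworkWeights, cfg: NetworkConfig, X: np.ndarray, D: np.ndarray,
    lam: float | None = None,
) -> float:
    """Total squared error Σ_p E_p over a batch (the training objective)."""
    return float(np.sum(batch_errors(w, cfg, X, D, lam=lam)))
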