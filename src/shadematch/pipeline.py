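"""End-to-end model fitting: normalization, training profiles, prediction.

Two named training profiles cover the experimental configurations the
package is built around:

* ``bp-improved`` — random initial weights, tangent-sigmoid activation,
  momentum plus adaptive learning efficiency.  The baseline improved
  backpropagation run.
* ``gabp-paper`` — identical training, but the initial weights and
  thresholds are found by the genetic algorithm and the flat-area
  gradient factor is enabled.  The GA+BP run.

Both profiles use the tangent-sigmoid activation, the transfer function
of the underlying experiments; the gradient-factor mechanics work for
either sigmoid, and keeping the activation fixed across profiles makes
GA initialization the only treatment difference (plus the flat-area
guard) when the two are compared.

The normalizer's target interval follows the activation: inputs map to
[−1, 1] for the tangent sigmoid and [0.1, 0.9] for the logistic, which
keeps them clear of the saturation asymptotes.  Recipe outputs are left
in raw mass-fraction units (they already lie in [0, 0.40], comfortably
inside both activations' output ranges), so predictions are directly
comparable to laboratory recipe tables.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import Dataset, Normalizer, fit_normalizer
from .ga import GAConfig, GenerationLog, evolve
from .network import (
    Activation,
    NetworkConfig,
    NetworkWeights,
    batch_errors,
    forward,
    total_mse,
)
from .training import FlatAreaConfig, TrainingConfig, TrainingState, train_gd

from .data import RECIPE_TOTAL

PROFILE_BP = "bp-improved"
PROFILE_GABP = "gabp-paper"
PROFILES = (PROFILE_BP, PROFILE_GABP)

#: normalization target interval per activation
NORM_INTERVAL = {
    Activation.TANGENT: (-1.0, 1.0),
    Activation.LOGISTIC: (0.1, 0.9),
    Activation.LINEAR: (-1.0, 1.0),
}


def profile_activation(profile: str) -> Activation:
    if profile in (PROFILE_BP, PROFILE_GABP):
        return Activation.TANGENT
    raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")


def gabp_ga_config() -> GAConfig:
    """The genetic-search settings of the ``gabp-paper`` profile.

    Fitness is the network error after a few Levenberg-Marquardt
    iterations, so chromosomes are selected for where training *takes*
    them rather than for their untrained error; this is what makes the
    selected initial weights reliably trainable.
    """
    return GAConfig(
        fitness_mode="trained_error", inner_trainer="lm_k_iters", inner_k=5
    )


def profile_training_config(profile: str, base: TrainingConfig | None = None) -> TrainingConfig:
    """Expand a profile name into a fully explicit training config."""
    tcfg = base or TrainingConfig()
    if profile == PROFILE_BP:
        return dataclasses.replace(
            tcfg, adaptive_lr=True,
            flat_area=dataclasses.replace(tcfg.flat_area, enabled=False),
        )
    if profile == PROFILE_GABP:
        return dataclasses.replace(
            tcfg, adaptive_lr=True,
            flat_area=dataclasses.replace(tcfg.flat_area, enabled=True),
        )
    raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")


@dataclasses.dataclass
class FittedModel:
    """A trained network bundled with everything needed to use it."""

    cfg: NetworkConfig
    weights: NetworkWeights
    normalizer: Normalizer
    profile: str
    seed: int
    metric_as_printed: bool = True
    ga_log: list[GenerationLog] | None = None
    training_state: TrainingState | None = None

    def predict(self, lab: np.ndarray, clip_simplex: bool = False) -> np.ndarray:
        """Predict powder mass fractions for CIELAB input(s).

        Raw network outputs by default (they need not sum to 0.40, just
        as raw laboratory predictions do not).  With
        ``clip_simplex=True`` outputs are clipped at zero and rescaled
        to sum to exactly 0.40.
        """
        x = self.normalizer.apply(np.asarray(lab, dtype=float))
        out, _, _ = forward(self.weights, self.cfg, x)
        if clip_simplex:
            out = np.clip(out, 0.0, None)
            total = out.sum(axis=-1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                out = np.where(total > 0, out * RECIPE_TOTAL / total, RECIPE_TOTAL / 5)
        return out


@dataclasses.dataclass(frozen=True)
class EvaluationResult:
    """Per-sample and aggregate errors of a model on a dataset."""

    per_sample: np.ndarray  # E_p for each record
    mse_as_printed: float   # mean of E_p²
    mse_mean_ep: float      # conventional mean of E_p


def fit_model(
    train: Dataset,
    profile: str = PROFILE_BP,
    n_hidden: int = 12,
    seed: int = 0,
    tcfg: TrainingConfig | None = None,
    gacfg: GAConfig | None = None,
) -> FittedModel:
    """Fit a colour-to-recipe model on a training dataset.

    The normalizer is fitted on ``train`` itself; callers doing a
    train/test study should pass only the training split here.  For
    the GA profile the genetic search runs first (seeded from ``seed``)
    and its best individual initializes gradient training.
    """
    if len(train) == 0:
        raise ValueError("training dataset is empty")
    activation = profile_activation(profile)
    cfg = NetworkConfig(n_hidden=n_hidden, activation=activation)
    tcfg = profile_training_config(profile, tcfg)
    lo, hi = NORM_INTERVAL[activation]
    normalizer = fit_normalizer(train, lo, hi)
    X = normalizer.apply(train.lab)
    D = train.recipe

    ga_log = None
    if profile == PROFILE_GABP:
        if gacfg is None:
            gacfg = gabp_ga_config()
        gacfg = dataclasses.replace(gacfg, seed=seed)
        init, ga_log = evolve(X, D, cfg, gacfg)
        weights, state = train_gd(X, D, cfg, tcfg, init=init)
    else:
        weights, state = train_gd(X, D, cfg, tcfg, seed=seed)

    return FittedModel(
        cfg=cfg,
        weights=weights,
        normalizer=normalizer,
        profile=profile,
        seed=seed,
        ga_log=ga_log,
        training_state=state,
    )


def evaluate_model(model: FittedModel, data: Dataset) -> EvaluationResult:
    """Per-sample errors E_p and both aggregate MSE variants."""
    X = model.normalizer.apply(data.lab)
    errs = batch_errors(model.weights, model.cfg, X, data.recipe)
    return EvaluationResult(
        per_sample=errs,
        mse_as_printed=total_mse(errs, as_printed=True),
        mse_mean_ep=total_mse(errs, as_printed=False),
    )
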