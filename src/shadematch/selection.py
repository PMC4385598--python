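"""Hidden-layer sizing and the BP vs GA+BP comparison harness.

Hidden-layer width has no closed-form answer for three-layer networks;
the common estimate h = √(n + m) + a with an integer a ∈ [1, 10] gives
a candidate range (4–13 for a 3-input, 5-output network), and the width
is then chosen by trial and error: train several independently seeded
networks at each candidate width, under otherwise identical settings,
and keep the width with the smallest mean test error.

The comparison harness runs matched batteries of baseline improved-BP
trainings and GA-initialized trainings on the same train/test split and
reports per-trial test errors with their means and variances, which is
the evidence format used to argue that GA initialization lowers both
the error and its run-to-run spread.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .data import Dataset, split_dataset
from .ga import GAConfig
from .pipeline import PROFILE_BP, PROFILE_GABP, evaluate_model, fit_model
from .training import TrainingConfig, TrainingDivergedError
from .utils import round_half_up, spawn_seeds


@dataclasses.dataclass(frozen=True)
class HiddenSizeRange:
    """Candidate hidden-layer widths h = round(√(n+m) + a), a ∈ [a_min, a_max]."""

    n: int
    m: int
    a_min: int
    a_max: int
    h_min: int
    h_max: int

    def widths(self) -> range:
        return range(self.h_min, self.h_max + 1)


def hidden_range(n: int, m: int, a_min: int = 1, a_max: int = 10) -> HiddenSizeRange:
    """Hidden-width bounds from the √(n+m)+a estimate.

    Rounds half up to the nearest integer at both ends.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    if not 1 <= a_min <= a_max <= 10:
        raise ValueError("need 1 <= a_min <= a_max <= 10")
    root = math.sqrt(n + m)
    return HiddenSizeRange(
        n=n, m=m, a_min=a_min, a_max=a_max,
        h_min=round_half_up(root + a_min),
        h_max=round_half_up(root + a_max),
    )


@dataclasses.dataclass
class TrialResult:
    """Repeated test errors for one hidden-layer width."""

    h: int
    errors: list[float]
    diverged: int = 0  # repetitions that failed and were scored worst-case

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.errors))

    @property
    def std_error(self) -> float:
        return float(np.std(self.errors, ddof=1)) if len(self.errors) > 1 else 0.0


def select_hidden_nodes(
    d: Dataset,
    hrange: HiddenSizeRange,
    reps: int = 20,
    seed: int = 0,
    profile: str = PROFILE_BP,
    tcfg: TrainingConfig | None = None,
    train_fraction: float = 0.75,
) -> tuple[int, list[TrialResult]]:
    """Pick the hidden-layer width by seeded trial and error.

    For every width in the candidate range, ``reps`` networks are
    trained from independent seeds with otherwise identical settings
    on a common train/test split, and the test error (mean of squared
    per-sample errors) is recorded.  Returns the width with the lowest
    mean error — ties broken toward the smaller, cheaper width — plus
    the full per-width results.  A diverging repetition is scored with
    the worst finite error observed so far (flagged on its
    TrialResult) rather than aborting the survey.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    widths = list(hrange.widths())
    split_seed, *train_seeds = spawn_seeds(seed, 1 + len(widths) * reps)
    train, test = split_dataset(d, train_fraction, split_seed)

    trials: list[TrialResult] = []
    worst_seen = 0.0
    k = 0
    for h in widths:
        errors: list[float] = []
        diverged = 0
        for _ in range(reps):
            s = train_seeds[k]; k += 1
            try:
                model = fit_model(train, profile=profile, n_hidden=h, seed=s, tcfg=tcfg)
                e = evaluate_model(model, test).mse_as_printed
                worst_seen = max(worst_seen, e)
                errors.append(e)
            except TrainingDivergedError:
                diverged += 1
                errors.append(math.inf)
        trials.append(TrialResult(h=h, errors=errors, diverged=diverged))
    # replace divergence sentinels by the worst finite error observed
    for t in trials:
        t.errors = [worst_seen if math.isinf(e) else e for e in t.errors]

    best = min(trials, key=lambda t: (t.mean_error, t.h))
    return best.h, trials


@dataclasses.dataclass
class ComparisonReport:
    """Matched BP and GA+BP trial errors with summary statistics.

    Errors are test-set values of the mean-of-squared-E_p metric.
    Variances are sample variances (ddof=1).
    """

    bp_errors: np.ndarray
    gabp_errors: np.ndarray
    n_train: int
    n_test: int
    metric: str = "mean of squared per-sample errors"

    @property
    def bp_mean(self) -> float:
        return float(np.mean(self.bp_errors))

    @property
    def gabp_mean(self) -> float:
        return float(np.mean(self.gabp_errors))

    @property
    def bp_var(self) -> float:
        return float(np.var(self.bp_errors, ddof=1))

    @property
    def gabp_var(self) -> float:
        return float(np.var(self.gabp_errors, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        n = len(self.bp_errors)
        return pd.DataFrame(
            {
                "trial": np.arange(1, n + 1),
                "bp_mse": self.bp_errors,
                "gabp_mse": self.gabp_errors,
            }
        )

    def summary(self) -> dict:
        return {
            "n_trials": int(len(self.bp_errors)),
            "n_train": self.n_train,
            "n_test": self.n_test,
            "metric": self.metric,
            "bp_mean": self.bp_mean,
            "bp_var": self.bp_var,
            "gabp_mean": self.gabp_mean,
            "gabp_var": self.gabp_var,
        }


def compare_bp_gabp(
    d: Dataset,
    n_trials: int = 10,
    seed: int = 0,
    n_hidden: int = 12,
    tcfg: TrainingConfig | None = None,
    gacfg: GAConfig | None = None,
    train_fraction: float = 0.75,
) -> ComparisonReport:
    """Run matched batteries of BP and GA+BP trainings.

    One 75/25 split (derived from ``seed``) is shared by both arms and
    all trials; each trial then uses its own derived seed for weight
    initialization (BP arm) or the genetic search (GA+BP arm).  Pure
    function of (data, configs, seed).
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    split_seed, *trial_seeds = spawn_seeds(seed, 1 + 2 * n_trials)
    train, test = split_dataset(d, train_fraction, split_seed)

    bp_errors = []
    gabp_errors = []
    for i in range(n_trials):
        bp_model = fit_model(
            train, profile=PROFILE_BP, n_hidden=n_hidden,
            seed=trial_seeds[2 * i], tcfg=tcfg,
        )
        bp_errors.append(evaluate_model(bp_model, test).mse_as_printed)
        gabp_model = fit_model(
            train, profile=PROFILE_GABP, n_hidden=n_hidden,
            seed=trial_seeds[2 * i + 1], tcfg=tcfg, gacfg=gacfg,
        )
        gabp_errors.append(evaluate_model(gabp_model, test).mse_as_printed)

    return ComparisonReport(
        bp_errors=np.array(bp_errors),
        gabp_errors=np.array(gabp_errors),
        n_train=len(train),
        n_test=len(test),
    )
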