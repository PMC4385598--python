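"""Datasets of porcelain colour-recipe records.

A record pairs a CIELAB colour measurement (L*, a*, b*) of a fired
ceramic specimen with the mass fractions of the five VITA VMK95 dentin
porcelain powders (A1, A4, B4, C4, D4) that were mixed to produce it.
Recipes in the study design are non-negative multiples of 0.08 that sum
to 0.40.

Datasets travel as plain CSV with columns ``L,a,b,A1,A4,B4,C4,D4``.
This module provides reading/writing, seeded train/test splitting and
per-dimension min-max normalization of the colour inputs.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .utils import round_half_up

LAB_COLUMNS: tuple[str, ...] = ("L", "a", "b")
POWDER_COLUMNS: tuple[str, ...] = ("A1", "A4", "B4", "C4", "D4")
ALL_COLUMNS: tuple[str, ...] = LAB_COLUMNS + POWDER_COLUMNS

#: grid step and total mass fraction of a study-design recipe
RECIPE_STEP = 0.08
RECIPE_TOTAL = 0.40


class DatasetSchemaError(ValueError):
    """A dataset file is missing a required column."""


class DatasetParseError(ValueError):
    """A dataset file contains a non-numeric cell."""


class DegenerateDimensionError(ValueError):
    """An input dimension is constant and cannot be normalized."""


@dataclasses.dataclass(frozen=True)
class Sample:
    """One colour-recipe record.

    Attributes
    ----------
    lab
        CIELAB coordinates ``(L*, a*, b*)``.
    recipe
        Mass fractions of the powders ``(A1, A4, B4, C4, D4)``.
    """

    lab: np.ndarray
    recipe: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lab", np.asarray(self.lab, dtype=float))
        object.__setattr__(self, "recipe", np.asarray(self.recipe, dtype=float))
        if self.lab.shape != (3,):
            raise ValueError(f"lab must have shape (3,), got {self.lab.shape}")
        if self.recipe.shape != (5,):
            raise ValueError(f"recipe must have shape (5,), got {self.recipe.shape}")
        if np.any(self.recipe < -1e-12):
            raise ValueError("recipe mass fractions must be non-negative")


def recipe_on_grid(recipe: np.ndarray, atol: float = 1e-9) -> bool:
    """True if every entry is a multiple of 0.08 and the sum is 0.40."""
    recipe = np.asarray(recipe, dtype=float)
    units = recipe / RECIPE_STEP
    return bool(
        np.all(np.abs(units - np.round(units)) < atol / RECIPE_STEP)
        and abs(recipe.sum() - RECIPE_TOTAL) < atol
        and np.all(recipe >= -atol)
    )


class Dataset:
    """An ordered collection of colour-recipe records.

    Stored column-wise as two float arrays: ``lab`` with shape (n, 3)
    and ``recipe`` with shape (n, 5).
    """

    def __init__(self, lab: np.ndarray, recipe: np.ndarray, name: str = "dataset"):
        lab = np.atleast_2d(np.asarray(lab, dtype=float))
        recipe = np.atleast_2d(np.asarray(recipe, dtype=float))
        if lab.ndim != 2 or lab.shape[1] != 3:
            raise ValueError(f"lab must have shape (n, 3), got {lab.shape}")
        if recipe.ndim != 2 or recipe.shape[1] != 5:
            raise ValueError(f"recipe must have shape (n, 5), got {recipe.shape}")
        if lab.shape[0] != recipe.shape[0]:
            raise ValueError("lab and recipe row counts differ")
        self.lab = lab
        self.recipe = recipe
        self.name = name

    @classmethod
    def from_samples(cls, samples: Sequence[Sample], name: str = "dataset") -> "Dataset":
        if samples:
            lab = np.stack([s.lab for s in samples])
            recipe = np.stack([s.recipe for s in samples])
        else:
            lab = np.empty((0, 3))
            recipe = np.empty((0, 5))
        return cls(lab, recipe, name=name)

    def __len__(self) -> int:
        return self.lab.shape[0]

    def __getitem__(self, i: int) -> Sample:
        return Sample(self.lab[i], self.recipe[i])

    @property
    def samples(self) -> list[Sample]:
        return [self[i] for i in range(len(self))]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(np.hstack([self.lab, self.recipe]), columns=list(ALL_COLUMNS))
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.lab.shape == other.lab.shape
            and np.array_equal(self.lab, other.lab)
            and np.array_equal(self.recipe, other.recipe)
        )


def read_dataset(
    path: str | Path,
    columns: Sequence[str] | None = None,
    name: str | None = None,
) -> Dataset:
    """Read a colour-recipe CSV.

    Parameters
    ----------
    path
        CSV file.  By default the file must carry a header row naming at
        least the eight standard columns ``L,a,b,A1,A4,B4,C4,D4``.
    columns
        Column order for headerless files.  When given, the file is read
        without a header and these names are assigned positionally; the
        eight standard names must all appear.

    Raises
    ------
    DatasetSchemaError
        If a required column is missing (the message names it).
    DatasetParseError
        If a cell is not numeric (the message gives the 1-based data
        row index).
    """
    path = Path(path)
    if columns is None:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    else:
        df = pd.read_csv(path, header=None, names=list(columns), dtype=str,
                         skipinitialspace=True)
    missing = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetSchemaError(f"missing column(s): {', '.join(missing)}")
    df = df[list(ALL_COLUMNS)]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(ALL_COLUMNS):
        # unicode minus occurs in copy-pasted colorimetric tables
        cleaned = df[col].astype(str).str.replace("−", "-", regex=False)
        parsed = pd.to_numeric(cleaned, errors="coerce")
        bad = np.nonzero(parsed.isna().to_numpy())[0]
        if bad.size:
            raise DatasetParseError(
                f"non-numeric value {df[col].iloc[bad[0]]!r} in column {col!r} "
                f"at data row {bad[0] + 1}"
            )
        values[:, j] = parsed.to_numpy(dtype=float)
    return Dataset(values[:, :3], values[:, 3:], name=name or path.stem)


def write_dataset(d: Dataset, path: str | Path) -> None:
    """Write a dataset as standard CSV (header ``L,a,b,A1,A4,B4,C4,D4``)."""
    d.to_frame().to_csv(path, index=False, lineterminator="\n")


def split_dataset(
    d: Dataset, train_fraction: float, seed: int
) -> tuple[Dataset, Dataset]:
    """Randomly partition a dataset into train and test subsets.

    The train size is ``round(train_fraction * n)`` (half up).  The
    shuffle is driven entirely by ``seed``: the same seed always yields
    the same split.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = round_half_up(train_fraction * n)
    perm = np.random.default_rng(seed).permutation(n)
    tr, te = perm[:n_train], perm[n_train:]
    return (
        Dataset(d.lab[tr], d.recipe[tr], name=f"{d.name}-train"),
        Dataset(d.lab[te], d.recipe[te], name=f"{d.name}-test"),
    )


@dataclasses.dataclass(frozen=True)
class Normalizer:
    """Per-dimension affine min-max map for the three colour inputs.

    ``apply`` sends the fitted minimum of each dimension to ``lo`` and
    the fitted maximum to ``hi``; ``invert`` is its exact inverse.
    """

    mins: np.ndarray
    maxs: np.ndarray
    lo: float = -1.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mins", np.asarray(self.mins, dtype=float))
        object.__setattr__(self, "maxs", np.asarray(self.maxs, dtype=float))
        if np.any(self.maxs <= self.mins):
            raise DegenerateDimensionError(
                "every dimension needs max > min; got "
                f"mins={self.mins}, maxs={self.maxs}"
            )
        if not self.hi > self.lo:
            raise ValueError("hi must exceed lo")

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        scale = (self.hi - self.lo) / (self.maxs - self.mins)
        return (x - self.mins) * scale + self.lo

    def invert(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        scale = (self.maxs - self.mins) / (self.hi - self.lo)
        return (y - self.lo) * scale + self.mins

    def to_dict(self) -> dict:
        return {
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "lo": self.lo,
            "hi": self.hi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(np.asarray(d["mins"]), np.asarray(d["maxs"]), d["lo"], d["hi"])


def fit_normalizer(d: Dataset, lo: float = -1.0, hi: float = 1.0) -> Normalizer:
    """Fit a min-max normalizer to a dataset's colour inputs.

    Fit this on the *training* split only, then apply it to both splits,
    so that no test information leaks into the preprocessing.

    Raises
    ------
    DegenerateDimensionError
        If an input dimension is constant over the dataset.
    """
    if len(d) == 0:
        raise ValueError("cannot fit a normalizer to an empty dataset")
    mins = d.lab.min(axis=0)
    maxs = d.lab.max(axis=0)
    return Normalizer(mins, maxs, lo, hi)
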