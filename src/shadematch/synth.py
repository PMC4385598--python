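"""Synthetic porcelain-mixing datasets.

The laboratory database that motivates this package — fired ceramic
specimens mixed from five VITA VMK95 dentin powders and measured with a
dental spectrophotometer — is not publicly available.  This module
generates datasets with the same statistical structure so that every
algorithm in the package can be exercised and tested end to end.

Recipes follow the study design: each of the five powder mass fractions
is a non-negative multiple of 0.08 g-per-g and the five fractions sum
to 0.40.  There are exactly C(9, 4) = 126 such compositions and the
generator samples them uniformly.

Colour is produced by a smooth surrogate mixing model

    lab(r) = offset + Bᵀ r + curvature · g(r) + ε,

where the rows of the 5 × 3 basis ``B`` are the per-unit-mass CIELAB
contributions of the powders (so a pure 0.40 recipe of powder j yields
``offset + 0.40 · B_j``), ``g`` is a fixed quadratic interaction term
standing in for the non-additive optics of pigment mixing, and ε is
i.i.d. Gaussian measurement noise per channel.  This is a surrogate,
not a radiative-transfer model: it reproduces the range, smoothness and
noise scale of real specimen colorimetry, nothing more.

The default basis is chosen so the pure-powder colours span
L* ≈ 63–73.5, a* ≈ −1.5–1.9, b* ≈ 14–22, bracketing the colour ranges
observed in fired dentin-porcelain specimens.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path

import numpy as np

from .data import RECIPE_STEP, RECIPE_TOTAL, Dataset, write_dataset

#: CIELAB colour of each pure (0.40 mass-fraction) powder: A1, A4, B4, C4, D4.
#: A1 is the lightest, least chromatic shade; the *4 shades are darker
#: and yellower, C4 the darkest.
PURE_POWDER_LAB = np.array(
    [
        [73.5, -1.5, 14.0],  # A1
        [66.0, 1.5, 21.0],   # A4
        [68.0, 0.5, 22.0],   # B4
        [63.0, 1.9, 18.0],   # C4
        [66.5, 0.8, 19.5],   # D4
    ]
)

DEFAULT_BASIS = PURE_POWDER_LAB / RECIPE_TOTAL
DEFAULT_OFFSET = np.zeros(3)

#: directions of the quadratic interaction g(r); fixed constants so the
#: generator is fully reproducible from its seed alone
_INTERACTION_U = np.array(
    [
        [1.0, -1.0, 0.5, -0.5, 0.0],   # L* channel
        [0.0, 1.0, -1.0, 0.5, -0.5],   # a* channel
        [0.5, 0.0, 1.0, -1.0, 0.5],    # b* channel
    ]
)


@dataclasses.dataclass(frozen=True)
class SyntheticModelParams:
    """Parameters of the surrogate powder-to-colour forward model.

    Parameters
    ----------
    basis
        5 × 3 matrix; row j is powder j's CIELAB contribution per unit
        mass fraction.
    offset
        Baseline colour added to every mixture.  The default is zero:
        with recipes constrained to a constant total mass, a nonzero
        offset is not separable from the basis anyway, so the default
        model carries all colour in the basis.
    curvature
        Strength of the smooth quadratic interaction g(r) emulating
        non-additive optical mixing (CIELAB units at full scale).
    noise_sd
        Per-channel measurement noise standard deviation, CIELAB units.
        The default 0.3 is a typical intra-instrument repeatability
        scale for dental spectrophotometers.
    seed
        Master seed for recipe sampling and noise.
    """

    basis: np.ndarray = dataclasses.field(default_factory=lambda: DEFAULT_BASIS.copy())
    offset: np.ndarray = dataclasses.field(default_factory=lambda: DEFAULT_OFFSET.copy())
    curvature: float = 5.0
    noise_sd: np.ndarray = dataclasses.field(default_factory=lambda: np.full(3, 0.3))
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "basis", np.asarray(self.basis, dtype=float))
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float))
        noise = np.asarray(self.noise_sd, dtype=float)
        if noise.ndim == 0:
            noise = np.full(3, float(noise))
        object.__setattr__(self, "noise_sd", noise)
        if self.basis.shape != (5, 3):
            raise ValueError("basis must have shape (5, 3)")
        if self.offset.shape != (3,):
            raise ValueError("offset must have shape (3,)")
        if self.noise_sd.shape != (3,):
            raise ValueError("noise_sd must have shape (3,) or be scalar")
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be non-negative")
        if self.curvature < 0:
            raise ValueError("curvature must be non-negative")

    def to_dict(self) -> dict:
        return {
            "basis": self.basis.tolist(),
            "offset": self.offset.tolist(),
            "curvature": self.curvature,
            "noise_sd": self.noise_sd.tolist(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticModelParams":
        return cls(
            basis=np.asarray(d["basis"]),
            offset=np.asarray(d["offset"]),
            curvature=d["curvature"],
            noise_sd=np.asarray(d["noise_sd"]),
            seed=d["seed"],
        )


def enumerate_recipes() -> np.ndarray:
    """All 126 grid recipes: weak compositions of five 0.08 units.

    Returns an array of shape (126, 5) in lexicographic order of the
    unit counts.
    """
    total_units = int(round(RECIPE_TOTAL / RECIPE_STEP))
    rows = []
    for c in itertools.product(range(total_units + 1), repeat=5):
        if sum(c) == total_units:
            rows.append(c)
    return np.array(rows, dtype=float) * RECIPE_STEP


_RECIPE_GRID = enumerate_recipes()


def sample_recipe(rng: np.random.Generator) -> np.ndarray:
    """Draw one recipe uniformly from the 126-member composition grid."""
    return _RECIPE_GRID[rng.integers(len(_RECIPE_GRID))].copy()


def interaction_term(r: np.ndarray) -> np.ndarray:
    """Fixed smooth quadratic interaction g(r), one value per channel."""
    r = np.asarray(r, dtype=float)
    proj = _INTERACTION_U @ r.T  # (3,) or (3, n)
    return (proj**2).T


def recipe_to_lab(
    r: np.ndarray,
    p: SyntheticModelParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Forward model: recipe → CIELAB, optionally with measurement noise.

    With ``rng=None`` the mapping is noiseless and deterministic.
    """
    r = np.asarray(r, dtype=float)
    lab = p.offset + r @ p.basis + p.curvature * interaction_term(r)
    if rng is not None:
        lab = lab + rng.normal(0.0, p.noise_sd, size=lab.shape)
    return lab


def generate_dataset(n: int, p: SyntheticModelParams, name: str = "synthetic") -> Dataset:
    """Generate ``n`` independent colour-recipe records.

    Recipes are uniform on the composition grid; colours come from the
    surrogate forward model plus noise.  Deterministic given
    ``p.seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(p.seed)
    recipes = np.stack([sample_recipe(rng) for _ in range(n)])
    labs = recipe_to_lab(recipes, p, rng=rng)
    return Dataset(labs, recipes, name=name)


#: seed of the packaged reference dataset — a fixed study artifact, so
#: that "the 119-specimen synthetic database" means the same rows in
#: every analysis that refers to it
REFERENCE_SEED = 42
REFERENCE_N = 119


def reference_dataset() -> Dataset:
    """The packaged 119-record synthetic specimen database.

    Generated with the default forward model and a fixed seed; plays
    the role of the laboratory specimen database in every packaged
    experiment and in the worked examples.
    """
    return generate_dataset(
        REFERENCE_N, SyntheticModelParams(seed=REFERENCE_SEED), name="reference"
    )


def write_dataset_with_sidecar(d: Dataset, p: SyntheticModelParams, path: str | Path) -> None:
    """Write the CSV plus a JSON sidecar recording the generator params."""
    path = Path(path)
    write_dataset(d, path)
    sidecar = path.with_suffix(path.suffix + ".params.json")
    sidecar.write_text(json.dumps(p.to_dict(), indent=2) + "\n")


def fit_linear_basis(d: Dataset, offset: np.ndarray | None = None) -> np.ndarray:
    """Least-squares estimate of the mixing basis from a dataset.

    Fits ``lab − offset ≈ Bᵀ r`` by ordinary least squares and returns
    the estimated 5 × 3 basis.  Because every recipe sums to the same
    total mass, an unknown offset is collinear with the basis and
    cannot be estimated jointly; it must be supplied (default: zero,
    matching the default generator).  On noiseless, curvature-free data
    this recovers the generating basis exactly up to round-off.
    """
    offset = np.zeros(3) if offset is None else np.asarray(offset, dtype=float)
    B, *_ = np.linalg.lstsq(d.recipe, d.lab - offset, rcond=None)
    return B
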