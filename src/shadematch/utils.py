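"""Small shared helpers."""

from __future__ import annotations

import numpy as np

_SEED_MOD = 2**31


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds from a single master seed.

    Uses :class:`numpy.random.SeedSequence` so that children are
    statistically independent and the derivation is stable across
    platforms.  Returned seeds fit in a signed 32-bit integer.
    """
    ss = np.random.SeedSequence(seed)
    return [int(s) % _SEED_MOD for s in ss.generate_state(n, dtype=np.uint64)]


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (0.5 -> 1)."""
    return int(np.floor(x + 0.5))
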