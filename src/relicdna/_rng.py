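"""Seed handling.

Every stochastic operation in the package accepts either an integer seed,
``None`` (fresh entropy), or an existing :class:`numpy.random.Generator`.
No function touches numpy's global random state.
"""

from __future__ import annotations

import numpy as np

SeedLike = "int | None | np.random.Generator"


def as_generator(seed) -> np.random.Generator:
    """Return a Generator: pass one through, or build one from a seed."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seed(seed) -> int:
    """Derive a single integer seed (< 2**31) from any seed-like input."""
    return int(as_generator(seed).integers(0, 2**31))


def round_half_away(x: float) -> int:
    """Round half away from zero (non-negative inputs): 2.5 -> 3."""
    return int(np.floor(x + 0.5))
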