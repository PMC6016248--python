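"""Regional species pools and finite communities.

A regional pool is a lognormal species abundance distribution (SAD) over S
species, held as normalized per-species sampling weights.  The lognormal
scale parameter sigma controls evenness: larger sigma concentrates weight
on fewer species (less even), sigma = 0 is perfectly even.  Communities are
integer abundance vectors drawn from a pool; zero-count species are kept so
all communities from one pool stay alignable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_generator
from .exceptions import InvalidParameterError

__all__ = [
    "RegionalPool",
    "Community",
    "build_lognormal_pool",
    "sample_community",
    "pool_to_table",
    "pool_from_table",
    "community_to_table",
    "community_from_table",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class RegionalPool:
    """Lognormal SAD over ``n_species`` taxa, stored as sampling weights.

    Attributes
    ----------
    relative_abundances : ndarray of float
        Per-species weights, non-negative, summing to 1 within 1e-9.
    sigma : float
        Lognormal scale parameter used to draw the weights (>= 0).
    seed : int or None
        Seed the weights were drawn with, for provenance.
    """

    relative_abundances: np.ndarray
    sigma: float
    seed: int | None = None

    def __post_init__(self):
        w = np.asarray(self.relative_abundances, dtype=float)
        object.__setattr__(self, "relative_abundances", w)
        if w.ndim != 1 or w.size < 1:
            raise InvalidParameterError("pool needs a 1-d weight vector with >= 1 species")
        if np.any(w < 0):
            raise InvalidParameterError("pool weights must be non-negative")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise InvalidParameterError(f"pool weights must sum to 1, got {w.sum()!r}")
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")

    @property
    def n_species(self) -> int:
        return self.relative_abundances.size


@dataclass(frozen=True)
class Community:
    """Integer abundance vector aligned to a regional pool's species order."""

    counts: np.ndarray = field()

    def __post_init__(self):
        c = np.asarray(self.counts)
        if not np.issubdtype(c.dtype, np.integer):
            rounded = np.rint(c)
            if not np.allclose(c, rounded):
                raise InvalidParameterError("community counts must be integral")
            c = rounded.astype(np.int64)
        else:
            c = c.astype(np.int64)
        if c.ndim != 1:
            raise InvalidParameterError("community counts must be a 1-d vector")
        if np.any(c < 0):
            raise InvalidParameterError("community counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def size(self) -> int:
        """Total number of individuals N."""
        return int(self.counts.sum())

    @property
    def n_species(self) -> int:
        return self.counts.size


def build_lognormal_pool(n_species: int, sigma: float, seed=None) -> RegionalPool:
    """Draw a lognormal regional pool of ``n_species`` taxa.

    Weights are independent lognormal(0, sigma) draws normalized to sum to 1.
    The location parameter is fixed at 0: normalization makes it irrelevant,
    leaving sigma as the single evenness knob.  sigma = 0 gives a perfectly
    even pool.
    """
    if n_species < 1:
        raise InvalidParameterError(f"n_species must be >= 1, got {n_species}")
    if sigma < 0:
        raise InvalidParameterError(f"sigma must be >= 0, got {sigma}")
    rng = as_generator(seed)
    draws = rng.lognormal(mean=0.0, sigma=sigma, size=n_species)
    weights = draws / draws.sum()
    return RegionalPool(weights, float(sigma), seed if isinstance(seed, int) else None)


def sample_community(pool: RegionalPool, n_individuals: int, seed=None) -> Community:
    """One multinomial draw of ``n_individuals`` with the pool's weights."""
    if n_individuals < 0:
        raise InvalidParameterError(f"n_individuals must be >= 0, got {n_individuals}")
    rng = as_generator(seed)
    counts = rng.multinomial(n_individuals, pool.relative_abundances)
    return Community(counts)


# -- tab-delimited serialization ---------------------------------------------

def pool_to_table(pool: RegionalPool, path) -> None:
    pd.DataFrame(
        {"species_id": np.arange(pool.n_species), "weight": pool.relative_abundances}
    ).to_csv(path, sep="\t", index=False)


def pool_from_table(path, sigma: float = float("nan")) -> RegionalPool:
    """Read a pool; ``sigma`` is provenance only and may be left NaN."""
    df = pd.read_csv(path, sep="\t")
    w = df["weight"].to_numpy(dtype=float)
    return RegionalPool(w / w.sum(), sigma)


def community_to_table(community: Community, path) -> None:
    pd.DataFrame(
        {"species_id": np.arange(community.n_species), "count": community.counts}
    ).to_csv(path, sep="\t", index=False)


def community_from_table(path) -> Community:
    df = pd.read_csv(path, sep="\t")
    return Community(df["count"].to_numpy())
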