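"""Sampling-based bias model.

Mixes an intact community with a relic community at a controlled relic
fraction, rarefies the total, and quantifies estimation bias as richness
ratios (total / intact at matched rarefaction depth) and Bray-Curtis
dissimilarity.  Bias requires both a large relic fraction and a relic SAD
distinct from the intact SAD: a more even relic pool (smaller sigma)
inflates richness, a less even one (larger sigma) deflates it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import distance as _ssd

from ._rng import as_generator, child_seed, round_half_away
from .communities import Community, build_lognormal_pool, sample_community
from .exceptions import (
    InsufficientIndividualsError,
    InvalidParameterError,
    UndefinedRatioError,
)

__all__ = [
    "MixedSample",
    "mix_communities",
    "rarefy",
    "observed_richness",
    "richness_ratio",
    "bray_curtis",
    "run_sampling_sweep",
]


@dataclass(frozen=True)
class MixedSample:
    """Intact + relic subsamples combined into one total community."""

    intact_part: Community
    relic_part: Community
    target_relic_fraction: float

    @property
    def total(self) -> Community:
        return Community(self.intact_part.counts + self.relic_part.counts)

    @property
    def realized_relic_fraction(self) -> float:
        total = self.intact_part.size + self.relic_part.size
        return self.relic_part.size / total if total else 0.0


def _subsample_counts(counts: np.ndarray, n: int, rng) -> np.ndarray:
    """Draw n individuals without replacement (multivariate hypergeometric)."""
    return rng.multivariate_hypergeometric(counts, n)


def mix_communities(
    intact: Community,
    relic: Community,
    relic_fraction: float,
    total_size: int,
    seed=None,
) -> MixedSample:
    """Mix without-replacement draws from intact and relic at a target fraction.

    Part sizes are ``round((1 - f) * total_size)`` and ``round(f * total_size)``
    with half-away-from-zero rounding, so the realized fraction can differ from
    the target by up to 1/total_size and is recorded on the result.
    """
    if not 0.0 <= relic_fraction <= 1.0:
        raise InvalidParameterError(f"relic_fraction must be in [0, 1], got {relic_fraction}")
    if total_size < 0:
        raise InvalidParameterError("total_size must be >= 0")
    n_relic = round_half_away(relic_fraction * total_size)
    n_intact = round_half_away((1.0 - relic_fraction) * total_size)
    if n_intact > intact.size:
        raise InsufficientIndividualsError(
            f"need {n_intact} intact individuals, community has {intact.size}"
        )
    if n_relic > relic.size:
        raise InsufficientIndividualsError(
            f"need {n_relic} relic individuals, community has {relic.size}"
        )
    rng = as_generator(seed)
    intact_part = Community(_subsample_counts(intact.counts, n_intact, rng))
    relic_part = Community(_subsample_counts(relic.counts, n_relic, rng))
    return MixedSample(intact_part, relic_part, float(relic_fraction))


def rarefy(community: Community, depth: int, seed=None) -> Community:
    """Subsample exactly ``depth`` individuals without replacement."""
    if depth < 0:
        raise InvalidParameterError("depth must be >= 0")
    if depth > community.size:
        raise InsufficientIndividualsError(
            f"rarefaction depth {depth} exceeds community size {community.size}"
        )
    rng = as_generator(seed)
    return Community(_subsample_counts(community.counts, depth, rng))


def observed_richness(community: Community) -> int:
    """Number of species with count > 0."""
    return int(np.count_nonzero(community.counts))


def richness_ratio(total: Community, intact: Community, depth: int, seed=None) -> float:
    """Richness of rarefied total over richness of rarefied intact.

    Both pools are rarefied to ``depth`` with the same derived seed, so
    identical inputs give a ratio of exactly 1.
    """
    s = child_seed(seed)
    rich_total = observed_richness(rarefy(total, depth, s))
    rich_intact = observed_richness(rarefy(intact, depth, s))
    if rich_intact == 0:
        raise UndefinedRatioError("intact pool has zero rarefied richness")
    return rich_total / rich_intact


def bray_curtis(a: Community, b: Community) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum a + sum b), in [0, 1]."""
    if a.size == 0 and b.size == 0:
        raise UndefinedRatioError("Bray-Curtis undefined for two empty communities")
    return float(_ssd.braycurtis(a.counts, b.counts))


def run_sampling_sweep(
    n_species: int = 10_000,
    intact_size: int = 1_000_000,
    sigma_intact: float = 0.98,
    sigma_relic_values=(0.25, 0.98, 1.8),
    relic_fractions=(0.01, 0.2, 0.5, 0.8, 0.96),
    depth: int = 10_000,
    n_replicates: int = 10,
    seed=None,
) -> pd.DataFrame:
    """Full factorial sweep over relic-SAD evenness and mixing fraction.

    For each (sigma_relic, fraction, replicate): draw intact and relic
    communities of ``intact_size`` individuals from their pools (the intact
    pool is reused as the relic pool when sigma_relic == sigma_intact), mix
    at the fraction into a total of ``intact_size`` individuals, rarefy total
    and intact to ``depth``, and record the richness ratio and the
    Bray-Curtis dissimilarity of the rarefied total vs intact pools.
    """
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    rng = as_generator(seed)
    intact_pool = build_lognormal_pool(n_species, sigma_intact, child_seed(rng))
    rows = []
    for sigma_relic in sigma_relic_values:
        if sigma_relic == sigma_intact:
            relic_pool = intact_pool
        else:
            relic_pool = build_lognormal_pool(n_species, sigma_relic, child_seed(rng))
        for fraction in relic_fractions:
            for rep in range(n_replicates):
                intact = sample_community(intact_pool, intact_size, rng)
                relic = sample_community(relic_pool, intact_size, rng)
                mix = mix_communities(intact, relic, fraction, intact_size, rng)
                rare_seed = child_seed(rng)
                total_r = rarefy(mix.total, depth, rare_seed)
                intact_r = rarefy(intact, depth, rare_seed)
                rich_i = observed_richness(intact_r)
                if rich_i == 0:
                    raise UndefinedRatioError("intact pool has zero rarefied richness")
                rows.append(
                    {
                        "sigma_relic": sigma_relic,
                        "relic_fraction": fraction,
                        "replicate": rep,
                        "realized_relic_fraction": mix.realized_relic_fraction,
                        "richness_ratio": observed_richness(total_r) / rich_i,
                        "bray_curtis_total_vs_intact": bray_curtis(total_r, intact_r),
                    }
                )
    return pd.DataFrame(rows)
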