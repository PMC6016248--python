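"""Stochastic process model of intact and relic DNA pools.

Each time step applies, in order: immigration (j individuals from the
regional pool into the intact community), birth (round(I*r) with-replacement
parent draws duplicated into the intact community), death (round(I*m) + j
individuals moved without replacement from intact to relic), and degradation
(round(R*d) + j individuals removed from the relic pool).  The "+j" terms
offset immigration so the intact community size stays near its initial
value when b = m.

At steady state the relic pool size satisfies R = m * I / d, so a target
relic proportion p = R / (R + I) is reached by setting d = m/p - m.

Degradation scenarios
---------------------
neutral
    every relic sequence equally likely to degrade.
protection
    per-species susceptibilities w_s ~ beta(0.7, 0.7), drawn once per run;
    removal probability per individual proportional to w_s.  Low-
    susceptibility species accumulate, making the relic SAD less even and
    biasing richness of the total pool downward.
hotspot
    removal probability per individual proportional to its species'
    abundance (species-level rate ~ n_s^2), mimicking density-dependent
    degradation hot spots.  Abundant species degrade faster, the relic SAD
    becomes more even, and richness of the total pool is biased upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import as_generator, child_seed, round_half_away
from .communities import Community, RegionalPool, build_lognormal_pool, sample_community
from .exceptions import (
    InsufficientIndividualsError,
    InvalidParameterError,
    UndefinedRatioError,
)
from .sampling_model import bray_curtis, observed_richness, rarefy

__all__ = [
    "ScenarioSpec",
    "ProcessParams",
    "SimulationRecord",
    "decay_rate_for_target",
    "equilibrium_relic_size",
    "residence_time",
    "assign_protection_susceptibilities",
    "step_immigration",
    "step_birth",
    "step_death",
    "step_degradation",
    "run_process_simulation",
    "bias_from_simulation",
]

SCENARIOS = ("neutral", "protection", "hotspot")


@dataclass(frozen=True)
class ScenarioSpec:
    """Degradation scenario: neutral, protection, or hotspot."""

    kind: str = "neutral"
    protection_alpha: float = 0.7
    protection_beta: float = 0.7
    susceptibilities: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in SCENARIOS:
            raise InvalidParameterError(f"scenario kind must be one of {SCENARIOS}")
        if self.kind == "protection":
            if self.protection_alpha <= 0 or self.protection_beta <= 0:
                raise InvalidParameterError("beta shape parameters must be > 0")
        if self.susceptibilities is not None:
            w = np.asarray(self.susceptibilities, dtype=float)
            if np.any((w < 0) | (w > 1)):
                raise InvalidParameterError("susceptibilities must lie in [0, 1]")
            object.__setattr__(self, "susceptibilities", w)


@dataclass(frozen=True)
class ProcessParams:
    """All rates, sizes and durations of one process-model run.

    Defaults are the model's reference configuration: a 4,000-species
    lognormal regional pool (sigma 0.98), intact community of 20,000
    individuals, immigration j = 2,000 per step, per-capita birth and
    mortality rates b = m = 0.1 per step.
    """

    n_species: int = 4_000
    initial_intact_size: int = 20_000
    immigration: int = 2_000
    birth_rate: float = 0.1
    mortality_rate: float = 0.1
    decay_rate: float = 0.1
    n_steps: int = 10_000
    sigma: float = 0.98
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    immigrant_death_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        for name in ("birth_rate", "mortality_rate", "immigrant_death_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        # d = m/p - m exceeds 1 for small target proportions (e.g. p = 0.05,
        # m = 0.1 gives d = 1.9); such rates just mean faster-than-one-step
        # pool turnover and are valid.
        if self.decay_rate < 0:
            raise InvalidParameterError(f"decay_rate must be >= 0, got {self.decay_rate}")
        if self.immigration < 0:
            raise InvalidParameterError("immigration must be >= 0")
        if self.n_steps < 1:
            raise InvalidParameterError("n_steps must be >= 1")
        if self.n_species < 1 or self.initial_intact_size < 0:
            raise InvalidParameterError("community sizes must be positive")


@dataclass(frozen=True)
class SimulationRecord:
    """Trajectories and final state of one run.

    ``realized_relic_proportion`` is R/(R+I) at the final step;
    ``tail_relic_proportion`` averages that quantity over the final 10% of
    steps, which is the better equilibrium estimate.
    """

    intact_trajectory: np.ndarray
    relic_trajectory: np.ndarray
    final_intact: Community
    final_relic: Community
    params: ProcessParams
    susceptibilities: np.ndarray | None = None

    @property
    def realized_relic_proportion(self) -> float:
        i, r = self.intact_trajectory[-1], self.relic_trajectory[-1]
        return r / (i + r) if (i + r) else 0.0

    @property
    def tail_relic_proportion(self) -> float:
        n_tail = max(1, self.params.n_steps // 10)
        i = self.intact_trajectory[-n_tail:]
        r = self.relic_trajectory[-n_tail:]
        return float(np.mean(r / (i + r)))

    @property
    def tail_relic_size(self) -> float:
        n_tail = max(1, self.params.n_steps // 10)
        return float(np.mean(self.relic_trajectory[-n_tail:]))


# -- closed-form relations ----------------------------------------------------

def decay_rate_for_target(mortality_rate: float, target_proportion: float) -> float:
    """Decay rate d = m/p - m giving equilibrium relic proportion p."""
    if not 0.0 < target_proportion <= 1.0:
        raise InvalidParameterError("target_proportion must be in (0, 1]")
    if mortality_rate <= 0:
        raise InvalidParameterError("mortality_rate must be > 0")
    return mortality_rate / target_proportion - mortality_rate


def equilibrium_relic_size(mortality_rate: float, intact_size: float, decay_rate: float) -> float:
    """Steady-state relic pool size R = m * I / d."""
    if decay_rate <= 0:
        raise UndefinedRatioError("equilibrium diverges for decay_rate <= 0")
    return mortality_rate * intact_size / decay_rate


def residence_time(relic_size: float, decay_rate: float) -> float:
    """Relic-pool residence quantity tau = R/d.

    Implemented exactly as stated; note the dimensional caveat that the
    conventional per-capita residence time would be 1/d.
    """
    if decay_rate <= 0:
        raise UndefinedRatioError("residence time diverges for decay_rate <= 0")
    return relic_size / decay_rate


def assign_protection_susceptibilities(
    n_species: int, alpha: float = 0.7, beta: float = 0.7, seed=None
) -> np.ndarray:
    """Per-species degradation susceptibilities ~ beta(alpha, beta).

    The default beta(0.7, 0.7) is U-shaped: most species are either well
    protected (w near 0) or fully exposed (w near 1).
    """
    if alpha <= 0 or beta <= 0:
        raise InvalidParameterError("beta shape parameters must be > 0")
    if n_species < 1:
        raise InvalidParameterError("n_species must be >= 1")
    return as_generator(seed).beta(alpha, beta, size=n_species)


# -- per-step updates ---------------------------------------------------------

def step_immigration(
    intact: Community,
    pool: RegionalPool,
    j: int,
    immigrant_death_fraction: float = 0.0,
    relic: Community | None = None,
    seed=None,
) -> tuple[Community, Community | None]:
    """Add j pool draws to intact; a binomial share may die straight into relic."""
    if j < 0:
        raise InvalidParameterError("j must be >= 0")
    rng = as_generator(seed)
    arrivals = rng.multinomial(j, pool.relative_abundances)
    if immigrant_death_fraction > 0:
        if relic is None:
            raise InvalidParameterError("relic community required when immigrants can die")
        dead = rng.binomial(arrivals, immigrant_death_fraction)
        return (
            Community(intact.counts + arrivals - dead),
            Community(relic.counts + dead),
        )
    return Community(intact.counts + arrivals), relic


def step_birth(
    intact: Community, birth_rate: float, seed=None, base_size: int | None = None
) -> Community:
    """Duplicate round(I*r) individuals chosen with replacement by abundance.

    ``base_size`` is the census size I the rate applies to; it defaults to
    the community's current size.  The driver passes the size at the start
    of the step so that births and deaths use the same base, which is what
    keeps the intact community stationary when b = m.
    """
    if base_size is None:
        base_size = intact.size
    n_births = round_half_away(base_size * birth_rate)
    if n_births == 0:
        return intact
    rng = as_generator(seed)
    births = rng.multinomial(n_births, intact.counts / intact.size)
    return Community(intact.counts + births)


def step_death(
    intact: Community,
    relic: Community,
    mortality_rate: float,
    j: int,
    seed=None,
    base_size: int | None = None,
) -> tuple[Community, Community]:
    """Move round(I*m) + j individuals without replacement from intact to relic.

    ``base_size`` as in :func:`step_birth`.
    """
    if base_size is None:
        base_size = intact.size
    n_deaths = round_half_away(base_size * mortality_rate) + j
    if n_deaths > intact.size:
        raise InsufficientIndividualsError(
            f"{n_deaths} deaths requested but intact community has {intact.size}"
        )
    rng = as_generator(seed)
    dead = rng.multivariate_hypergeometric(intact.counts, n_deaths)
    return Community(intact.counts - dead), Community(relic.counts + dead)


def _weighted_removal(counts: np.ndarray, weights: np.ndarray | None, n: int, rng) -> np.ndarray:
    """Remove n individuals, species probability ~ counts * weights.

    ``weights=None`` means hotspot: the weight is the (current) abundance
    itself, so species-level probability ~ counts**2, recomputed after each
    batch.  Draws exceeding a species' count are truncated and the remainder
    redrawn from the surviving capacity.
    """
    counts = counts.copy()
    remaining = n
    while remaining > 0:
        w = counts.astype(float) * (counts if weights is None else weights)
        total_w = w.sum()
        if total_w <= 0:
            # only zero-weight species remain: fall back to uniform removal
            w = counts.astype(float)
            total_w = w.sum()
        draw = rng.multinomial(remaining, w / total_w)
        draw = np.minimum(draw, counts)
        counts -= draw
        remaining -= int(draw.sum())
    return counts


def step_degradation(
    relic: Community,
    decay_rate: float,
    j: int,
    scenario: ScenarioSpec,
    seed=None,
    max_removals: int | None = None,
    base_size: int | None = None,
) -> Community:
    """Remove round(R*d) + j individuals under the scenario's weighting.

    ``base_size`` is the relic census size R the decay rate applies to
    (defaults to the current size; the driver passes the size at the start
    of the step, before the death inflow, so that at equilibrium the removal
    exactly balances the inflow and R settles at m*I/d).  ``max_removals``
    caps the request (used by the driver to survive the early transient at
    high decay rates, before the relic pool has grown to its equilibrium
    size); without it, over-requests raise.
    """
    if base_size is None:
        base_size = relic.size
    n_remove = round_half_away(base_size * decay_rate) + j
    if max_removals is not None:
        n_remove = min(n_remove, max_removals)
    if n_remove > relic.size:
        raise InsufficientIndividualsError(
            f"{n_remove} removals requested but relic pool has {relic.size}"
        )
    if n_remove == 0:
        return relic
    rng = as_generator(seed)
    if scenario.kind == "neutral":
        removed = rng.multivariate_hypergeometric(relic.counts, n_remove)
        return Community(relic.counts - removed)
    if scenario.kind == "protection":
        if scenario.susceptibilities is None:
            raise InvalidParameterError("protection scenario needs susceptibilities")
        return Community(_weighted_removal(relic.counts, scenario.susceptibilities, n_remove, rng))
    return Community(_weighted_removal(relic.counts, None, n_remove, rng))


# -- full simulation ----------------------------------------------------------

def run_process_simulation(params: ProcessParams) -> SimulationRecord:
    """Run the immigration -> birth -> death -> degradation loop.

    The intact community is initialized as a multinomial draw of
    ``initial_intact_size`` individuals from a fresh lognormal pool; the
    relic pool starts empty.  Degradation requests are capped at the current
    relic pool size (relevant only during the early transient at high decay
    rates).  Deterministic given ``params.seed``.
    """
    rng = as_generator(params.seed)
    pool = build_lognormal_pool(params.n_species, params.sigma, child_seed(rng))
    intact = sample_community(pool, params.initial_intact_size, rng)
    relic = Community(np.zeros(params.n_species, dtype=np.int64))

    scenario = params.scenario
    susceptibilities = scenario.susceptibilities
    if scenario.kind == "protection" and susceptibilities is None:
        susceptibilities = assign_protection_susceptibilities(
            params.n_species, scenario.protection_alpha, scenario.protection_beta, rng
        )
        scenario = replace(scenario, susceptibilities=susceptibilities)

    intact_sizes = np.empty(params.n_steps + 1, dtype=np.int64)
    relic_sizes = np.empty(params.n_steps + 1, dtype=np.int64)
    intact_sizes[0], relic_sizes[0] = intact.size, relic.size

    for t in range(1, params.n_steps + 1):
        # census sizes the per-capita rates refer to this step
        base = intact.size
        relic_base = relic.size
        intact, relic_opt = step_immigration(
            intact, pool, params.immigration, params.immigrant_death_fraction, relic, rng
        )
        relic = relic_opt if relic_opt is not None else relic
        intact = step_birth(intact, params.birth_rate, rng, base_size=base)
        if round_half_away(base * params.mortality_rate) + params.immigration >= intact.size:
            raise InsufficientIndividualsError(
                f"step {t}: death would empty the intact community (size {intact.size})"
            )
        intact, relic = step_death(
            intact, relic, params.mortality_rate, params.immigration, rng, base_size=base
        )
        relic = step_degradation(
            relic, params.decay_rate, params.immigration, scenario, rng,
            max_removals=relic.size, base_size=relic_base,
        )
        intact_sizes[t], relic_sizes[t] = intact.size, relic.size

    return SimulationRecord(
        intact_trajectory=intact_sizes,
        relic_trajectory=relic_sizes,
        final_intact=intact,
        final_relic=relic,
        params=params,
        susceptibilities=susceptibilities,
    )


def bias_from_simulation(
    record: SimulationRecord, depth: int | None = None, seed=None
) -> dict[str, float]:
    """Richness ratio and Bray-Curtis of final total (intact+relic) vs intact.

    Depth defaults to min(final intact size, final total size, 10,000),
    mirroring the sampling model's rarefaction depth.
    """
    total = Community(record.final_intact.counts + record.final_relic.counts)
    intact = record.final_intact
    if depth is None:
        depth = min(intact.size, total.size, 10_000)
    rare_seed = child_seed(seed)
    total_r = rarefy(total, depth, rare_seed)
    intact_r = rarefy(intact, depth, rare_seed)
    rich_intact = observed_richness(intact_r)
    if rich_intact == 0:
        raise UndefinedRatioError("intact pool has zero rarefied richness")
    return {
        "richness_ratio": observed_richness(total_r) / rich_intact,
        "bray_curtis": bray_curtis(total_r, intact_r),
        "depth": depth,
    }
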