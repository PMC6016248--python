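"""Synthetic paired-sample generator.

Emulates a paired DNase design: each site's sample is split in half, one
half DNase-treated (leaving intact DNA only), the other left untreated
(intact + relic).  Per site the generator draws an intact and a relic
community from lognormal pools, mixes them at a controlled relic fraction,
emulates sequencing as multinomial read draws, and emulates qPCR as a
linear copies-per-individual readout with multiplicative lognormal noise.
Ground truth (realized relic fractions, pool weights) is returned so
downstream bias statistics can be validated against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import as_generator, child_seed
from .bias_metrics import PairedSample
from .communities import Community, build_lognormal_pool, sample_community
from .exceptions import InvalidParameterError
from .io import (
    read_paired_samples,
    write_otu_table,
    write_sample_sheet,
)
from .sampling_model import mix_communities

__all__ = ["FixtureSpec", "generate_paired_samples", "write_fixture", "read_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Configuration for one synthetic paired-sample set.

    ``relic_fraction`` may be a single value or a per-site sequence.
    ``copy_noise_cv`` is the coefficient of variation of the multiplicative
    lognormal qPCR noise (default 0.16, a realistic assay CV); 0 gives a
    noiseless assay whose relic-proportion estimate equals the realized
    mixing fraction exactly.

    ``relic_source`` selects where a site's relic community comes from:
    ``"regional"`` draws it from the relic regional pool (independent of the
    site's standing community — mixing such relic DNA homogenizes sites);
    ``"site"`` resamples the site's own intact community, emulating relic
    DNA produced by local neutral death, the no-bias null in which total and
    intact samples are compositionally exchangeable.
    """

    n_sites: int = 6
    n_otus: int = 1_000
    sigma_intact: float = 0.98
    sigma_relic: float = 0.98
    relic_fraction: float | tuple = 0.33
    sequencing_depth: int = 50_000
    community_size: int = 100_000
    copy_number_scale: float = 1.0
    copy_noise_cv: float = 0.16
    relic_source: str = "regional"
    ecosystem: str = "synthetic"
    seed: int | None = None

    def __post_init__(self):
        if self.relic_source not in ("regional", "site"):
            raise InvalidParameterError("relic_source must be 'regional' or 'site'")
        if self.n_sites < 1 or self.n_otus < 1:
            raise InvalidParameterError("n_sites and n_otus must be >= 1")
        if self.sequencing_depth < 1 or self.community_size < 1:
            raise InvalidParameterError("sequencing_depth and community_size must be >= 1")
        if self.copy_noise_cv < 0:
            raise InvalidParameterError("copy_noise_cv must be >= 0")
        fractions = self.site_fractions()
        if np.any((fractions < 0) | (fractions >= 1)):
            raise InvalidParameterError("relic fractions must be in [0, 1)")

    def site_fractions(self) -> np.ndarray:
        f = np.atleast_1d(np.asarray(self.relic_fraction, dtype=float))
        if f.size == 1:
            f = np.repeat(f, self.n_sites)
        if f.size != self.n_sites:
            raise InvalidParameterError(
                f"relic_fraction must be scalar or length {self.n_sites}"
            )
        return f


def _lognormal_noise(rng, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal factors with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=size)


def generate_paired_samples(spec: FixtureSpec) -> tuple[list[PairedSample], pd.DataFrame]:
    """Generate one synthetic paired-sample set plus its ground-truth table.

    The relic pool is the intact pool itself when ``sigma_relic ==
    sigma_intact`` (the no-bias null); otherwise a distinct lognormal pool.
    Returns (samples, truth) where ``truth`` has one row per site with the
    realized relic fraction and the noiseless copy numbers.
    """
    rng = as_generator(spec.seed)
    intact_pool = build_lognormal_pool(spec.n_otus, spec.sigma_intact, child_seed(rng))
    if spec.sigma_relic == spec.sigma_intact:
        relic_pool = intact_pool
    else:
        relic_pool = build_lognormal_pool(spec.n_otus, spec.sigma_relic, child_seed(rng))

    fractions = spec.site_fractions()
    noise = _lognormal_noise(rng, spec.copy_noise_cv, 2 * spec.n_sites)
    samples, truth_rows = [], []
    for i in range(spec.n_sites):
        intact = sample_community(intact_pool, spec.community_size, rng)
        if spec.relic_source == "site":
            relic = Community(
                rng.multinomial(spec.community_size, intact.counts / intact.size)
            )
        else:
            relic = sample_community(relic_pool, spec.community_size, rng)
        mix = mix_communities(intact, relic, fractions[i], spec.community_size, rng)
        total = mix.total
        f_real = mix.realized_relic_fraction

        intact_reads = rng.multinomial(spec.sequencing_depth, intact.counts / intact.size)
        total_reads = rng.multinomial(spec.sequencing_depth, total.counts / total.size)

        intact_copies_true = spec.copy_number_scale * (1.0 - f_real) * total.size
        total_copies_true = spec.copy_number_scale * total.size
        sample = PairedSample(
            sample_id=f"site{i + 1}",
            ecosystem=spec.ecosystem,
            intact_counts=intact_reads,
            total_counts=total_reads,
            intact_copies=intact_copies_true * noise[2 * i],
            total_copies=total_copies_true * noise[2 * i + 1],
        )
        samples.append(sample)
        truth_rows.append(
            {
                "sample_id": sample.sample_id,
                "target_relic_fraction": fractions[i],
                "realized_relic_fraction": f_real,
                "intact_copies_true": intact_copies_true,
                "total_copies_true": total_copies_true,
            }
        )
    return samples, pd.DataFrame(truth_rows)


def write_fixture(samples: list[PairedSample], otu_table_path, sample_sheet_path) -> None:
    """Write samples as an OTU table + sample sheet in the package dialect."""
    table = pd.DataFrame(
        {
            **{f"{s.sample_id}_intact": s.intact_counts for s in samples},
            **{f"{s.sample_id}_total": s.total_counts for s in samples},
        },
        index=[f"otu{k + 1}" for k in range(samples[0].intact_counts.size)],
    )
    sheet = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "ecosystem": [s.ecosystem for s in samples],
            "intact_column": [f"{s.sample_id}_intact" for s in samples],
            "total_column": [f"{s.sample_id}_total" for s in samples],
            "intact_copies": [s.intact_copies for s in samples],
            "total_copies": [s.total_copies for s in samples],
        }
    )
    write_otu_table(table, otu_table_path)
    write_sample_sheet(sheet, sample_sheet_path)


def read_fixture(otu_table_path, sample_sheet_path) -> list[PairedSample]:
    """Inverse of :func:`write_fixture` (delegates to the io module)."""
    return read_paired_samples(otu_table_path, sample_sheet_path)
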