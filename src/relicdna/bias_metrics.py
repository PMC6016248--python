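"""Bias statistics for paired intact/total DNA samples.

Given a DNase-treated ("intact") and untreated ("total") OTU profile per
site, plus qPCR 16S copy numbers for each half, these statistics quantify
how much the relic (extracellular) DNA in the untreated half shifts
diversity estimates:

* relic proportion 1 - intact/total from the copy numbers,
* resampled alpha diversity (richness, Simpson's evenness) and per-sample
  total/intact diversity ratios with propagated SEM,
* two-sample Kolmogorov-Smirnov comparison of the two SADs,
* centroid-distance ratios on a PCoA ordination, a paired beta-dispersion
  measure (> 1: relic DNA inflates beta-diversity; < 1: homogenizes it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sstats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from ._rng import as_generator
from .communities import Community
from .exceptions import (
    InsufficientIndividualsError,
    InvalidMatrixError,
    InvalidParameterError,
    UndefinedRatioError,
)
from .sampling_model import rarefy

__all__ = [
    "PairedSample",
    "DiversityEstimate",
    "CentroidDistanceResult",
    "relic_proportion",
    "simpson_evenness",
    "resampled_alpha",
    "diversity_ratio",
    "ks_compare_sads",
    "pcoa",
    "centroid_distance_ratio",
]

METRICS = ("richness", "simpson_evenness")


@dataclass(frozen=True)
class PairedSample:
    """One site's intact and total OTU vectors plus qPCR copy numbers."""

    sample_id: str
    ecosystem: str
    intact_counts: np.ndarray
    total_counts: np.ndarray
    intact_copies: float
    total_copies: float

    def __post_init__(self):
        intact = np.asarray(self.intact_counts, dtype=np.int64)
        total = np.asarray(self.total_counts, dtype=np.int64)
        if intact.shape != total.shape:
            raise InvalidParameterError("intact and total OTU vectors must align")
        if np.any(intact < 0) or np.any(total < 0):
            raise InvalidParameterError("OTU counts must be non-negative")
        if self.intact_copies < 0 or self.total_copies < 0:
            raise InvalidParameterError("copy numbers must be >= 0")
        object.__setattr__(self, "intact_counts", intact)
        object.__setattr__(self, "total_counts", total)


@dataclass(frozen=True)
class DiversityEstimate:
    metric: str
    mean: float
    sem: float
    depth: int
    n_resamples: int


@dataclass(frozen=True)
class CentroidDistanceResult:
    """Per-sample distances to the total-pool centroid and their ratios."""

    sample_ids: list
    total_distances: np.ndarray
    intact_distances: np.ndarray
    ratios: np.ndarray  # NaN where the intact distance is 0
    group: str

    @property
    def mean_ratio(self) -> float:
        return float(np.nanmean(self.ratios))


def relic_proportion(intact_copies: float, total_copies: float) -> float:
    """Estimated relic fraction 1 - intact/total, clipped to [0, 1].

    qPCR noise can put the intact estimate above the total; such samples are
    reported as proportion 0 rather than negative.
    """
    if total_copies <= 0:
        raise UndefinedRatioError("total copy number must be > 0")
    return float(np.clip(1.0 - intact_copies / total_copies, 0.0, 1.0))


def simpson_evenness(counts) -> float:
    """Simpson's evenness: inverse-Simpson concentration over observed richness.

    E = (1 / sum p_i^2) / S_obs with p over species present; E = 1 for a
    perfectly even community.
    """
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise InvalidParameterError("evenness undefined for an empty vector")
    p = c / total
    s_obs = int(np.count_nonzero(c))
    return float((1.0 / np.sum(p**2)) / s_obs)


def _metric_value(counts: np.ndarray, metric: str) -> float:
    if metric == "richness":
        return float(np.count_nonzero(counts))
    if metric == "simpson_evenness":
        return simpson_evenness(counts)
    raise InvalidParameterError(f"metric must be one of {METRICS}, got {metric!r}")


def resampled_alpha(
    counts, metric: str, depth: int, n_resamples: int = 1000, seed=None
) -> DiversityEstimate:
    """Mean and SEM of an alpha metric over repeated rarefactions at ``depth``."""
    if metric not in METRICS:
        raise InvalidParameterError(f"metric must be one of {METRICS}, got {metric!r}")
    if n_resamples < 1:
        raise InvalidParameterError("n_resamples must be >= 1")
    community = Community(np.asarray(counts))
    if depth > community.size:
        raise InsufficientIndividualsError(
            f"depth {depth} exceeds read total {community.size}"
        )
    rng = as_generator(seed)
    values = np.array(
        [_metric_value(rarefy(community, depth, rng).counts, metric) for _ in range(n_resamples)]
    )
    sem = float(values.std(ddof=1) / np.sqrt(n_resamples)) if n_resamples > 1 else 0.0
    return DiversityEstimate(metric, float(values.mean()), sem, depth, n_resamples)


def diversity_ratio(
    total, intact, metric: str, depth: int, n_resamples: int = 1000, seed=None
) -> tuple[float, float]:
    """Total/intact ratio of resampled alpha means, with delta-method SEM."""
    rng = as_generator(seed)
    est_total = resampled_alpha(total, metric, depth, n_resamples, rng)
    est_intact = resampled_alpha(intact, metric, depth, n_resamples, rng)
    if est_intact.mean == 0:
        raise UndefinedRatioError("intact mean metric is zero")
    ratio = est_total.mean / est_intact.mean
    rel_var = (est_total.sem / est_total.mean) ** 2 if est_total.mean else 0.0
    rel_var += (est_intact.sem / est_intact.mean) ** 2
    return ratio, abs(ratio) * float(np.sqrt(rel_var))


def ks_compare_sads(total, intact) -> tuple[float, float]:
    """Two-sample KS test on the nonzero relative abundances of each pool.

    Taxa absent from a pool contribute nothing to that pool's SAD.  Returns
    (D, p).
    """
    t = np.asarray(total, dtype=float)
    i = np.asarray(intact, dtype=float)
    t_nz = t[t > 0]
    i_nz = i[i > 0]
    if t_nz.size == 0 or i_nz.size == 0:
        raise InvalidParameterError("each pool needs at least one OTU with positive count")
    res = _sstats.ks_2samp(t_nz / t_nz.sum(), i_nz / i_nz.sum())
    return float(res.statistic), float(res.pvalue)


def _validate_distance_matrix(dm: np.ndarray) -> np.ndarray:
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise InvalidMatrixError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-10):
        raise InvalidMatrixError("distance matrix must be symmetric")
    if np.any(np.diag(dm) != 0):
        raise InvalidMatrixError("distance matrix diagonal must be zero")
    if np.any(dm < 0):
        raise InvalidMatrixError("distances must be non-negative")
    return dm


def pcoa(distance_matrix) -> np.ndarray:
    """Classical metric multidimensional scaling (principal coordinates).

    Returns an (n_samples, k) coordinate array; axes with non-positive
    eigenvalues are dropped (with a warning when the negative part is
    non-trivial, i.e. the matrix is not Euclidean-embeddable).
    """
    dm = _validate_distance_matrix(distance_matrix)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues itself
        ord_res = _skbio_pcoa(DistanceMatrix(dm), method="eigh")
    eigvals = ord_res.eigvals.to_numpy()
    if eigvals.size and eigvals.min() < -1e-8 * max(eigvals.max(), 1.0):
        warnings.warn(
            "distance matrix is not Euclidean-embeddable; "
            "negative-eigenvalue axes dropped",
            stacklevel=2,
        )
    keep = eigvals > 1e-12 * max(eigvals.max(), 1.0) if eigvals.size else eigvals > 0
    coords = ord_res.samples.to_numpy()[:, keep]
    return coords


def _log_transform_relative(profiles: np.ndarray) -> np.ndarray:
    """log10 transform of relative abundances, shifted to be non-negative.

    Rows are samples.  With c the smallest nonzero relative abundance in the
    table, each entry x maps to log10((x + c) / c), a monotone transform of
    log10(x + c) that keeps Bray-Curtis well defined (all values >= 0,
    absences exactly 0).
    """
    rel = profiles / profiles.sum(axis=1, keepdims=True)
    nonzero = rel[rel > 0]
    if nonzero.size == 0:
        raise InvalidParameterError("all profiles are empty")
    c = nonzero.min()
    return np.log10((rel + c) / c)


def centroid_distance_ratio(
    samples: list[PairedSample],
    distance: str = "bray_curtis",
    distance_matrix=None,
    group: str | None = None,
) -> CentroidDistanceResult:
    """Paired beta-dispersion of total vs intact pools within one group.

    All 2n profiles (n totals then n intacts, in sample order) are ordinated
    together by PCoA; the centroid is the mean of the *total* samples'
    coordinates; each sample's ratio is its total profile's Euclidean
    distance to that centroid over its intact profile's distance.

    ``distance_matrix``, when given, must be 2n x 2n in that same order and
    overrides the built-in Bray-Curtis on log10-transformed relative
    abundances.  Samples whose intact distance is zero get a NaN ratio and
    are excluded from the mean.
    """
    if len(samples) < 3:
        raise InvalidParameterError("need at least 3 paired samples in a group")
    n = len(samples)
    if distance_matrix is not None:
        dm = _validate_distance_matrix(distance_matrix)
        if dm.shape[0] != 2 * n:
            raise InvalidMatrixError(f"expected a {2*n}x{2*n} matrix for {n} paired samples")
    elif distance == "bray_curtis":
        profiles = np.vstack(
            [s.total_counts for s in samples] + [s.intact_counts for s in samples]
        ).astype(float)
        transformed = _log_transform_relative(profiles)
        dm = squareform(pdist(transformed, metric="braycurtis"))
        dm = _validate_distance_matrix(np.nan_to_num(dm, nan=0.0))
    else:
        raise InvalidParameterError("distance must be 'bray_curtis' or give distance_matrix")

    coords = pcoa(dm)
    total_coords, intact_coords = coords[:n], coords[n:]
    centroid = total_coords.mean(axis=0)
    total_d = np.linalg.norm(total_coords - centroid, axis=1)
    intact_d = np.linalg.norm(intact_coords - centroid, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(intact_d > 0, total_d / intact_d, np.nan)
    return CentroidDistanceResult(
        sample_ids=[s.sample_id for s in samples],
        total_distances=total_d,
        intact_distances=intact_d,
        ratios=ratios,
        group=group if group is not None else (samples[0].ecosystem or ""),
    )
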