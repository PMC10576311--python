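"""Trajectory-level outlier detectors.

* **COT** — hierarchical clustering (Euclidean distance, complete linkage)
  cut into ``nc = max(2, floor(n/10))`` clusters.  Complete linkage favours
  compact clusters, so anomalous trajectories end up isolated in small
  ones; every subject in a cluster smaller than the average cluster size
  ``n/nc`` is flagged.
* **MMOT** — k-means trajectory clusters as in MMOM; within each cluster
  each member's residual sum of squares (RSS) to the cluster's per-visit
  mean trajectory is computed, and members whose RSS exceeds the cluster's
  mean RSS by more than ``k_sd`` RSS-SDs are flagged (one-sided: only a
  poor fit is anomalous).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from ..cohort import CohortTable, ConfigError, TrajectoryMatrix, to_matrix
from .base import DetectionResult
from .points import kmeans_labels

__all__ = ["COTParams", "MMOTParams", "nc_of", "cot", "rss", "mmot"]


def nc_of(n: int) -> int:
    """Number of hierarchical clusters for COT: ``max(2, floor(n/10))``."""
    if n < 2:
        raise ConfigError("need at least 2 subjects")
    return max(2, n // 10)


@dataclass(frozen=True)
class COTParams:
    """COT configuration.  ``small_cluster_size``: flag clusters strictly
    smaller than this; ``None`` means the average cluster size n/nc.
    Linkage and distance are fixed (complete, Euclidean) by design."""

    small_cluster_size: float | None = None

    def threshold(self, n: int, nc: int) -> float:
        if self.small_cluster_size is not None:
            if self.small_cluster_size < 1:
                raise ConfigError("small_cluster_size must be >= 1")
            return float(self.small_cluster_size)
        return n / nc


@dataclass(frozen=True)
class MMOTParams:
    k: int = 2
    k_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")


def _as_matrix(data: TrajectoryMatrix | CohortTable) -> TrajectoryMatrix:
    return to_matrix(data) if isinstance(data, CohortTable) else data


def cot(data: TrajectoryMatrix | CohortTable,
        params: COTParams | None = None) -> DetectionResult:
    """Flag subjects isolated in small complete-linkage clusters."""
    params = params or COTParams()
    matrix = _as_matrix(data)
    n = matrix.n_subjects
    nc = nc_of(n)
    tree = linkage(pdist(matrix.values, metric="euclidean"), method="complete")
    labels = fcluster(tree, t=nc, criterion="maxclust")
    sizes = np.bincount(labels)
    thr = params.threshold(n, nc)
    small = sizes < thr
    flags = frozenset(
        matrix.subject_ids[i] for i in range(n) if small[labels[i]]
    )
    return DetectionResult("trajectory", flags, "cot",
                           {"nc": nc, "small_cluster_threshold": thr})


def rss(trajectory: np.ndarray, reference: np.ndarray) -> float:
    """Residual sum of squares between a trajectory and a reference curve."""
    x = np.asarray(trajectory, float)
    r = np.asarray(reference, float)
    if x.shape != r.shape:
        raise ConfigError(f"length mismatch: {x.shape} vs {r.shape}")
    return float(np.sum((x - r) ** 2))


def mmot(data: TrajectoryMatrix | CohortTable,
         params: MMOTParams | None = None) -> DetectionResult:
    """Flag trajectories fitting their k-means cluster's average model
    poorly (RSS > cluster mean RSS + k_sd * RSS SD)."""
    params = params or MMOTParams()
    matrix = _as_matrix(data)
    if matrix.n_subjects < params.k:
        raise ConfigError("k exceeds number of subjects")
    labels = kmeans_labels(matrix.values, params.k, params.seed)
    flags = set()
    for lab in np.unique(labels):
        rows = np.nonzero(labels == lab)[0]
        if rows.size < 2:  # SD of a single RSS is undefined; rule skipped
            continue
        member = matrix.values[rows]
        reference = member.mean(axis=0)
        errs = np.array([rss(member[i], reference) for i in range(rows.size)])
        cut = errs.mean() + params.k_sd * errs.std(ddof=0)
        flags.update(matrix.subject_ids[rows[i]]
                     for i in np.nonzero(errs > cut)[0])
    return DetectionResult("trajectory", frozenset(flags), "mmot",
                           {"k": params.k, "k_sd": params.k_sd,
                            "seed": params.seed})
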