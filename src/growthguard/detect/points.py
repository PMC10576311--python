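"""Measurement-level outlier detectors.

Four detectors flag individual time-point measurements:

* **sBIV** — static biologically-implausible-value screen against fixed
  WHO flag limits, applied cross-sectionally (z strictly beyond the
  per-measure bounds).
* **mBIV** — longitudinal refinement of sBIV: a candidate BIV is cleared
  when another measurement of the same child, within a 2-year age window,
  lies within 2 z-units of it — the "implausible" value is then read as
  part of an extreme but internally consistent trajectory.
* **SMOM** — single-model screen: flag measurements beyond ±2 SDs of the
  population mean at that time-point (under normality ~4.55% of clean
  observations fall outside this band).
* **MMOM** — multi-model screen: k-means (Euclidean) clusters whole
  trajectories into latent growth groups; the ±2 SD time-point screen is
  applied within each child's own cluster.

All SDs use the population-style divisor ``n`` so that MMOM with a single
cluster reduces exactly to SMOM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ..cohort import CohortTable, ConfigError, TrajectoryMatrix, to_matrix
from .base import DetectionResult

__all__ = [
    "BIVCutoffs",
    "MBIVParams",
    "DEFAULT_CUTOFFS",
    "sbiv",
    "mbiv",
    "smom",
    "mmom",
    "kmeans_labels",
]

#: WHO flag limits per measure (lower, upper), z-units.
DEFAULT_CUTOFFS: dict[str, tuple[float, float]] = {
    "zWFL": (-5.0, 5.0),
    "zWA": (-6.0, 5.0),
    "zMUAC": (-5.0, 5.0),
}


@dataclass(frozen=True)
class BIVCutoffs:
    """Per-measure biologically-implausible-value bounds."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CUTOFFS)
    )

    def __post_init__(self) -> None:
        for m, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ConfigError(f"cutoffs for {m!r}: lower must be < upper")

    def for_measure(self, measure: str) -> tuple[float, float]:
        try:
            return self.bounds[measure]
        except KeyError:
            raise ConfigError(f"no BIV cut-offs configured for measure {measure!r}")


@dataclass(frozen=True)
class MBIVParams:
    window: float = 24.0     # months either side of the candidate
    closeness: float = 2.0   # z-units

    def __post_init__(self) -> None:
        if not self.window > 0 or not self.closeness > 0:
            raise ConfigError("window and closeness must be > 0")


def sbiv(cohort: CohortTable, cutoffs: BIVCutoffs | None = None) -> DetectionResult:
    """Flag every measurement strictly beyond the fixed WHO limits."""
    cutoffs = cutoffs or BIVCutoffs()
    lo, hi = cutoffs.for_measure(cohort.measure)
    z = cohort.frame["zscore"].to_numpy()
    mask = (z < lo) | (z > hi)
    flags = frozenset(
        zip(
            cohort.frame.loc[mask, "subject_id"],
            cohort.frame.loc[mask, "visit_index"].astype(int),
        )
    )
    return DetectionResult("measurement", flags, "sbiv",
                           {"lower": lo, "upper": hi})


def mbiv(cohort: CohortTable, cutoffs: BIVCutoffs | None = None,
         params: MBIVParams | None = None) -> DetectionResult:
    """sBIV candidates, confirmed only when no nearby-in-age measurement
    of the same child lies within ``closeness`` z-units of the candidate."""
    cutoffs = cutoffs or BIVCutoffs()
    params = params or MBIVParams()
    candidates = sbiv(cohort, cutoffs).flags
    if not candidates:
        return DetectionResult("measurement", frozenset(), "mbiv",
                               {"window": params.window,
                                "closeness": params.closeness})
    by_subject = {
        sid: grp[["visit_index", "age_months", "zscore"]].to_numpy(float)
        for sid, grp in cohort.frame.groupby("subject_id", sort=False)
    }
    confirmed = set()
    for sid, visit in candidates:
        rows = by_subject[sid]
        cand = rows[rows[:, 0] == visit][0]
        others = rows[rows[:, 0] != visit]
        near = np.abs(others[:, 1] - cand[1]) <= params.window
        close = np.abs(others[:, 2] - cand[2]) <= params.closeness
        if not np.any(near & close):
            confirmed.add((sid, visit))
    return DetectionResult("measurement", frozenset(confirmed), "mbiv",
                           {"window": params.window,
                            "closeness": params.closeness})


def _per_column_flags(values: np.ndarray, rows: np.ndarray, k_sd: float) -> np.ndarray:
    """Boolean mask over ``values[rows]`` cells beyond k_sd column SDs of
    the column mean (population divisor).  Zero-SD columns flag nothing."""
    sub = values[rows]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore"):
        mask = np.abs(sub - mean) > k_sd * sd
    mask[:, sd == 0] = False
    return mask


def smom(matrix: TrajectoryMatrix | CohortTable, k_sd: float = 2.0) -> DetectionResult:
    """Single-model screen: ±k_sd SDs around the per-time-point population
    mean."""
    if isinstance(matrix, CohortTable):
        matrix = to_matrix(matrix)
    if matrix.n_subjects < 2:
        raise ConfigError("smom needs at least 2 subjects")
    mask = _per_column_flags(matrix.values, np.arange(matrix.n_subjects), k_sd)
    ii, jj = np.nonzero(mask)
    flags = frozenset((matrix.subject_ids[i], int(j)) for i, j in zip(ii, jj))
    return DetectionResult("measurement", flags, "smom", {"k_sd": k_sd})


def kmeans_labels(values: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """K-means (k-means++, Euclidean, 10 restarts) labels for whole
    trajectories; deterministic given seed."""
    n = values.shape[0]
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > n:
        raise ConfigError(f"k={k} exceeds n_subjects={n}")
    if k == 1:
        return np.zeros(n, dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(values)


def mmom(matrix: TrajectoryMatrix | CohortTable, k: int = 2, k_sd: float = 2.0,
         seed: int = 0) -> DetectionResult:
    """Multi-model screen: the SMOM rule applied within each k-means
    trajectory cluster."""
    if isinstance(matrix, CohortTable):
        matrix = to_matrix(matrix)
    if matrix.n_subjects < 2:
        raise ConfigError("mmom needs at least 2 subjects")
    labels = kmeans_labels(matrix.values, k, seed)
    flags = set()
    for lab in np.unique(labels):
        rows = np.nonzero(labels == lab)[0]
        mask = _per_column_flags(matrix.values, rows, k_sd)
        ii, jj = np.nonzero(mask)
        flags.update((matrix.subject_ids[rows[i]], int(j)) for i, j in zip(ii, jj))
    return DetectionResult("measurement", frozenset(flags), "mmom",
                           {"k": k, "k_sd": k_sd, "seed": seed})
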