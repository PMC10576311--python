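"""Synthetic outlier injection with a gold-standard flag table.

Three error types are injected into clean cohorts, each at six intensities
(0.5-5 SD multipliers):

* **Type a** (moderate-to-extreme): add ``sign * intensity * 1`` — a signed
  multiple of the standard-normal SD.
* **Type b** (extreme): add ``+intensity * 1`` to the *absolute value* of
  the measurement, always pushing it into the implausible upper range.
* **Type c** (local/contextual): add ``sign * intensity * sd_i`` where
  ``sd_i`` is the SD of the subject's own trajectory — anomalous for the
  child even when plausible for the population.

In the default *spread* mode each requested type perturbs 5% of all
measurements, cells drawn uniformly without replacement and never
double-flagged, so ALL three types together contaminate 15% of the data.
The *concentrated* mode instead hits 30% of the children with 4 outliers
each (same overall count, fewer children), for density sensitivity
analyses.  Every perturbed cell is recorded in a flag table that serves as
the gold standard for evaluating detectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    CohortTable,
    ConfigError,
    empty_flags,
    to_matrix,
)

__all__ = [
    "ERROR_TYPES",
    "INTENSITY_GRID",
    "InjectionSpec",
    "InjectionResult",
    "injection_count",
    "perturb",
    "inject",
    "trajectory_gold",
]

ERROR_TYPES = ("a", "b", "c")
INTENSITY_GRID = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class InjectionSpec:
    error_types: tuple[str, ...] = ERROR_TYPES
    intensity: float = 1.0
    rate: float = 0.05
    mode: str = "spread"  # or "concentrated"
    child_fraction: float = 0.30
    outliers_per_child: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        types = tuple(self.error_types)
        if isinstance(self.error_types, str):
            types = tuple(self.error_types.split(",")) if "," in self.error_types \
                else tuple(self.error_types)
        if not types or any(t not in ERROR_TYPES for t in types):
            raise ConfigError(f"error_types must be a nonempty subset of {ERROR_TYPES}")
        if len(set(types)) != len(types):
            raise ConfigError("duplicate error types")
        object.__setattr__(self, "error_types", types)
        if not self.intensity > 0:
            raise ConfigError("intensity must be > 0")
        if not 0 < self.rate < 1:
            raise ConfigError("rate must be in (0, 1)")
        if self.mode not in ("spread", "concentrated"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not 0 < self.child_fraction <= 1:
            raise ConfigError("child_fraction must be in (0, 1]")
        if self.outliers_per_child < 1:
            raise ConfigError("outliers_per_child must be >= 1")


@dataclass(frozen=True)
class InjectionResult:
    """Perturbed cohort plus the gold-standard flag table."""

    cohort: CohortTable
    flags: pd.DataFrame

    @property
    def outlier_subjects(self) -> frozenset[str]:
        return frozenset(self.flags["subject_id"])

    def flag_cells(self) -> frozenset[tuple[str, int]]:
        return frozenset(
            zip(self.flags["subject_id"], self.flags["visit_index"].astype(int))
        )


def injection_count(n_measurements: int, rate: float) -> int:
    """Number of cells to perturb per error type: round-half-up(rate * n)."""
    if n_measurements < 0:
        raise ConfigError("n_measurements must be >= 0")
    if not 0 < rate < 1:
        raise ConfigError("rate must be in (0, 1)")
    return int(math.floor(rate * n_measurements + 0.5))


def perturb(value: float, error_type: str, intensity: float,
            traj_sd: float | None = None, sign: int = 1) -> float:
    """Apply one synthetic error to a single z-score.

    ``sign`` (+1/-1) is used by types a and c; type b is always positive
    and acts on the absolute value.  ``traj_sd`` — the SD of the subject's
    own trajectory — is required for type c only.
    """
    if sign not in (1, -1):
        raise ConfigError("sign must be +1 or -1")
    if not intensity > 0:
        raise ConfigError("intensity must be > 0")
    if error_type == "a":
        return value + sign * intensity
    if error_type == "b":
        return abs(value) + intensity
    if error_type == "c":
        if traj_sd is None:
            raise ConfigError("type c requires the subject's trajectory SD")
        return value + sign * intensity * traj_sd
    raise ConfigError(f"unknown error type {error_type!r}")


def _subject_sds(cohort: CohortTable) -> dict[str, float]:
    # population-style divisor n, matching the detectors' SD convention
    matrix = to_matrix(cohort)
    sds = matrix.values.std(axis=1, ddof=0)
    return dict(zip(matrix.subject_ids, sds))


def inject(cohort: CohortTable, spec: InjectionSpec) -> InjectionResult:
    """Perturb a cohort and record every altered cell as a gold flag.

    Spread mode: for each requested type, ``injection_count`` cells are
    drawn uniformly without replacement from the not-yet-altered cells.
    Concentrated mode: ``child_fraction`` of subjects get
    ``outliers_per_child`` perturbed cells each, types cycled.
    Reproducible given ``spec.seed``; unflagged cells are bit-identical.
    """
    rng = np.random.default_rng(spec.seed)
    frame = cohort.frame  # sorted (subject_id, visit_index)
    n = len(frame)
    traj_sd = _subject_sds(cohort) if "c" in spec.error_types else {}

    chosen: list[tuple[int, str]] = []  # (row position, error type)
    if spec.mode == "spread":
        per_type = injection_count(n, spec.rate)
        total = per_type * len(spec.error_types)
        if total >= n and per_type > 0:
            raise ConfigError(
                f"requested {total} injections but cohort has only {n} cells"
            )
        available = np.arange(n)
        for etype in spec.error_types:
            if per_type == 0:
                continue
            pick = rng.choice(available.size, size=per_type, replace=False)
            chosen.extend((int(available[p]), etype) for p in pick)
            available = np.delete(available, pick)
    else:
        sids = np.asarray(cohort.subject_ids)
        n_children = int(math.floor(spec.child_fraction * len(sids) + 0.5))
        if spec.outliers_per_child > cohort.n_visits:
            raise ConfigError("outliers_per_child exceeds visits per subject")
        hit = rng.choice(len(sids), size=n_children, replace=False)
        hit.sort()
        cycle = 0
        for s in hit:
            visits = rng.choice(cohort.n_visits, size=spec.outliers_per_child,
                                replace=False)
            for v in sorted(int(v) for v in visits):
                etype = spec.error_types[cycle % len(spec.error_types)]
                cycle += 1
                chosen.append((s * cohort.n_visits + v, etype))

    if not chosen:
        return InjectionResult(cohort, empty_flags())

    z = frame["zscore"].to_numpy(copy=True)
    sid_col = frame["subject_id"].to_numpy()
    visit_col = frame["visit_index"].to_numpy()
    records = []
    for pos, etype in chosen:
        sid = sid_col[pos]
        sign = 1 if etype == "b" else int(rng.choice((-1, 1)))
        original = float(z[pos])
        injected = perturb(original, etype, spec.intensity,
                           traj_sd.get(sid), sign)
        z[pos] = injected
        records.append((sid, int(visit_col[pos]), etype, original, injected))

    flags = pd.DataFrame(
        records,
        columns=["subject_id", "visit_index", "error_type", "original_z",
                 "injected_z"],
    ).sort_values(["subject_id", "visit_index"], kind="mergesort").reset_index(drop=True)

    dirty = frame.copy()
    dirty["zscore"] = z
    return InjectionResult(
        CohortTable(dirty, cohort.schedule, cohort.measure), flags
    )


def trajectory_gold(result: InjectionResult) -> frozenset[str]:
    """Subjects carrying at least one injected outlier measurement — the
    gold standard for trajectory-level detectors."""
    return result.outlier_subjects
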