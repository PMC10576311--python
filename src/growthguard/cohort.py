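"""Core containers for longitudinal growth z-score data.

A cohort is a long-format table of WHO-standardized growth measurements
(one row per subject per scheduled visit, single measure per table).
All detectors operate on the equivalent wide form, a complete
subjects x visits grid of z-scores (:class:`TrajectoryMatrix`).

Visits are aligned by nominal ``visit_index`` on a fixed schedule; age in
months is carried as metadata. Subjects with missing visits are rejected
(complete-case), mirroring the exclusion of incompletely measured children
from the cohorts this toolkit targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MEASURES",
    "CohortError",
    "FormatError",
    "CompletenessError",
    "ConfigError",
    "CohortTable",
    "TrajectoryMatrix",
    "read_cohort",
    "write_cohort",
    "to_matrix",
    "from_matrix",
    "read_flags",
    "write_flags",
    "empty_flags",
]

MEASURES = ("zWFL", "zWA", "zMUAC", "other")

COHORT_COLUMNS = ["subject_id", "visit_index", "age_months", "measure", "zscore"]
FLAG_COLUMNS = ["subject_id", "visit_index", "error_type", "original_z", "injected_z"]


class CohortError(ValueError):
    """Base class for cohort validation failures."""


class FormatError(CohortError):
    """Malformed input file: missing columns or unparseable values."""


class CompletenessError(CohortError):
    """A subject is missing one or more scheduled visits."""


class ConfigError(ValueError):
    """Invalid or inconsistent configuration."""


@dataclass(frozen=True)
class CohortTable:
    """Long-format set of growth records for one population and measure.

    Parameters
    ----------
    frame
        Columns ``subject_id, visit_index, age_months, measure, zscore``;
        one row per (subject, visit), every subject complete on the schedule.
    schedule
        Nominal visit ages in months, one per visit index, strictly increasing.
    measure
        The single measure the table carries (``zWFL``/``zWA``/``zMUAC``/``other``).
    """

    frame: pd.DataFrame
    schedule: tuple[float, ...]
    measure: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedule", tuple(float(a) for a in self.schedule))
        _validate_cohort(self.frame, self.schedule, self.measure)
        frame = self.frame.loc[:, COHORT_COLUMNS].copy()
        frame = frame.sort_values(["subject_id", "visit_index"], kind="mergesort")
        frame = frame.reset_index(drop=True)
        object.__setattr__(self, "frame", frame)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    @property
    def n_visits(self) -> int:
        return len(self.schedule)

    @property
    def n_measurements(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["subject_id"].unique()))

    def cells(self) -> frozenset[tuple[str, int]]:
        """All (subject_id, visit_index) evaluation units."""
        return frozenset(
            zip(self.frame["subject_id"], self.frame["visit_index"].astype(int))
        )

    def equals(self, other: "CohortTable") -> bool:
        return (
            self.schedule == other.schedule
            and self.measure == other.measure
            and self.frame.equals(other.frame)
        )


def _validate_cohort(
    frame: pd.DataFrame, schedule: tuple[float, ...], measure: str
) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"cohort table missing columns: {missing}")
    if len(schedule) < 1:
        raise CohortError("schedule must have at least one visit")
    if any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise CohortError("schedule ages must be strictly increasing")
    if not frame["measure"].eq(measure).all():
        bad = sorted(set(frame["measure"]) - {measure})
        raise CohortError(f"records carry measures {bad} but table declares {measure!r}")
    if not np.issubdtype(frame["zscore"].dtype, np.number):
        raise FormatError("zscore column is not numeric")
    if frame["zscore"].isna().any():
        row = int(frame.index[frame["zscore"].isna()][0])
        raise FormatError(f"non-numeric zscore at row {row}")
    dup = frame.duplicated(subset=["subject_id", "visit_index", "measure"])
    if dup.any():
        row = frame.iloc[int(np.argmax(dup.to_numpy()))]
        raise CohortError(
            f"duplicate record for subject {row['subject_id']!r} "
            f"visit {row['visit_index']}"
        )
    expected = set(range(len(schedule)))
    for sid, grp in frame.groupby("subject_id", sort=False):
        visits = set(grp["visit_index"].astype(int))
        if visits != expected:
            lacking = sorted(expected - visits)
            raise CompletenessError(
                f"subject {sid!r} is incomplete: missing visit(s) {lacking}"
            )
        ages = grp.sort_values("visit_index")["age_months"].to_numpy(float)
        if np.any(np.diff(ages) <= 0):
            raise CohortError(f"ages not strictly increasing for subject {sid!r}")


@dataclass(frozen=True)
class TrajectoryMatrix:
    """Complete subjects x visits grid of z-scores on a fixed schedule."""

    subject_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_subjects, n_visits), float64
    schedule: tuple[float, ...]
    measure: str = "other"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise CohortError("trajectory values must be 2-D")
        if values.shape[0] != len(self.subject_ids):
            raise CohortError("row count does not match subject_ids")
        if values.shape[1] != len(self.schedule):
            raise CohortError("column count does not match schedule")
        if np.isnan(values).any():
            raise CohortError("trajectory grid contains missing cells")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "schedule", tuple(float(a) for a in self.schedule))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_visits(self) -> int:
        return self.values.shape[1]


def to_matrix(cohort: CohortTable) -> TrajectoryMatrix:
    """Pivot a cohort into its trajectory grid (rows sorted by subject_id)."""
    if cohort.n_measurements == 0:
        return TrajectoryMatrix((), np.empty((0, cohort.n_visits)), cohort.schedule,
                                cohort.measure)
    wide = cohort.frame.pivot(index="subject_id", columns="visit_index",
                              values="zscore").sort_index()
    wide = wide.reindex(columns=range(cohort.n_visits))
    return TrajectoryMatrix(
        tuple(wide.index), wide.to_numpy(np.float64), cohort.schedule, cohort.measure
    )


def from_matrix(matrix: TrajectoryMatrix) -> CohortTable:
    """Inverse of :func:`to_matrix`; ages are the nominal schedule ages."""
    n, k = matrix.values.shape
    frame = pd.DataFrame(
        {
            "subject_id": np.repeat(matrix.subject_ids, k),
            "visit_index": np.tile(np.arange(k), n),
            "age_months": np.tile(np.asarray(matrix.schedule, float), n),
            "measure": matrix.measure,
            "zscore": matrix.values.ravel(),
        }
    )
    return CohortTable(frame, matrix.schedule, matrix.measure)


def _schedule_from_frame(frame: pd.DataFrame) -> tuple[float, ...]:
    sched = (
        frame.groupby("visit_index")["age_months"].median().sort_index()
    )
    return tuple(float(a) for a in sched)


def read_cohort(path: str | Path, measure: str | None = None,
                schedule: tuple[float, ...] | None = None) -> CohortTable:
    """Read and validate a long-format cohort CSV.

    The file must carry the header ``subject_id,visit_index,age_months,
    measure,zscore``.  ``measure`` defaults to the single measure found in
    the file; the schedule defaults to the per-visit median recorded age.
    """
    frame = pd.read_csv(path, dtype={"subject_id": str, "measure": str})
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in ("visit_index", "age_months", "zscore"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().any():
            row = int(np.argmax(coerced.isna().to_numpy())) + 2  # 1-based + header
            raise FormatError(f"{path}: non-numeric {col} at line {row}")
        frame[col] = coerced
    frame["visit_index"] = frame["visit_index"].astype(int)
    if measure is None:
        uniq = sorted(frame["measure"].unique())
        if len(uniq) != 1:
            raise FormatError(f"{path}: multiple measures {uniq}; pass measure=")
        measure = uniq[0]
    if schedule is None:
        schedule = _schedule_from_frame(frame)
    return CohortTable(frame, schedule, measure)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV with deterministic row order; lossless round-trip."""
    cohort.frame.to_csv(path, index=False)


def empty_flags() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": pd.Series(dtype=str),
            "visit_index": pd.Series(dtype=int),
            "error_type": pd.Series(dtype=str),
            "original_z": pd.Series(dtype=float),
            "injected_z": pd.Series(dtype=float),
        }
    )


def _normalise_flags(flags: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FLAG_COLUMNS if c not in flags.columns]
    if missing:
        raise FormatError(f"flag table missing columns: {missing}")
    out = flags.loc[:, FLAG_COLUMNS].copy()
    out["subject_id"] = out["subject_id"].astype(str)
    out["visit_index"] = out["visit_index"].astype(int)
    bad = ~out["error_type"].isin(("a", "b", "c"))
    if bad.any():
        raise FormatError(f"unknown error_type {out.loc[bad, 'error_type'].iloc[0]!r}")
    out = out.sort_values(["subject_id", "visit_index"], kind="mergesort")
    return out.reset_index(drop=True)


def write_flags(flags: pd.DataFrame, path: str | Path) -> None:
    """Write a gold-standard flag table (sorted, fixed column order)."""
    _normalise_flags(flags).to_csv(path, index=False)


def read_flags(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        dtype={"subject_id": str, "error_type": str},
    )
    if frame.empty and list(frame.columns) == FLAG_COLUMNS:
        return empty_flags()
    return _normalise_flags(frame)
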