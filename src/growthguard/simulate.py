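"""Synthetic longitudinal growth cohorts with latent group structure.

Real paediatric growth cohorts of the kind this toolkit cleans are access
restricted, so downstream modules are exercised on simulated populations
that match their published shapes: a primary-care cohort of 393 children
with 8 scheduled weight-for-length visits (zWFL), and a clinical-trial
cohort measured at 9 visits for weight-for-age (849 children, zWA) and
mid-upper-arm circumference (802 children, zMUAC).

Each population mixes two latent growth-pattern groups.  Subject ``i`` in
group ``g`` follows

    z_ij = a_g + b_g * t_j + c_g * t_j^2 + u_i + e_ij

with ``t_j`` the months elapsed since the first scheduled visit, a random
intercept ``u_i ~ N(0, subject_sd^2)`` and residual ``e_ij ~ N(0,
noise_sd^2)``.  Group intercepts/slopes in the presets encode the verbal
descriptions of the published cluster shapes (e.g. "severe wasting,
increase within abnormal levels" starts near -3.5 zWA and rises but stays
below -2); they are configurable, not data-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortTable, ConfigError

__all__ = ["GroupSpec", "CohortSpec", "generate", "preset", "PRESET_NAMES"]


@dataclass(frozen=True)
class GroupSpec:
    """Mean growth curve of one latent group (z-units at first visit,
    z-units/month, z-units/month^2)."""

    intercept: float
    slope: float
    curvature: float = 0.0

    def curve(self, ages: np.ndarray) -> np.ndarray:
        t = np.asarray(ages, float) - float(ages[0])
        return self.intercept + self.slope * t + self.curvature * t**2


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one simulated population."""

    n_subjects: int
    schedule: tuple[float, ...]
    groups: tuple[GroupSpec, ...]
    group_weights: tuple[float, ...]
    noise_sd: float = 0.3
    subject_sd: float = 0.8
    measure: str = "other"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedule", tuple(float(a) for a in self.schedule))
        object.__setattr__(self, "groups", tuple(self.groups))
        w = np.asarray(self.group_weights, float)
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if len(self.schedule) < 2:
            raise ConfigError("need at least 2 visits")
        if len(self.groups) != len(w) or len(self.groups) == 0:
            raise ConfigError("groups and group_weights must match and be nonempty")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ConfigError("group_weights must be nonnegative and sum to 1")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ConfigError("noise_sd and subject_sd must be >= 0")
        object.__setattr__(self, "group_weights", tuple(float(x) for x in w))

    @property
    def n_visits(self) -> int:
        return len(self.schedule)


def generate(spec: CohortSpec, seed: int | None = None,
             return_groups: bool = False):
    """Draw a complete cohort from ``spec``.

    Each subject gets its own deterministic random sub-stream derived from
    the master seed and the subject index, so enlarging ``n_subjects``
    leaves already-generated subjects unchanged.

    Returns the :class:`CohortTable`; with ``return_groups=True`` also the
    per-subject latent group labels (the generative ground truth used by
    cluster-recovery checks).
    """
    master = spec.seed if seed is None else seed
    ages = np.asarray(spec.schedule, float)
    cum_w = np.cumsum(spec.group_weights)
    curves = np.stack([g.curve(ages) for g in spec.groups])
    width = len(str(spec.n_subjects - 1))

    rows_z = np.empty((spec.n_subjects, spec.n_visits))
    labels = np.empty(spec.n_subjects, dtype=int)
    for i in range(spec.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence(master, spawn_key=(i,)))
        g = int(np.searchsorted(cum_w, rng.random(), side="right"))
        g = min(g, len(spec.groups) - 1)
        u = rng.normal(0.0, spec.subject_sd)
        eps = rng.normal(0.0, spec.noise_sd, size=spec.n_visits)
        rows_z[i] = curves[g] + u + eps
        labels[i] = g

    sids = np.array([f"S{i:0{width}d}" for i in range(spec.n_subjects)])
    frame = pd.DataFrame(
        {
            "subject_id": np.repeat(sids, spec.n_visits),
            "visit_index": np.tile(np.arange(spec.n_visits), spec.n_subjects),
            "age_months": np.tile(ages, spec.n_subjects),
            "measure": spec.measure,
            "zscore": rows_z.ravel(),
        }
    )
    cohort = CohortTable(frame, spec.schedule, spec.measure)
    if return_groups:
        return cohort, dict(zip(sids, labels))
    return cohort


# Scheduled ages in months.  The primary-care preset uses the well-child
# visit schedule (2-24 months); the trial preset uses monthly follow-up
# visits then quarterly to 12 months.
_TARGETKIDS_SCHEDULE = (2.0, 4.0, 6.0, 9.0, 12.0, 15.0, 18.0, 24.0)
_CTX_SCHEDULE = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 9.0, 12.0)

_PRESETS: dict[str, CohortSpec] = {
    # two groups: "low normal, rapid increase" vs "normal, modest steady increase"
    "targetkids_zwfl": CohortSpec(
        n_subjects=393,
        schedule=_TARGETKIDS_SCHEDULE,
        groups=(GroupSpec(-1.0, 0.065), GroupSpec(0.0, 0.015)),
        group_weights=(199 / 393, 194 / 393),
        measure="zWFL",
    ),
    # "severe wasting, increase within abnormal levels" vs
    # "wasting, increase to normal levels"
    "ctx_zwa": CohortSpec(
        n_subjects=849,
        schedule=_CTX_SCHEDULE,
        groups=(GroupSpec(-3.5, 0.07), GroupSpec(-3.0, 0.25)),
        group_weights=(490 / 849, 359 / 849),
        measure="zWA",
    ),
    # "increase to normal levels" vs "increase but within wasting"
    "ctx_zmuac": CohortSpec(
        n_subjects=802,
        schedule=_CTX_SCHEDULE,
        groups=(GroupSpec(-2.5, 0.21), GroupSpec(-3.2, 0.08)),
        group_weights=(634 / 802, 168 / 802),
        measure="zMUAC",
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, **overrides) -> CohortSpec:
    """Return the named population preset; keyword overrides are applied
    with :func:`dataclasses.replace` (e.g. ``preset("ctx_zwa", seed=7)``)."""
    try:
        base = _PRESETS[name]
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return replace(base, **overrides) if overrides else base
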