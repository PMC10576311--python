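"""Scoring detections against the injected gold standard.

A true positive at the measurement level is a flag at exactly the cell
(subject, visit) where a synthetic outlier was injected; at the trajectory
level it is a flagged subject who carries at least one injected outlier.
Performance is summarized by sensitivity, specificity, precision and
Cohen's kappa; ratios with zero denominators are reported as NaN (never 0)
and excluded from repetition averages.

``run_experiment`` drives the full simulation grid (methods x error types
x intensities x cohort presets, repeated with fresh seeds) and aggregates
per-configuration metric means and SDs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, ConfigError, to_matrix
from .detect import (
    DetectionResult,
    cot,
    mbiv,
    mmom,
    mmot,
    sbiv,
    smom,
)
from .detect.trajectories import COTParams, MMOTParams
from .inject import InjectionSpec, inject, trajectory_gold
from .simulate import CohortSpec, generate, preset

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EvalSummary",
    "OverlapReport",
    "ExperimentConfig",
    "confusion",
    "metrics",
    "combine",
    "overlap",
    "evaluate_detection",
    "enumerate_grid",
    "run_experiment",
    "METHOD_LEVELS",
]

METHOD_LEVELS = {
    "sbiv": "measurement",
    "mbiv": "measurement",
    "smom": "measurement",
    "mmom": "measurement",
    "cot": "trajectory",
    "mmot": "trajectory",
}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    precision: float
    kappa: float


def confusion(predicted: Iterable, gold: Iterable, universe: Iterable) -> ConfusionCounts:
    """2x2 counts of predicted vs gold flags over a finite universe of
    evaluation units (cells or subjects)."""
    pred, gld, uni = frozenset(predicted), frozenset(gold), frozenset(universe)
    if not pred <= uni:
        raise ConfigError("predicted flags outside the evaluation universe")
    if not gld <= uni:
        raise ConfigError("gold flags outside the evaluation universe")
    tp = len(pred & gld)
    fp = len(pred - gld)
    fn = len(gld - pred)
    tn = len(uni) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, precision and Cohen's kappa.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement
    p_o = (tp+tn)/N and chance agreement
    p_e = [(tp+fp)(tp+fn) + (fn+tn)(fp+tn)] / N^2.
    """
    n = counts.total
    if n == 0:
        raise ConfigError("empty confusion table")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = (p_o - p_e) / (1 - p_e) if p_e != 1 else math.nan
    return Metrics(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
        kappa=kappa,
    )


def combine(*results: DetectionResult) -> DetectionResult:
    """Pairwise (or n-wise) method combination: the union of flags."""
    if not results:
        raise ConfigError("nothing to combine")
    levels = {r.level for r in results}
    if len(levels) != 1:
        raise ConfigError(f"cannot combine mixed levels {sorted(levels)}")
    flags = frozenset().union(*(r.flags for r in results))
    return DetectionResult(
        results[0].level,
        flags,
        "+".join(r.method for r in results),
        {"parents": [r.method for r in results]},
    )


@dataclass(frozen=True)
class OverlapReport:
    """True-positive / false-positive overlap between two methods."""

    method_a: str
    method_b: str
    shared_tp: int
    unique_tp_a: int
    unique_tp_b: int
    shared_fp: int
    unique_fp_a: int
    unique_fp_b: int


def overlap(a: DetectionResult, b: DetectionResult, gold: Iterable,
            universe: Iterable | None = None) -> OverlapReport:
    """How two methods share and split their true and false positives."""
    if a.level != b.level:
        raise ConfigError("cannot compare mixed levels")
    gld = frozenset(gold)
    tp_a, tp_b = a.flags & gld, b.flags & gld
    fp_a, fp_b = a.flags - gld, b.flags - gld
    return OverlapReport(
        method_a=a.method,
        method_b=b.method,
        shared_tp=len(tp_a & tp_b),
        unique_tp_a=len(tp_a - tp_b),
        unique_tp_b=len(tp_b - tp_a),
        shared_fp=len(fp_a & fp_b),
        unique_fp_a=len(fp_a - fp_b),
        unique_fp_b=len(fp_b - fp_a),
    )


def _run_method(method: str, cohort: CohortTable, seed: int,
                method_params: Mapping | None = None) -> DetectionResult:
    p = dict(method_params or {})
    if method == "sbiv":
        return sbiv(cohort, p.get("cutoffs"))
    if method == "mbiv":
        return mbiv(cohort, p.get("cutoffs"), p.get("mbiv_params"))
    if method == "smom":
        return smom(cohort, k_sd=p.get("k_sd", 2.0))
    if method == "mmom":
        return mmom(cohort, k=p.get("k", 2), k_sd=p.get("k_sd", 2.0), seed=seed)
    if method == "cot":
        return cot(cohort, p.get("cot_params"))
    if method == "mmot":
        return mmot(cohort, MMOTParams(k=p.get("k", 2),
                                       k_sd=p.get("k_sd", 2.0), seed=seed))
    raise ConfigError(f"unknown method {method!r}")


def evaluate_detection(result: DetectionResult, cohort: CohortTable,
                       gold_cells: Iterable, gold_subjects: Iterable) -> Metrics:
    """Score one detection against the gold standard at its own level."""
    if result.level == "measurement":
        counts = confusion(result.flags, gold_cells, cohort.cells())
    else:
        counts = confusion(result.flags, gold_subjects, cohort.subject_ids)
    return metrics(counts)


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid of simulation conditions for :func:`run_experiment`."""

    presets: tuple[str, ...] = ("targetkids_zwfl", "ctx_zwa", "ctx_zmuac")
    methods: tuple[str, ...] = ("sbiv", "mbiv", "smom", "mmom", "cot", "mmot")
    error_types: tuple[tuple[str, ...], ...] = (("a",), ("b",), ("c",),
                                                ("a", "b", "c"))
    intensities: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
    rate: float = 0.05
    mode: str = "spread"
    n_reps: int = 100
    seed: int = 0
    fresh_cohort: bool = True  # re-draw the cohort every repetition
    method_params: dict = field(default_factory=dict)


def enumerate_grid(config: ExperimentConfig) -> list[tuple]:
    """All (preset, method, error_types, intensity) configurations."""
    return list(
        itertools.product(config.presets, config.methods, config.error_types,
                          config.intensities)
    )


def _types_label(types: Sequence[str]) -> str:
    return "ALL" if set(types) == {"a", "b", "c"} else "+".join(types)


def run_experiment(config: ExperimentConfig,
                   progress: bool = False) -> pd.DataFrame:
    """Run the full injection/detection/scoring grid.

    Per repetition a cohort is drawn (fresh noise unless
    ``fresh_cohort=False``), outliers are injected, every requested method
    is run on the contaminated data and scored against the gold standard.
    Returns one row per configuration with mean/SD of each metric across
    repetitions and the count of repetitions where a metric was undefined.
    """
    rng_root = np.random.SeedSequence(config.seed)
    rows = []
    metric_names = ("sensitivity", "specificity", "precision", "kappa")
    for ip, preset_name in enumerate(config.presets):
        spec = preset(preset_name)
        base_cohort = generate(spec, seed=config.seed) if not config.fresh_cohort else None
        # rep -> (cohort seed, injection seed, detector seed), stable across grids
        rep_seeds = [
            s.generate_state(3) % (2**31)
            for s in np.random.SeedSequence(config.seed,
                                            spawn_key=(ip,)).spawn(config.n_reps)
        ]
        for types in config.error_types:
            for intensity in config.intensities:
                per_rep: dict[str, list[Metrics]] = {m: [] for m in config.methods}
                for rep in range(config.n_reps):
                    cseed, iseed, dseed = (int(x) for x in rep_seeds[rep])
                    cohort = base_cohort if base_cohort is not None else \
                        generate(spec, seed=cseed)
                    inj = inject(cohort, InjectionSpec(
                        error_types=tuple(types), intensity=intensity,
                        rate=config.rate, mode=config.mode, seed=iseed))
                    gold_cells = inj.flag_cells()
                    gold_subj = trajectory_gold(inj)
                    for method in config.methods:
                        det = _run_method(method, inj.cohort, dseed,
                                          config.method_params.get(method))
                        per_rep[method].append(
                            evaluate_detection(det, inj.cohort, gold_cells,
                                               gold_subj))
                for method in config.methods:
                    row = {
                        "preset": preset_name,
                        "measure": spec.measure,
                        "method": method,
                        "level": METHOD_LEVELS[method],
                        "error_types": _types_label(types),
                        "intensity": intensity,
                        "n_reps": config.n_reps,
                    }
                    for name in metric_names:
                        vals = np.array([getattr(m, name)
                                         for m in per_rep[method]])
                        ok = vals[~np.isnan(vals)]
                        row[f"{name}_mean"] = ok.mean() if ok.size else math.nan
                        row[f"{name}_sd"] = ok.std(ddof=1) if ok.size > 1 else math.nan
                        row[f"{name}_n_missing"] = int(np.isnan(vals).sum())
                    rows.append(row)
                if progress:
                    print(f"done: {preset_name} {_types_label(types)} "
                          f"intensity={intensity}")
    return pd.DataFrame(rows)
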