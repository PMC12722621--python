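"""Cohort construction: propensity matching, grouped splits, schedules.

Patients are matched 1:1 to controls by greedy nearest neighbor on the logit
of a logistic propensity score over age and sex (no replacement, optional
caliper in logit units). Train/validation/test splits are drawn per class
and per subject, so every image of a subject lands in the same subset and
class balance is preserved. A sampling schedule enumerates (data sampling,
weight initialization) pairs; the same seed list is reused for every
preprocessing configuration so sessions are pairwise comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phantom import SubjectRecord

__all__ = [
    "SplitSpec",
    "SamplingSchedule",
    "SessionPlan",
    "propensity_logit_match",
    "grouped_split",
    "make_schedule",
    "standardized_mean_difference",
]


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


@dataclass(frozen=True)
class SamplingSchedule:
    n_samplings: int = 10
    n_inits: int = 3

    def __post_init__(self) -> None:
        if self.n_samplings < 1 or self.n_inits < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class SessionPlan:
    sampling_index: int
    init_index: int
    sampling_seed: int
    init_seed: int


def _design_matrix(subjects: Sequence[SubjectRecord]) -> np.ndarray:
    """Intercept + age + sex, dropping covariates without variation (a
    constant column would make the design singular)."""
    cols = [np.ones(len(subjects))]
    for values in (
        np.array([s.age for s in subjects], dtype=float),
        np.array([1.0 if s.sex == "M" else 0.0 for s in subjects]),
    ):
        if np.ptp(values) > 0:
            cols.append(values)
    return np.column_stack(cols)


def propensity_logit_match(
    cases: Sequence[SubjectRecord],
    controls: Sequence[SubjectRecord],
    caliper: Optional[float] = None,
) -> list[tuple[str, str]]:
    """Greedy 1:1 nearest-neighbor matching on the propensity logit.

    The propensity model is a logistic regression of case status on age and
    sex. Cases are processed in descending logit order (hardest to match
    first); each is paired with the nearest unmatched control, skipped if no
    control lies within ``caliper`` logit units.
    """
    if not cases or not controls:
        raise ValueError("need at least one case and one control")
    subjects = list(cases) + list(controls)
    y = np.array([1.0] * len(cases) + [0.0] * len(controls))
    x = _design_matrix(subjects)
    if x.shape[1] == 1:
        # no covariate variation at all: every propensity logit is equal
        logits = np.zeros(len(subjects))
    else:
        try:
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(fit.params)):
                raise ValueError("non-finite propensity coefficients")
        except Exception as exc:  # perfect separation, singular design, ...
            raise ValueError(
                "degenerate covariates: propensity model could not be fit "
                f"({exc})"
            ) from exc
        logits = x @ fit.params
    case_logits = logits[: len(cases)]
    control_logits = logits[len(cases):]

    order = np.argsort(-case_logits, kind="stable")
    available = np.ones(len(controls), dtype=bool)
    pairs: list[tuple[str, str]] = []
    for i in order:
        if not available.any():
            break
        dist = np.abs(control_logits - case_logits[i])
        dist[~available] = np.inf
        j = int(np.argmin(dist))
        if caliper is not None and dist[j] > caliper:
            continue
        available[j] = False
        pairs.append((cases[i].subject_id, controls[j].subject_id))
    return pairs


def standardized_mean_difference(
    cases: Sequence[float], controls: Sequence[float]
) -> float:
    """Absolute standardized mean difference with pooled SD (matching
    balance diagnostic)."""
    a = np.asarray(cases, dtype=float)
    b = np.asarray(controls, dtype=float)
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / pooled)


def grouped_split(
    subjects: Sequence[SubjectRecord],
    spec: SplitSpec,
    image_counts: Optional[dict[str, int]] = None,
) -> dict[str, str]:
    """Assign each subject to train/val/test, per class, by image count.

    All images of a subject share one subset. Within each class, subjects
    are shuffled (seeded) and cut at the boundaries closest to the target
    cumulative image fractions, so image-count proportions deviate from the
    target ratios by at most one subject's images per class.
    """
    if not subjects:
        raise ValueError("no subjects to split")
    counts = image_counts or {s.subject_id: 1 for s in subjects}
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0x5B11,)))
    assignment: dict[str, str] = {}
    names = ("train", "val", "test")
    for class_label in sorted({s.class_label for s in subjects}):
        members = [s for s in subjects if s.class_label == class_label]
        if len(members) < 3:
            raise ValueError(
                f"class {class_label!r} has {len(members)} subjects; need >= 3"
            )
        perm = rng.permutation(len(members))
        ordered = [members[i] for i in perm]
        weights = np.array([counts[s.subject_id] for s in ordered], dtype=float)
        cum = np.cumsum(weights)
        total = cum[-1]
        # boundary after subject k is the k+1 prefix; pick cuts nearest the targets
        t1 = spec.ratios[0] * total
        t2 = (spec.ratios[0] + spec.ratios[1]) * total
        cut1 = int(np.argmin(np.abs(cum - t1))) + 1
        cut2 = int(np.argmin(np.abs(cum - t2))) + 1
        cut1 = min(cut1, len(ordered) - 2)
        cut2 = min(max(cut2, cut1 + 1), len(ordered) - 1)
        for k, s in enumerate(ordered):
            subset = names[0] if k < cut1 else names[1] if k < cut2 else names[2]
            assignment[s.subject_id] = subset
    return assignment


def make_schedule(
    schedule: SamplingSchedule = SamplingSchedule(),
    split_spec: SplitSpec = SplitSpec(),
) -> list[SessionPlan]:
    """Enumerate the (sampling, initialization) session grid.

    Seeds derive from the split seed alone, so two configurations trained
    under the same schedule receive identical (sampling_seed, init_seed)
    lists and their sessions pair up one-to-one.
    """
    root = np.random.SeedSequence(split_spec.seed, spawn_key=(0x5C8E,))
    sampling_seeds = [int(s) % (2**31) for s in root.generate_state(schedule.n_samplings)]
    init_seeds = [int(s) % (2**31) for s in np.random.SeedSequence(
        split_spec.seed, spawn_key=(0x1117,)
    ).generate_state(schedule.n_inits)]
    return [
        SessionPlan(i, j, sampling_seeds[i], init_seeds[j])
        for i in range(schedule.n_samplings)
        for j in range(schedule.n_inits)
    ]


def split_table(assignment: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject_id": k, "subset": v} for k, v in sorted(assignment.items())]
    )
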