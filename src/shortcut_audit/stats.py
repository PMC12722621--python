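"""Exact McNemar tests with discrete (Tarone-style) Bonferroni-Holm control.

Two models trained under the same data sampling and initialization are
compared image by image on the shared test set: the conditional exact
McNemar test looks only at discordant images (correct under exactly one
model) and refers the smaller discordant count to Binomial(n, 1/2); the
two-sided p-value doubles the smaller tail, capped at 1.

Because the tests are discrete, each carries a finite support of attainable
p-values; the step-down Holm correction counts, at every step, only the
remaining tests that could possibly fall below the current threshold
(Tarone's adjustment), which makes the correction less conservative for
small discordant counts without losing family-wise error control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .cnn import RunResult

__all__ = [
    "PairedOutcome",
    "ComparisonSpec",
    "TestRecord",
    "ComparisonReport",
    "paired_outcome",
    "mcnemar_exact",
    "discrete_holm",
    "run_family",
]

SCOPES = ("accuracy", "sensitivity", "specificity")


@dataclass(frozen=True)
class PairedOutcome:
    """2x2 cross-tabulation of per-image correctness of two models."""

    n11: int  # correct under both
    n01: int  # correct under reference only
    n10: int  # correct under alternative only
    n00: int  # correct under neither

    def __post_init__(self) -> None:
        if min(self.n11, self.n01, self.n10, self.n00) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_discordant(self) -> int:
        return self.n01 + self.n10


@dataclass(frozen=True)
class ComparisonSpec:
    alpha_level: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_level < 1.0):
            raise ValueError("alpha_level must lie in (0, 1)")


@dataclass
class TestRecord:
    config_id: str
    sampling_index: int
    init_index: int
    metric: str
    n01: int
    n10: int
    p_value: float
    min_attainable_p: float
    rejected: bool = False


@dataclass
class ComparisonReport:
    tests: list[TestRecord]
    alpha_level: float

    @property
    def n_significant(self) -> int:
        return sum(t.rejected for t in self.tests)

    def significant_by_config(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.tests:
            out.setdefault(t.config_id, 0)
            out[t.config_id] += int(t.rejected)
        return out


def paired_outcome(ref: RunResult, alt: RunResult, scope: str = "accuracy") -> PairedOutcome:
    """Cross-tabulate per-image correctness of two runs over the scoped
    subset: all test images for accuracy, true patients for sensitivity,
    true controls for specificity."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    if ref.image_ids != alt.image_ids:
        raise ValueError("runs were evaluated on different test images")
    if not np.array_equal(ref.true_labels, alt.true_labels):
        raise ValueError("runs disagree on true labels")
    keep = np.ones(len(ref.true_labels), dtype=bool)
    if scope == "sensitivity":
        keep = ref.true_labels == 1
    elif scope == "specificity":
        keep = ref.true_labels == 0
    ref_ok = (ref.predicted_labels == ref.true_labels)[keep]
    alt_ok = (alt.predicted_labels == alt.true_labels)[keep]
    return PairedOutcome(
        n11=int(np.sum(ref_ok & alt_ok)),
        n01=int(np.sum(ref_ok & ~alt_ok)),
        n10=int(np.sum(~ref_ok & alt_ok)),
        n00=int(np.sum(~ref_ok & ~alt_ok)),
    )


def _two_sided_p(k_min: int, n: int) -> float:
    return min(1.0, 2.0 * float(binom.cdf(k_min, n, 0.5)))


def mcnemar_exact(outcome: PairedOutcome) -> tuple[float, np.ndarray]:
    """Conditional exact McNemar test.

    Returns the two-sided p-value and the sorted support of attainable
    p-values over all possible discordant splits k = 0..n. With no
    discordant pairs the p-value is 1 and the support is {1}.
    """
    n = outcome.n_discordant
    if n == 0:
        return 1.0, np.array([1.0])
    k = min(outcome.n01, outcome.n10)
    p = _two_sided_p(k, n)
    support = np.unique([_two_sided_p(min(j, n - j), n) for j in range(n + 1)])
    return p, support


def discrete_holm(
    tests: Sequence[tuple[float, Sequence[float] | np.ndarray]],
    alpha: float = 0.05,
) -> list[bool]:
    """Step-down Holm with Tarone's discreteness adjustment.

    ``tests`` is a list of (p_value, attainable-p support). At each step the
    effective family size is the smallest m such that at most m of the
    remaining tests have a minimal attainable p-value <= alpha / m; the
    smallest remaining p is rejected while p <= alpha / m.
    """
    n = len(tests)
    if n == 0:
        return []
    p_values = np.array([t[0] for t in tests], dtype=float)
    p_min = np.array([float(np.min(t[1])) for t in tests])
    remaining = list(range(n))
    rejected = [False] * n
    while remaining:
        mins = p_min[remaining]
        m_eff = 1
        while np.sum(mins <= alpha / m_eff) > m_eff:
            m_eff += 1
        i_best = min(remaining, key=lambda i: p_values[i])
        if p_values[i_best] <= alpha / m_eff:
            rejected[i_best] = True
            remaining.remove(i_best)
        else:
            break
    return rejected


def run_family(
    sessions: dict[str, list[RunResult]],
    ref_config: str = "A2",
    spec: ComparisonSpec = ComparisonSpec(),
    scopes: Sequence[str] = SCOPES,
) -> ComparisonReport:
    """All (alternative configuration, aligned session pair, metric) tests
    against the reference configuration, corrected family-wide.

    Sessions pair on (sampling_index, init_index); pairs where either run is
    missing or non-converged are skipped, shrinking the family.
    """
    if ref_config not in sessions:
        raise ValueError(f"reference configuration {ref_config!r} has no sessions")
    ref_runs = {
        (r.sampling_index, r.init_index): r
        for r in sessions[ref_config]
        if r.converged
    }
    records: list[TestRecord] = []
    stats: list[tuple[float, np.ndarray]] = []
    for config_id, runs in sorted(sessions.items()):
        if config_id == ref_config:
            continue
        for alt in runs:
            if not alt.converged:
                continue
            ref = ref_runs.get((alt.sampling_index, alt.init_index))
            if ref is None:
                continue
            for scope in scopes:
                outcome = paired_outcome(ref, alt, scope)
                p, support = mcnemar_exact(outcome)
                records.append(
                    TestRecord(
                        config_id, alt.sampling_index, alt.init_index, scope,
                        outcome.n01, outcome.n10, p, float(support.min()),
                    )
                )
                stats.append((p, support))
    if not records:
        raise ValueError("no aligned converged session pairs to compare")
    for rec, rej in zip(records, discrete_holm(stats, spec.alpha_level)):
        rec.rejected = rej
    return ComparisonReport(records, spec.alpha_level)
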