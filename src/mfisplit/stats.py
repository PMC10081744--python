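"""Evaluation statistics for the discharge-destination prediction models.

Covers exact-match accuracy, relative percent improvement between model
variants, the one-tailed two-proportion Z-test (unpooled standard error)
used to compare model accuracies, per-destination coverage, mortality
recall, beta selection for the weighted single index, and the leave-one-out
high- vs low-impact comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "AccuracyResult",
    "ZTestResult",
    "accuracy",
    "percent_improvement",
    "two_prop_ztest",
    "destination_coverage",
    "mortality_recall",
    "select_beta",
    "leave_one_out_compare",
]

DEATH_LABEL = "death"


@dataclass(frozen=True)
class AccuracyResult:
    variant: str
    specialty: str
    n_test: int
    n_correct: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_test


@dataclass(frozen=True)
class ZTestResult:
    p1: float
    p2: float
    n1: int
    n2: int
    z: float
    p_one_tailed: float
    direction: str  # improvement | decline | none
    degenerate: bool = False


def accuracy(
    predictions: Sequence, labels: Sequence, variant: str = "", specialty: str = ""
) -> AccuracyResult:
    """Exact-match fraction of predicted vs recorded destinations."""
    predictions = np.asarray(predictions, dtype=object)
    labels = np.asarray(labels, dtype=object)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must have equal length")
    if len(labels) == 0:
        raise ValueError("empty test set")
    n_correct = int(np.sum(predictions == labels))
    return AccuracyResult(variant, specialty, n_test=len(labels), n_correct=n_correct)


def percent_improvement(acc_single: float, acc_split: float) -> float | None:
    """Relative accuracy gain, in percent: 100 * (acc_split / acc_single - 1).

    Returns None (not applicable) when the reference accuracy is zero.
    """
    if not 0 <= acc_single <= 1 or not 0 <= acc_split <= 1:
        raise ValueError("accuracies must lie in [0, 1]")
    if acc_single == 0:
        return None
    return 100.0 * (acc_split / acc_single - 1.0)


def two_prop_ztest(p1: float, n1: int, p2: float, n2: int) -> ZTestResult:
    """One-tailed two-proportion Z-test with unpooled (Wald) standard error.

    z = (p2 - p1) / sqrt(p1(1-p1)/n1 + p2(1-p2)/n2); the one-tailed p-value
    is the upper-tail normal probability of |z|, reported in the observed
    direction.  When both proportions are degenerate (SE = 0) no test is
    possible and p = 0.5 is flagged.
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    if se == 0.0:
        return ZTestResult(p1, p2, n1, n2, z=float("nan"), p_one_tailed=0.5,
                           direction="none", degenerate=True)
    z = (p2 - p1) / se
    p_val = float(norm.sf(abs(z)))
    direction = "improvement" if p2 > p1 else ("decline" if p2 < p1 else "none")
    return ZTestResult(p1, p2, n1, n2, z=float(z), p_one_tailed=p_val, direction=direction)


def destination_coverage(
    predictions: Sequence, labels: Sequence, present_destinations: Sequence[str]
) -> float:
    """Fraction of the dataset's destinations with >= 1 correctly predicted case."""
    predictions = np.asarray(predictions, dtype=object)
    labels = np.asarray(labels, dtype=object)
    if len(labels) == 0:
        raise ValueError("empty test set")
    if len(present_destinations) == 0:
        raise ValueError("no destinations present")
    covered = sum(
        1 for d in present_destinations
        if np.any((labels == d) & (predictions == d))
    )
    return covered / len(present_destinations)


def mortality_recall(predictions: Sequence, labels: Sequence) -> float | None:
    """Fraction of death-labelled cases predicted as death; None if no deaths."""
    predictions = np.asarray(predictions, dtype=object)
    labels = np.asarray(labels, dtype=object)
    deaths = labels == DEATH_LABEL
    if not deaths.any():
        return None
    return float(np.mean(predictions[deaths] == DEATH_LABEL))


def select_beta(per_beta_accuracies: Mapping[float, float]) -> float:
    """Beta with maximal composite accuracy; exact ties go to the smaller beta."""
    if not per_beta_accuracies:
        raise ValueError("no (beta, accuracy) pairs supplied")
    return min(
        per_beta_accuracies,
        key=lambda b: (-per_beta_accuracies[b], b),
    )


def leave_one_out_compare(
    accuracies: Mapping[str, Mapping[str, float]],
) -> dict[str, dict[str, object]]:
    """Per-specialty ordering of the single-index models.

    ``accuracies`` maps specialty -> {variant name -> accuracy}.  For each
    specialty, reports whether the high-impact-only model beats the
    low-impact-only one (the leave-one-out importance signal) and whether
    the joint split model is at least as accurate as both.
    """
    out: dict[str, dict[str, object]] = {}
    for specialty, accs in accuracies.items():
        if "high_only" not in accs or "low_only" not in accs:
            out[specialty] = {"comparable": False}
            continue
        hi, lo = accs["high_only"], accs["low_only"]
        entry: dict[str, object] = {
            "comparable": True,
            "high_only": hi,
            "low_only": lo,
            "high_dominant": hi > lo,
            "tie": hi == lo,
        }
        if "split_mfi" in accs:
            entry["split_ge_both"] = accs["split_mfi"] >= max(hi, lo)
        out[specialty] = entry
    return out
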