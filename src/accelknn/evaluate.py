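"""Minimum-majority threshold filtering and discard-aware evaluation.

A KNN classification whose confidence ``prob`` falls below the threshold is
discarded rather than reported.  Evaluation therefore distinguishes four
outcomes per test sample:

* kept and correct        -> true positive  (TP)
* kept and incorrect      -> false positive (FP)
* discarded and incorrect -> true negative  (TN)
* discarded and correct   -> false negative (FN)

Note the discard-aware twist: discarding a *correct* classification counts
against the method as a false negative.  From the single dataset-level
TP/FP/TN/FN quadruple (multiclass collapsed to correct/incorrect):

* accuracy  = (TP + TN) / (TP + FP + TN + FN)
* precision = TP / (TP + FP)
* recall    = TP / (TP + FN)

"Surpass the threshold" is implemented as ``prob >= threshold``: with k = 3
and threshold 0.9, a strict ``>`` would also discard unanimous prob = 1
votes, which is never the intent.  Metrics with zero denominators are
reported as ``None`` (an explicit not-a-value state), never silently 0 or 1 —
high thresholds can legitimately discard everything.

A threshold sweep evaluates a grid of thresholds (default 0.5 … 0.9) on the
same votes and rank-correlates each metric against the threshold with
Spearman's r (average ranks for ties; exact permutation p-value for n <= 9,
where the t-approximation is poor, t-approximation otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from accelknn.knn import NeighborVote

__all__ = [
    "Classification",
    "ConfusionCounts",
    "MetricsReport",
    "SpearmanResult",
    "SweepResult",
    "DEFAULT_THRESHOLDS",
    "apply_threshold",
    "confusion_counts",
    "accuracy",
    "precision",
    "recall",
    "metrics_report",
    "sweep",
    "spearman",
    "per_behavior_counts",
    "write_metrics_csv",
    "write_correlations_csv",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class Classification:
    """A thresholded prediction for one test sample."""

    predicted: str
    prob: float
    passed: bool
    true_label: str | None = None


@dataclass(frozen=True)
class ConfusionCounts:
    """Dataset-level discard-aware confusion quadruple."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Counts and derived metrics at one threshold; ``None`` marks an
    undefined (zero-denominator) metric."""

    threshold: float
    counts: ConfusionCounts
    accuracy: float | None
    precision: float | None
    recall: float | None
    proportion_classified: float


@dataclass(frozen=True)
class SpearmanResult:
    """Spearman rank correlation; r/p are ``None`` when rank variance is zero
    or fewer than 3 defined pairs exist."""

    r: float | None
    p: float | None
    n: int


@dataclass(frozen=True)
class SweepResult:
    reports: tuple[MetricsReport, ...]
    correlations: dict[str, SpearmanResult]


def apply_threshold(
    votes: Sequence[NeighborVote],
    threshold: float,
    truths: Sequence[str] | None = None,
) -> list[Classification]:
    """Flag (never drop) each vote by whether its prob passes the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    if truths is not None and len(truths) != len(votes):
        raise ValueError("votes and truths must have the same length")
    out = []
    for i, v in enumerate(votes):
        out.append(
            Classification(
                predicted=v.winning_label,
                prob=v.prob,
                passed=v.prob >= threshold,
                true_label=None if truths is None else truths[i],
            )
        )
    return out


def confusion_counts(
    votes: Sequence[NeighborVote],
    truths: Sequence[str],
    threshold: float,
) -> ConfusionCounts:
    """Assign each sample exactly one of TP/FP/TN/FN and count."""
    if len(votes) != len(truths):
        raise ValueError(
            f"votes ({len(votes)}) and truths ({len(truths)}) must have equal length"
        )
    if len(votes) == 0:
        raise ValueError("cannot evaluate an empty test set")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    tp = fp = tn = fn = 0
    for v, truth in zip(votes, truths):
        correct = v.winning_label == truth
        kept = v.prob >= threshold
        if kept and correct:
            tp += 1
        elif kept:
            fp += 1
        elif correct:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def accuracy(counts: ConfusionCounts) -> float | None:
    """(TP + TN) / total — overall proportion of correctly handled samples."""
    if counts.total == 0:
        return None
    return (counts.tp + counts.tn) / counts.total


def precision(counts: ConfusionCounts) -> float | None:
    """TP / (TP + FP) — proportion of kept classifications that were correct;
    ``None`` when everything was discarded."""
    kept = counts.tp + counts.fp
    if kept == 0:
        return None
    return counts.tp / kept


def recall(counts: ConfusionCounts) -> float | None:
    """TP / (TP + FN) — proportion of correct classifications that survived
    the filter; ``None`` when the classifier got nothing right."""
    correct = counts.tp + counts.fn
    if correct == 0:
        return None
    return counts.tp / correct


def metrics_report(
    votes: Sequence[NeighborVote],
    truths: Sequence[str],
    threshold: float,
) -> MetricsReport:
    c = confusion_counts(votes, truths, threshold)
    return MetricsReport(
        threshold=threshold,
        counts=c,
        accuracy=accuracy(c),
        precision=precision(c),
        recall=recall(c),
        proportion_classified=(c.tp + c.fp) / c.total,
    )


def spearman(xs: Sequence[float], ys: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with ties averaged.

    The p-value is two-sided: exact, by enumerating all n! permutations of
    one rank vector, when n <= 9; otherwise by the usual t-approximation
    with n - 2 degrees of freedom.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("xs and ys must be equal-length 1-D sequences")
    n = len(xs)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    rx = stats.rankdata(xs, method="average")
    ry = stats.rankdata(ys, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return SpearmanResult(r=None, p=None, n=n)
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    if n <= 9:
        p = _exact_permutation_p(rx, ry, r)
    else:
        t = r * math.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return SpearmanResult(r=r, p=min(1.0, p), n=n)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Two-sided exact p: share of permutations of ry with |r| >= |r_obs|."""
    n = len(rx)
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    num = ryc @ rxc
    den = math.sqrt((rxc**2).sum()) * np.sqrt((ryc**2).sum(axis=1))
    rs = num / den
    return float(np.mean(np.abs(rs) >= abs(r_obs) - 1e-12))


_METRIC_NAMES = ("proportion_classified", "accuracy", "precision", "recall")


def sweep(
    votes: Sequence[NeighborVote],
    truths: Sequence[str],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> SweepResult:
    """Evaluate the same votes at every threshold and rank-correlate each
    metric against the threshold grid."""
    thresholds = tuple(float(t) for t in thresholds)
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    if any(not 0.0 <= t <= 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    reports = tuple(metrics_report(votes, truths, t) for t in thresholds)
    correlations: dict[str, SpearmanResult] = {}
    for name in _METRIC_NAMES:
        pairs = [
            (rep.threshold, getattr(rep, name))
            for rep in reports
            if getattr(rep, name) is not None
        ]
        if len(pairs) < 3:
            correlations[name] = SpearmanResult(r=None, p=None, n=len(pairs))
        else:
            correlations[name] = spearman([p[0] for p in pairs], [p[1] for p in pairs])
    return SweepResult(reports=reports, correlations=correlations)


def per_behavior_counts(
    votes: Sequence[NeighborVote],
    truths: Sequence[str],
    threshold: float,
    behavior: str,
) -> ConfusionCounts:
    """One-vs-rest diagnostic quadruple for a single behaviour.

    Conventional one-vs-rest on the kept classifications, with discarded
    samples counted as predicted-negative.  This is a diagnostic view; the
    headline metrics use the dataset-level quadruple.
    """
    if len(votes) != len(truths):
        raise ValueError("votes and truths must have equal length")
    tp = fp = tn = fn = 0
    for v, truth in zip(votes, truths):
        pred_pos = v.prob >= threshold and v.winning_label == behavior
        is_pos = truth == behavior
        if pred_pos and is_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif is_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _fmt(v: float | None) -> str | float:
    return "NA" if v is None else v


def write_metrics_csv(result: SweepResult, path: str | Path) -> Path:
    """One row per threshold: counts plus derived metrics (NA = undefined)."""
    rows = [
        {
            "threshold": rep.threshold,
            "TP": rep.counts.tp,
            "FP": rep.counts.fp,
            "TN": rep.counts.tn,
            "FN": rep.counts.fn,
            "proportion_classified": rep.proportion_classified,
            "accuracy": _fmt(rep.accuracy),
            "precision": _fmt(rep.precision),
            "recall": _fmt(rep.recall),
        }
        for rep in result.reports
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_correlations_csv(result: SweepResult, path: str | Path) -> Path:
    """One row per metric: Spearman r and p against the threshold grid."""
    rows = [
        {"metric": name, "r": _fmt(sr.r), "p": _fmt(sr.p), "n": sr.n}
        for name, sr in result.correlations.items()
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
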