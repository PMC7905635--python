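"""Performance metrics and paired classifier comparison.

Accuracy, sensitivity and specificity follow the usual confusion-matrix
closed forms: (TP+TN)/N, TP/(TP+FN), TN/(TN+FP). With coding as the
positive class, sensitivity is the fraction of truly coding ORFs
recovered and specificity the fraction of intergenic ORFs correctly
rejected. A metric whose denominator is zero is *undefined* and reported
as ``None``, never silently 0.

AUC uses the Mann-Whitney formulation: the probability a random positive
outscores a random negative, ties worth one half.

McNemar's test compares two predictors on paired per-instance correctness:
only the discordant pairs matter (b = A right, B wrong; c = the reverse).
With b + c >= 25 the continuity-corrected chi-square statistic
(|b-c|-1)^2/(b+c) on 1 df is used; below that, the exact two-sided
binomial(b; b+c, 1/2) test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError

POSITIVE = "coding"
NEGATIVE = "intergenic"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")
        if self.total < 1:
            raise EvaluationError("confusion counts must sum to >= 1")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    predicted_labels: Sequence[str], true_labels: Sequence[str]
) -> ConfusionCounts:
    """Count TP/TN/FP/FN with 'coding' as the positive class."""
    if len(predicted_labels) != len(true_labels):
        raise EvaluationError(
            f"length mismatch: {len(predicted_labels)} predictions vs "
            f"{len(true_labels)} truths"
        )
    if len(true_labels) == 0:
        raise EvaluationError("need at least one instance")
    valid = {POSITIVE, NEGATIVE}
    tp = tn = fp = fn = 0
    for p, t in zip(predicted_labels, true_labels):
        if p not in valid or t not in valid:
            raise EvaluationError(f"labels must be in {sorted(valid)}; got ({p!r}, {t!r})")
        if t == POSITIVE:
            tp += p == POSITIVE
            fn += p != POSITIVE
        else:
            tn += p == NEGATIVE
            fp += p != NEGATIVE
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(cc: ConfusionCounts) -> float:
    return (cc.tp + cc.tn) / cc.total


def sensitivity(cc: ConfusionCounts) -> float | None:
    """TP/(TP+FN); None when no positive instances exist."""
    denom = cc.tp + cc.fn
    return None if denom == 0 else cc.tp / denom


def specificity(cc: ConfusionCounts) -> float | None:
    """TN/(TN+FP); None when no negative instances exist."""
    denom = cc.tn + cc.fp
    return None if denom == 0 else cc.tn / denom


def auc(scores: Sequence[float], true_labels: Sequence[str]) -> float:
    """Mann-Whitney AUC of ``scores`` against coding/intergenic truth."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(true_labels):
        raise EvaluationError("scores and labels differ in length")
    if not np.isfinite(scores).all():
        raise EvaluationError("scores must be finite")
    y = np.array([t == POSITIVE for t in true_labels])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC requires both classes present")
    ranks = stats.rankdata(scores)  # average ranks give ties 1/2 credit
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    auc: float | None


def metrics_report(
    predicted_labels: Sequence[str],
    true_labels: Sequence[str],
    scores: Sequence[float] | None = None,
) -> MetricsReport:
    cc = confusion(predicted_labels, true_labels)
    a = None
    if scores is not None:
        try:
            a = auc(scores, true_labels)
        except EvaluationError:
            a = None
    return MetricsReport(accuracy(cc), sensitivity(cc), specificity(cc), a)


@dataclass(frozen=True)
class McNemarResult:
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    statistic: float | None  # chi-square statistic; None when exact test used
    p_value: float
    exact: bool
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def mcnemar(
    outcomes_a: Sequence[bool],
    outcomes_b: Sequence[bool],
    alpha: float = 0.01,
    exact_threshold: int = 25,
) -> McNemarResult:
    """Paired McNemar test on per-instance correctness vectors.

    Continuity-corrected chi-square on 1 df when b + c >= exact_threshold,
    else the exact two-sided binomial test. b + c = 0 yields p = 1.
    """
    if len(outcomes_a) != len(outcomes_b):
        raise EvaluationError("paired outcome vectors differ in length")
    a = np.asarray(outcomes_a, dtype=bool)
    bv = np.asarray(outcomes_b, dtype=bool)
    b = int((a & ~bv).sum())
    c = int((~a & bv).sum())
    n = b + c
    if n == 0:
        return McNemarResult(b, c, None, 1.0, True, alpha)
    if n >= exact_threshold:
        statistic = (abs(b - c) - 1) ** 2 / n
        p = float(stats.chi2.sf(statistic, df=1))
        return McNemarResult(b, c, float(statistic), p, False, alpha)
    p = float(stats.binomtest(b, n, 0.5, alternative="two-sided").pvalue)
    return McNemarResult(b, c, None, p, True, alpha)


def contingency_table(
    outcomes_a: Sequence[bool], outcomes_b: Sequence[bool]
) -> pd.DataFrame:
    """2x2 correct/wrong table with marginals for two paired predictors."""
    a = np.asarray(outcomes_a, dtype=bool)
    bv = np.asarray(outcomes_b, dtype=bool)
    if a.shape != bv.shape:
        raise EvaluationError("paired outcome vectors differ in length")
    tbl = pd.DataFrame(
        [
            [int((a & bv).sum()), int((a & ~bv).sum())],
            [int((~a & bv).sum()), int((~a & ~bv).sum())],
        ],
        index=["A correct", "A wrong"],
        columns=["B correct", "B wrong"],
    )
    tbl["total"] = tbl.sum(axis=1)
    tbl.loc["total"] = tbl.sum(axis=0)
    return tbl


def report_frame(rows: dict[str, MetricsReport]) -> pd.DataFrame:
    """One row per predictor with acc/sens/spec/auc columns."""
    return pd.DataFrame(
        {
            name: {
                "accuracy": r.accuracy,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "auc": r.auc,
            }
            for name, r in rows.items()
        }
    ).T.rename_axis("predictor")


def write_report(rows: dict[str, MetricsReport], path: str | Path) -> None:
    report_frame(rows).to_csv(path, sep="\t", na_rep="NA")
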