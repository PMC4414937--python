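"""Single-feature classification performance: confusion metrics, ROC/AUC,
and Welch t-tests.

The malignant class is the positive class throughout.  By convention every
shape feature here is "malignant-high": spiculated, irregular boundaries give
larger values, so a score at or above the operating threshold is called
malignant.  The operating threshold reported for each feature maximizes
Youden's J (sensitivity + specificity - 1) on the evaluated sample itself —
a resubstitution estimate, and therefore optimistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LabeledScores",
    "ConfusionCounts",
    "RocResult",
    "binary_metrics",
    "classify_by_threshold",
    "roc_auc",
    "welch_t_test",
    "evaluate_cohort",
    "evaluate_all",
]

BENIGN, MALIGNANT = "benign", "malignant"


@dataclass
class LabeledScores:
    """Per-case scores with benign/malignant labels.

    ``direction="high"`` means larger scores indicate malignancy (the default
    for all contour features); ``"low"`` flips the comparison.
    """

    scores: np.ndarray
    labels: np.ndarray  # strings "benign" / "malignant"
    direction: str = "high"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if len(self.scores) != len(self.labels):
            raise ValueError("scores and labels must have equal length")
        if self.direction not in ("high", "low"):
            raise ValueError("direction must be 'high' or 'low'")

    @property
    def is_malignant(self) -> np.ndarray:
        return self.labels == MALIGNANT

    def both_classes_present(self) -> bool:
        m = self.is_malignant
        return bool(m.any() and (~m).any())


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    youden_threshold: float


def binary_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as percentages.

    Sensitivity is the malignant detection rate TP/(TP+FN); specificity the
    benign detection rate TN/(TN+FP).
    """
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("undefined metric: one class has no cases")
    acc = 100.0 * (c.tp + c.tn) / c.total
    sens = 100.0 * c.tp / (c.tp + c.fn)
    spec = 100.0 * c.tn / (c.tn + c.fp)
    return acc, sens, spec


def classify_by_threshold(data: LabeledScores, threshold: float) -> ConfusionCounts:
    """Threshold the scores into benign/malignant calls.

    Malignant-high direction calls a case positive when its score is >= the
    threshold (ties go to positive); malignant-low uses <=.
    """
    if not data.both_classes_present():
        raise ValueError("both classes must be present")
    if data.direction == "high":
        positive = data.scores >= threshold
    else:
        positive = data.scores <= threshold
    m = data.is_malignant
    return ConfusionCounts(
        tp=int(np.sum(positive & m)),
        tn=int(np.sum(~positive & ~m)),
        fp=int(np.sum(positive & ~m)),
        fn=int(np.sum(~positive & m)),
    )


def roc_auc(data: LabeledScores) -> RocResult:
    """ROC sweep over the unique scores plus AUC.

    AUC equals the probability that a random malignant case outscores a
    random benign one (ties count 1/2) — computed from average ranks, which
    matches the all-pairs concordance count exactly.  The Youden threshold
    maximizes tpr - fpr; ties resolve to the lowest threshold.
    """
    if not data.both_classes_present():
        raise ValueError("both classes must be present for ROC analysis")
    s = data.scores if data.direction == "high" else -data.scores
    m = data.is_malignant
    n_pos, n_neg = int(m.sum()), int((~m).sum())

    ranks = stats.rankdata(s)
    auc = (ranks[m].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.unique(s)
    # predict positive when s >= t; sweep from all-positive to all-negative
    tpr = np.array([(s[m] >= t).mean() for t in thresholds])
    fpr = np.array([(s[~m] >= t).mean() for t in thresholds])
    j = tpr - fpr
    best = int(np.flatnonzero(j == j.max())[0])  # lowest threshold on ties
    youden = thresholds[best]
    if data.direction == "low":
        thresholds, youden = -thresholds, -youden
    return RocResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=float(auc),
        youden_threshold=float(youden),
    )


def welch_t_test(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test; returns (t, p).

    Identical constant groups return (0, 1) by convention; constant groups
    with different means have no defined statistic and raise.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("degenerate input: zero variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def evaluate_cohort(
    table: pd.DataFrame, feature_name: str, mode: str, direction: str = "high"
) -> dict:
    """One report row for a feature/mode: AUC, Youden-threshold confusion
    metrics, and the benign-vs-malignant Welch p-value.

    ``table`` needs columns ``mode``, ``label`` and the feature itself.
    """
    sub = table[table["mode"] == mode]
    if feature_name not in sub.columns:
        raise KeyError(f"feature {feature_name!r} not in table")
    if sub[feature_name].isna().any():
        raise ValueError(f"feature {feature_name!r} missing for some cases")
    data = LabeledScores(
        scores=sub[feature_name].to_numpy(),
        labels=sub["label"].to_numpy(),
        direction=direction,
    )
    roc = roc_auc(data)
    counts = classify_by_threshold(data, roc.youden_threshold)
    acc, sens, spec = binary_metrics(counts)
    mal = sub.loc[sub["label"] == MALIGNANT, feature_name].to_numpy()
    ben = sub.loc[sub["label"] == BENIGN, feature_name].to_numpy()
    t, p = welch_t_test(mal, ben)
    return {
        "feature": feature_name,
        "mode": mode,
        "n": len(sub),
        "accuracy_pct": acc,
        "sensitivity_pct": sens,
        "specificity_pct": spec,
        "auc": roc.auc,
        "youden_threshold": roc.youden_threshold,
        "t": t,
        "p": p,
    }


def evaluate_all(
    table: pd.DataFrame,
    features: tuple[str, ...] = ("tc", "nrl_m", "nrl_std", "ar", "ri", "sdd"),
    modes: tuple[str, ...] = ("full", "half"),
) -> pd.DataFrame:
    """Feature-by-mode performance report (one row per feature and mode)."""
    rows = [evaluate_cohort(table, f, m) for f in features for m in modes]
    return pd.DataFrame(rows)
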