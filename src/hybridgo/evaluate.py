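"""Performance metrics for annotation classifiers.

Covers the full battery used to compare classifier families and feature
sets: AUROC and AUPRC from predicted probabilities, thresholded precision /
recall / accuracy / F1 / Matthews correlation coefficient, confusion counts
at a fixed threshold, sensitivity (TPR) as a function of the classification
threshold, random-forest impurity-decrease feature importances, and Pearson
agreement between classifier pairs on confidently annotated genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "EvalReport",
    "compute_metrics",
    "confusion_at",
    "tpr_curve",
    "mean_tpr",
    "evaluate_bootstraps",
    "BootstrapEval",
    "feature_importance",
    "agreement",
]


def _align(
    probs: pd.Series, labels: pd.Series, require_both_classes: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    probs = pd.Series(probs)
    labels = pd.Series(labels)
    if set(probs.index) != set(labels.index):
        raise ValueError("probabilities and labels must cover the same genes")
    labels = labels.loc[probs.index]
    y = labels.to_numpy()
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if require_both_classes and len(set(np.unique(y))) < 2:
        raise ValueError("both classes must be present to evaluate")
    return probs.to_numpy(dtype=float), y.astype(int)


def confusion_at(
    probs: pd.Series, labels: pd.Series, threshold: float = 0.75
) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) with predicted-positive defined as prob >= threshold."""
    p, y = _align(probs, labels)
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return tp, fp, fn, tn


def _mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is 0."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass
class EvalReport:
    """The full metric battery for one probability/label table."""

    auroc: float
    auprc: float
    precision: float
    recall: float
    accuracy: float
    f1: float
    mcc: float
    n_pos: int
    n_neg: int
    threshold: float
    confusion: tuple[int, int, int, int]  # (TP, FP, FN, TN)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "auroc": self.auroc,
                "auprc": self.auprc,
                "precision": self.precision,
                "recall": self.recall,
                "accuracy": self.accuracy,
                "f1": self.f1,
                "mcc": self.mcc,
                "n_pos": self.n_pos,
                "n_neg": self.n_neg,
                "threshold": self.threshold,
            }
        )


def compute_metrics(
    probs: pd.Series, labels: pd.Series, threshold: float = 0.5
) -> EvalReport:
    """Compute the full battery: ranking metrics plus thresholded metrics.

    AUROC uses trapezoidal integration with rank-based tie handling; AUPRC
    is the step-integrated precision–recall area (average precision).
    Thresholded metrics use prob >= threshold; ill-defined ratios (zero
    denominator) are reported as 0.
    """
    p, y = _align(probs, labels, require_both_classes=True)
    auroc = float(roc_auc_score(y, p))
    auprc = float(average_precision_score(y, p))
    tp, fp, fn, tn = confusion_at(pd.Series(p), pd.Series(y), threshold)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = (tp + tn) / (tp + fp + fn + tn)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(
        auroc=auroc,
        auprc=auprc,
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        f1=f1,
        mcc=_mcc(tp, fp, fn, tn),
        n_pos=int(y.sum()),
        n_neg=int((1 - y).sum()),
        threshold=threshold,
        confusion=(tp, fp, fn, tn),
    )


@dataclass
class BootstrapEval:
    """Per-iteration metrics, their mean, and pooled-prediction metrics.

    The headline numbers are the mean of the per-iteration metrics; the
    pooled variant (all iterations' out-of-fold predictions evaluated as one
    table) is also provided and labeled distinctly.
    """

    per_iteration: list[EvalReport]
    mean: pd.Series
    pooled: EvalReport


def evaluate_bootstraps(
    probs: dict[int, pd.Series],
    labels: dict[int, pd.Series],
    threshold: float = 0.5,
) -> BootstrapEval:
    """Evaluate a bootstrap regime's out-of-fold predictions."""
    reports = [
        compute_metrics(probs[b], labels[b], threshold) for b in sorted(probs)
    ]
    mean = pd.concat([r.to_series() for r in reports], axis=1).mean(axis=1)
    pooled_p = pd.concat(
        [probs[b].rename(lambda g, _b=b: f"{_b}:{g}") for b in sorted(probs)]
    )
    pooled_y = pd.concat(
        [labels[b].rename(lambda g, _b=b: f"{_b}:{g}") for b in sorted(labels)]
    )
    pooled = compute_metrics(pooled_p, pooled_y, threshold)
    return BootstrapEval(per_iteration=reports, mean=mean, pooled=pooled)


# ---------------------------------------------------------------------------
# TPR-vs-threshold curves
# ---------------------------------------------------------------------------


def tpr_curve(
    probs: pd.Series, positive_ids: list[str], thresholds: list[float]
) -> pd.Series:
    """Sensitivity TPR(t) = |positives with prob >= t| / |positives|.

    ``thresholds`` must be sorted ascending; the curve is non-increasing.
    """
    positive_ids = list(positive_ids)
    if not positive_ids:
        raise ValueError("positive set must be nonempty")
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    missing = [g for g in positive_ids if g not in probs.index]
    if missing:
        raise ValueError(f"positives missing from prediction table: {missing[:5]}")
    p = probs.loc[positive_ids].to_numpy(dtype=float)
    return pd.Series(
        [float(np.mean(p >= t)) for t in thresholds], index=thresholds, name="tpr"
    )


def mean_tpr(
    probs: pd.Series,
    positive_ids: list[str],
    thresholds: list[float],
    interval: tuple[float, float] | None = None,
) -> float:
    """Mean TPR over the requested thresholds (optionally windowed).

    Used for cross-model sensitivity comparisons over a threshold band,
    e.g. the mean sensitivity over classification thresholds 0.3–0.5.
    """
    curve = tpr_curve(probs, positive_ids, thresholds)
    if interval is not None:
        lo, hi = interval
        curve = curve[(curve.index >= lo) & (curve.index <= hi)]
        if curve.empty:
            raise ValueError(f"no thresholds inside interval [{lo}, {hi}]")
    return float(curve.mean())


# ---------------------------------------------------------------------------
# feature importance
# ---------------------------------------------------------------------------


def feature_importance(
    models: list, feature_names: list[str]
) -> pd.DataFrame:
    """Mean impurity-decrease importances across random-forest models.

    Per model, scikit-learn's impurity-decrease importances sum to 1; the
    report gives per-feature mean and standard deviation over models.
    """
    if not models:
        raise ValueError("no models given")
    rows = []
    for m in models:
        if not isinstance(m, RandomForestClassifier):
            raise TypeError(
                f"feature importance requires random-forest models, got {type(m).__name__}"
            )
        rows.append(m.feature_importances_)
    arr = np.vstack(rows)
    if arr.shape[1] != len(feature_names):
        raise ValueError("feature_names length does not match model width")
    return pd.DataFrame(
        {
            "mean_importance": arr.mean(axis=0),
            "sd": arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else 0.0,
        },
        index=feature_names,
    ).sort_values("mean_importance", ascending=False)


# ---------------------------------------------------------------------------
# inter-classifier agreement
# ---------------------------------------------------------------------------


def agreement(
    preds_a: pd.Series,
    preds_b: pd.Series,
    upper: float = 0.6,
    lower: float = 0.4,
) -> tuple[float, int]:
    """Pearson r between two classifiers over confidently annotated genes.

    A gene is retained iff its mean probability is > ``upper`` or < ``lower``
    in *both* tables.  Returns (r, number of retained genes); fewer than 3
    retained genes is an error.
    """
    shared = [g for g in preds_a.index if g in set(preds_b.index)]
    a = preds_a.loc[shared].astype(float)
    b = preds_b.loc[shared].astype(float)
    conf = ((a > upper) | (a < lower)) & ((b > upper) | (b < lower))
    a, b = a[conf], b[conf]
    if len(a) < 3:
        raise ValueError(
            f"fewer than 3 genes confidently annotated by both classifiers ({len(a)})"
        )
    r = float(stats.pearsonr(a.to_numpy(), b.to_numpy()).statistic)
    return r, int(len(a))
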