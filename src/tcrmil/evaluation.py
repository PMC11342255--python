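"""Classifier evaluation: confusion-matrix metrics, ROC/PRC, health score,
and the two rank-based statistical tests used alongside the model.

Metric conventions: positive = cancer-related immune status.  Accuracy,
sensitivity (recall), specificity, precision and F1 are computed exactly
from the confusion counts; metrics with a zero denominator are reported as
NaN with a warning rather than silently coerced to 0.  The health score of a
sample is 1 minus its predicted cancer probability; values below 0.5 flag an
immune status that warrants attention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as skm


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class HealthScore:
    """1 - cancer score; below 0.5 the immune status warrants attention."""

    value: float
    needs_attention: bool


@dataclass
class EvaluationReport:
    counts: ConfusionCounts
    metrics: Metrics
    roc: dict  # fpr, tpr, thresholds, auc
    prc: dict  # precision, recall, thresholds, auprc
    cancer_scores: np.ndarray
    health_scores: np.ndarray
    labels: np.ndarray
    threshold: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "threshold": self.threshold,
            "confusion": self.counts.__dict__,
            "metrics": self.metrics.as_dict(),
            "roc_auc": self.roc["auc"],
            "prc_auc": self.prc["auc"],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def confusion(labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with prediction = score > threshold."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if labels.size == 0:
        raise ValueError("cannot evaluate an empty sample set")
    pred = scores > threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity, precision and F1 from counts."""
    acc = _safe_div(c.TP + c.TN, c.n, "accuracy")
    sens = _safe_div(c.TP, c.TP + c.FN, "sensitivity")
    spec = _safe_div(c.TN, c.TN + c.FP, "specificity")
    prec = _safe_div(c.TP, c.TP + c.FP, "precision")
    if np.isnan(prec) or np.isnan(sens) or prec + sens == 0:
        warnings.warn("f1 undefined; reporting NaN", stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return Metrics(accuracy=acc, sensitivity=sens, specificity=spec, precision=prec, f1=f1)


def roc_prc(labels: Sequence[int], scores: Sequence[float]) -> tuple[dict, dict]:
    """ROC and precision-recall curves with their areas.

    ROC area by trapezoid over the threshold sweep (equal scores grouped);
    PRC area by the step interpolation (average precision).  Requires both
    classes to be present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC/PRC need both classes present")
    fpr, tpr, roc_thr = skm.roc_curve(labels, scores)
    auc = float(skm.auc(fpr, tpr))
    prec, rec, prc_thr = skm.precision_recall_curve(labels, scores)
    auprc = float(skm.average_precision_score(labels, scores))
    roc = {"fpr": fpr, "tpr": tpr, "thresholds": roc_thr, "auc": auc}
    prc = {"precision": prec, "recall": rec, "thresholds": prc_thr, "auc": auprc}
    return roc, prc


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve."""
    roc, _ = roc_prc(labels, scores)
    return roc["auc"]


def health_score(cancer_score: float) -> HealthScore:
    """Health score = 1 - cancer score; < 0.5 flags an at-risk status."""
    if not 0.0 <= cancer_score <= 1.0:
        raise ValueError("cancer score must lie in [0, 1]")
    value = 1.0 - cancer_score
    return HealthScore(value=value, needs_attention=value < 0.5)


def evaluate(
    labels: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
) -> EvaluationReport:
    """Full binary evaluation of per-sample cancer scores."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    c = confusion(labels, scores, threshold)
    roc, prc = roc_prc(labels, scores)
    return EvaluationReport(
        counts=c,
        metrics=metrics(c),
        roc=roc,
        prc=prc,
        cancer_scores=scores,
        health_scores=1.0 - scores,
        labels=labels,
        threshold=threshold,
    )


def multiclass_report(
    labels: Sequence[int],
    scores: np.ndarray,
    n_classes: int | None = None,
) -> dict:
    """One-vs-rest metrics per class plus the full confusion matrix.

    ``scores`` are un-normalised per-class scores (n, C); decisions are
    argmax with ties to the lowest class index.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    C = n_classes or scores.shape[1]
    decisions = scores.argmax(axis=1)
    cm = np.zeros((C, C), dtype=int)
    for t, p in zip(labels, decisions):
        cm[t, p] += 1
    per_class = {}
    for c in range(C):
        counts = ConfusionCounts(
            TP=int(cm[c, c]),
            FN=int(cm[c].sum() - cm[c, c]),
            FP=int(cm[:, c].sum() - cm[c, c]),
            TN=int(cm.sum() - cm[c].sum() - cm[:, c].sum() + cm[c, c]),
        )
        per_class[c] = metrics(counts)
    macro = {
        name: float(np.nanmean([m.as_dict()[name] for m in per_class.values()]))
        for name in ("accuracy", "sensitivity", "specificity", "precision", "f1")
    }
    return {
        "confusion_matrix": cm,
        "accuracy": float(np.mean(decisions == labels)),
        "per_class": per_class,
        "macro": macro,
        "decisions": decisions,
    }


# ---------------------------------------------------------------------------
# statistical tests


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples of at least 3 values")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def significance_stars(p: float) -> str:
    """ns for p > 0.05; then * / ** / *** at 0.05 / 0.01 / 0.001."""
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    return "***"


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, str]:
    """Mann-Whitney U (tie-corrected, two-sided) with significance stars.

    The returned U counts pairs where an ``a`` value exceeds a ``b`` value
    (ties half-weighted), i.e. the statistic for the first group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), significance_stars(float(res.pvalue))


# ---------------------------------------------------------------------------
# writers


def write_curves_csv(report: EvaluationReport, out_dir: str | Path) -> None:
    """Curves as CSV (threshold, x, y) plus the confusion matrix."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    roc = report.roc
    n = len(roc["fpr"])
    thr = np.concatenate([[np.inf], roc["thresholds"]])[:n] if len(roc["thresholds"]) < n else roc["thresholds"][:n]
    pd.DataFrame({"threshold": thr, "fpr": roc["fpr"], "tpr": roc["tpr"]}).to_csv(
        out_dir / "roc.csv", index=False
    )
    prc = report.prc
    m = len(prc["precision"])
    pthr = np.concatenate([prc["thresholds"], [np.inf]])[:m]
    pd.DataFrame({"threshold": pthr, "recall": prc["recall"], "precision": prc["precision"]}).to_csv(
        out_dir / "prc.csv", index=False
    )
    c = report.counts
    pd.DataFrame(
        [[c.TN, c.FP], [c.FN, c.TP]],
        index=["true_0", "true_1"],
        columns=["pred_0", "pred_1"],
    ).to_csv(out_dir / "confusion.csv")
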