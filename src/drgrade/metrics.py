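"""Evaluation: one-vs-rest class metrics, ROC/AUC, folds and ablation.

For a five-class grader each class c is scored one-vs-rest from its
TP/TN/FP/FN counts:

    accuracy_c    = (TP + TN) / N        specificity_c = TN / (TN + FP)
    precision_c   = TP / (TP + FP)       sensitivity_c = TP / (TP + FN)
    F1_c          = 2 * precision * sensitivity / (precision + sensitivity)

reported per class plus their unweighted macro mean, with the headline
multiclass accuracy = trace(confusion) / N. AUC is the area under the
threshold-swept ROC curve, equal to the probability that a random
positive is scored above a random negative (ties half-credited).
Referable disease is grade 2 or higher; its score is p2 + p3 + p4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from drgrade.io import DatasetManifest, ICDR_CLASS_NAMES, N_CLASSES

logger = logging.getLogger("drgrade")

METRIC_NAMES = ("accuracy", "specificity", "precision", "sensitivity", "f1")


@dataclass
class ClassCounts:
    """Per-class one-vs-rest confusion counts; each row sums to N."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])


@dataclass
class MetricsSummary:
    per_class: pd.DataFrame          # one row per class, METRIC_NAMES columns
    macro: dict[str, float]
    overall_accuracy: float
    confusion: np.ndarray
    confusion_normalized: np.ndarray
    per_class_auc: Optional[np.ndarray] = None
    macro_auc: Optional[float] = None
    adjacent_error_fraction: Optional[float] = None


def confusion_matrix(truth: Sequence[int], predicted: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Raw and row-normalized 5x5 confusion matrices (rows = truth)."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    raw = skm.confusion_matrix(truth, predicted, labels=list(range(N_CLASSES)))
    row_sums = raw.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, raw / row_sums, 0.0)
    return raw, norm


def one_vs_rest_counts(matrix: np.ndarray) -> ClassCounts:
    """TP/TN/FP/FN per class from a square confusion matrix."""
    matrix = np.asarray(matrix)
    if matrix.shape != (N_CLASSES, N_CLASSES):
        raise ValueError("expected a 5x5 confusion matrix")
    total = matrix.sum()
    tp = np.diag(matrix).astype(int)
    fp = matrix.sum(axis=0) - tp
    fn = matrix.sum(axis=1) - tp
    tn = total - tp - fp - fn
    return ClassCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def summary_metrics(counts: ClassCounts,
                    class_names: Sequence[str] = ICDR_CLASS_NAMES) -> MetricsSummary:
    """One-vs-rest metrics per class plus unweighted macro means.

    Classes with a zero denominator leave that metric undefined (NaN);
    undefined values are excluded from the macro mean and logged.
    """
    n = counts.tp + counts.tn + counts.fp + counts.fn
    if int(n.sum()) == 0:
        raise ValueError("all-zero counts")

    def safe_div(num, den):
        num = num.astype(float)
        den = den.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)

    acc = safe_div(counts.tp + counts.tn, n)
    spec = safe_div(counts.tn, counts.tn + counts.fp)
    prec = safe_div(counts.tp, counts.tp + counts.fp)
    sens = safe_div(counts.tp, counts.tp + counts.fn)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(prec + sens > 0, 2 * prec * sens / (prec + sens), np.nan)
    per_class = pd.DataFrame(
        {"class": list(class_names), "accuracy": acc, "specificity": spec,
         "precision": prec, "sensitivity": sens, "f1": f1}
    )
    macro = {}
    for name in METRIC_NAMES:
        vals = per_class[name].to_numpy()
        defined = vals[~np.isnan(vals)]
        if len(defined) < len(vals):
            logger.info("metric %s undefined for %d class(es); excluded from macro",
                        name, len(vals) - len(defined))
        macro[name] = float(defined.mean()) if len(defined) else float("nan")
    overall = float(counts.tp.sum() / n[0])
    raw = np.zeros((N_CLASSES, N_CLASSES), dtype=int)  # placeholder when built from counts
    return MetricsSummary(per_class=per_class, macro=macro, overall_accuracy=overall,
                          confusion=raw, confusion_normalized=raw.astype(float))


def roc_auc(truth: Sequence[int], scores: Sequence[float]) -> tuple[float, np.ndarray, np.ndarray]:
    """Binary AUC (Mann-Whitney with tie half-credit) plus ROC curve points."""
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(truth)) < 2:
        raise ValueError("roc_auc needs both positive and negative labels")
    fpr, tpr, _ = skm.roc_curve(truth, scores, drop_intermediate=False)
    auc = float(skm.roc_auc_score(truth, scores))
    return auc, fpr, tpr


def multiclass_auc(truth: Sequence[int], probs: np.ndarray) -> tuple[np.ndarray, float]:
    """One-vs-rest AUC per class plus the unweighted macro mean.

    Classes absent from the truth leave an undefined (NaN) AUC that is
    excluded from the macro mean.
    """
    truth = np.asarray(truth, dtype=int)
    probs = np.asarray(probs, dtype=float)
    aucs = np.full(N_CLASSES, np.nan)
    for c in range(N_CLASSES):
        binary = (truth == c).astype(int)
        if 0 < binary.sum() < len(binary):
            aucs[c], _, _ = roc_auc(binary, probs[:, c])
    defined = aucs[~np.isnan(aucs)]
    macro = float(defined.mean()) if len(defined) else float("nan")
    return aucs, macro


def referable_binarize(grades: Sequence[int],
                       probs: Optional[np.ndarray] = None) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Referable disease = grade 2 or higher; score = p2 + p3 + p4."""
    grades = np.asarray(grades, dtype=int)
    labels = (grades >= 2).astype(int)
    scores = None
    if probs is not None:
        scores = np.asarray(probs, dtype=float)[:, 2:].sum(axis=1)
    return labels, scores


def adjacent_error_fraction(truth: Sequence[int], predicted: Sequence[int]) -> float:
    """Among misclassifications, the fraction that are one grade off."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    errors = truth != predicted
    if not errors.any():
        return float("nan")
    return float((np.abs(truth - predicted)[errors] == 1).mean())


def evaluate_predictions(truth: Sequence[int], predicted: Sequence[int],
                         probs: Optional[np.ndarray] = None) -> MetricsSummary:
    """Full summary from labels (and optionally probabilities for AUC)."""
    raw, norm = confusion_matrix(truth, predicted)
    counts = one_vs_rest_counts(raw)
    summary = summary_metrics(counts)
    summary.confusion = raw
    summary.confusion_normalized = norm
    summary.adjacent_error_fraction = adjacent_error_fraction(truth, predicted)
    if probs is not None:
        summary.per_class_auc, summary.macro_auc = multiclass_auc(truth, probs)
    return summary


# ---------------------------------------------------------------------------
# Five-fold worst case and ablation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold: int
    summary: MetricsSummary
    worst: bool = False


def stratified_folds(manifest: DatasetManifest, k: int, seed: int) -> list[list[str]]:
    """Seeded stratified k-fold partition of the source-origin record ids."""
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for c in range(N_CLASSES):
        recs = [r for r in manifest.records if r.grade == c]
        if 0 < len(recs) < k:
            logger.warning("class %s has %d records (< %d folds); uneven fold coverage",
                           ICDR_CLASS_NAMES[c], len(recs), k)
        perm = rng.permutation(len(recs))
        for i, j in enumerate(perm):
            folds[i % k].append(recs[j].id)
    return folds


def kfold_worst(manifest: DatasetManifest, k: int, seed: int,
                run_fold: Callable[[int, DatasetManifest], tuple[np.ndarray, np.ndarray, np.ndarray]],
                auxiliary: Optional[DatasetManifest] = None) -> list[FoldResult]:
    """Five-fold cross-validation reporting the worst case.

    Only source-origin (primary/synthetic) records are folded; auxiliary
    records join every fold's manifest with split=train and never enter a
    validation split. ``run_fold`` maps ``(fold_index, split_manifest)``
    to ``(truth, predicted, probs)`` and encapsulates
    assemble -> train -> evaluate. The worst fold is the one with lowest
    overall accuracy, ties broken by lowest macro AUC.
    """
    folded = manifest.subset(lambda r: r.origin in ("primary", "synthetic"))
    folds = stratified_folds(folded, k, seed)
    aux_records = []
    if auxiliary is not None:
        aux_records = [r.with_(split="train", origin="auxiliary")
                       for r in auxiliary.records]
    results: list[FoldResult] = []
    for i, val_ids in enumerate(folds):
        val_set = set(val_ids)
        split = DatasetManifest(
            [r.with_(split="val" if r.id in val_set else "train") for r in folded.records]
            + aux_records,
            manifest.class_labels,
        )
        truth, predicted, probs = run_fold(i, split)
        results.append(FoldResult(fold=i, summary=evaluate_predictions(truth, predicted, probs)))
    def sort_key(res: FoldResult):
        mauc = res.summary.macro_auc
        return (res.summary.overall_accuracy, mauc if mauc is not None else np.inf)
    worst = min(results, key=sort_key)
    worst.worst = True
    return results


def ablation(truth: Sequence[int], member_probs: dict[str, np.ndarray],
             combined_probs: np.ndarray) -> dict[str, MetricsSummary]:
    """Evaluate each member alone and the ensemble on the same split."""
    out: dict[str, MetricsSummary] = {}
    for name, probs in member_probs.items():
        out[name] = evaluate_predictions(truth, np.argmax(probs, axis=1), probs)
    out["ensemble"] = evaluate_predictions(truth, np.argmax(combined_probs, axis=1),
                                           combined_probs)
    return out
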