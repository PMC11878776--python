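"""Slide-level aggregation, patient-grouped cross-validation, and metrics.

Slide prediction is soft voting: with z_i the logits of patch i of a slide,

    P_j = (1/N) * sum_i Softmax(z_i)_j

i.e. the slide probability of subtype j is the mean of the per-patch softmax
probabilities. Evaluation uses five-fold cross-validation with folds grouped
by patient (no patient ever straddles train/test) and stratified by subtype
as closely as the grouping allows. AUROC is one-vs-rest per class, computed
in its rank (Mann-Whitney) form with the half-credit tie convention, and the
macro AUROC is the unweighted mean over the four classes. 95% confidence
intervals are a normal approximation across fold values (mean +/- 1.96
sd/sqrt(k)), with a slide-level bootstrap available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import softmax
from scipy.stats import rankdata
from sklearn.model_selection import GroupKFold, StratifiedGroupKFold

from .synthetic import SUBTYPES

FPR_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass(frozen=True)
class SlidePrediction:
    """Per-subtype probability vector aggregated over a slide's patches."""

    slide_id: str
    probs: np.ndarray
    n_patches: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probs must be a probability vector, got {p}")
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_slide_ids: tuple[str, ...]
    test_slide_ids: tuple[str, ...]


def aggregate_slide(logits: np.ndarray | list, slide_id: str) -> SlidePrediction:
    """Soft-voting aggregation: mean of per-patch softmax probabilities."""
    z = np.asarray(logits, dtype=float)
    if z.size == 0:
        raise ValueError(f"slide {slide_id}: no patch logits to aggregate")
    if z.ndim != 2:
        raise ValueError(f"slide {slide_id}: expected (n_patches, n_classes) logits")
    probs = softmax(z, axis=1).mean(axis=0)
    return SlidePrediction(slide_id=slide_id, probs=probs, n_patches=z.shape[0])


def kfold_split(manifest: pd.DataFrame, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Patient-grouped, subtype-stratified k-fold split of the slides.

    Every patient's slides land entirely on one side of every split; each
    fold's slides serve as the test set exactly once. When a class has fewer
    slides than k, stratification is impossible and a plain patient-grouped
    split (balanced fold sizes) is used instead.
    """
    n_patients = manifest["patient_id"].nunique()
    if n_patients < k:
        raise ValueError(f"need at least k={k} patients, got {n_patients}")
    slides = manifest["slide_id"].to_numpy()
    y = manifest["subtype"].to_numpy()
    groups = manifest["patient_id"].to_numpy()
    class_counts = pd.Series(y).value_counts()
    if class_counts.min() >= k:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        warnings.warn(
            f"smallest class has {class_counts.min()} slides < k={k}; "
            "falling back to an unstratified patient-grouped split"
        )
        splitter = GroupKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (train_idx, test_idx) in enumerate(splitter.split(slides, y, groups)):
        folds.append(
            FoldSplit(
                fold_index=i,
                train_slide_ids=tuple(slides[train_idx]),
                test_slide_ids=tuple(slides[test_idx]),
            )
        )
    return folds


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """One-vs-rest AUROC in rank form.

    Equals the Mann-Whitney probability P(score_pos > score_neg) +
    0.5 * P(tie); ties get half credit through midranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both label values must be present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def macro_auroc(per_class: np.ndarray | list) -> float:
    """Unweighted mean of the four class-wise AUROC values."""
    values = np.asarray(per_class, dtype=float)
    if values.size != len(SUBTYPES) or not np.all(np.isfinite(values)):
        raise ValueError(f"need {len(SUBTYPES)} finite class AUROC values, got {values}")
    return float(values.mean())


def fold_ci(values: np.ndarray | list, method: str = "normal") -> tuple[float, float, float]:
    """(mean, low, high): 95% CI of a fold-level metric, clipped to [0, 1].

    ``normal`` uses mean +/- 1.96 sd/sqrt(k) over fold values; ``bootstrap``
    resamples the fold values (percentile interval).
    """
    values = np.asarray(values, dtype=float)
    k = len(values)
    if k < 2:
        raise ValueError("need at least 2 fold values for a CI")
    mean = float(values.mean())
    if method == "normal":
        half = 1.96 * float(values.std(ddof=1)) / np.sqrt(k)
        lo, hi = mean - half, mean + half
    elif method == "bootstrap":
        rng = np.random.default_rng(0)
        boots = values[rng.integers(0, k, size=(2000, k))].mean(axis=1)
        lo, hi = (float(q) for q in np.quantile(boots, [0.025, 0.975]))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return mean, float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(
    preds: list[SlidePrediction], labels: dict[str, str]
) -> dict:
    """Threshold metrics from hard argmax calls (ties -> lowest class index).

    Per class (one-vs-rest): precision, recall (= sensitivity), specificity,
    NPV, F1; plus overall accuracy and unweighted macro averages. Cells with
    a zero denominator are reported as NaN (undefined), never as 0, and are
    excluded from macro averages with a warning.
    """
    if not preds:
        raise ValueError("no predictions to score")
    y_true = np.array([labels[p.slide_id] for p in preds])
    y_pred = np.array([SUBTYPES[int(np.argmax(p.probs))] for p in preds])
    report: dict = {"accuracy": float((y_true == y_pred).mean()), "per_class": {}}
    macro_acc: dict[str, list[float]] = {m: [] for m in ("precision", "recall", "specificity", "npv", "f1")}
    for cls in SUBTYPES:
        tp = int(np.sum((y_pred == cls) & (y_true == cls)))
        fp = int(np.sum((y_pred == cls) & (y_true != cls)))
        fn = int(np.sum((y_pred != cls) & (y_true == cls)))
        tn = int(np.sum((y_pred != cls) & (y_true != cls)))
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        specificity = _safe_div(tn, tn + fp)
        npv = _safe_div(tn, tn + fn)
        f1 = (
            _safe_div(2 * precision * recall, precision + recall)
            if np.isfinite(precision) and np.isfinite(recall)
            else float("nan")
        )
        report["per_class"][cls] = {
            "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "precision": precision, "recall": recall, "sensitivity": recall,
            "specificity": specificity, "npv": npv, "f1": f1,
        }
        for name, value in (
            ("precision", precision), ("recall", recall),
            ("specificity", specificity), ("npv", npv), ("f1", f1),
        ):
            if np.isfinite(value):
                macro_acc[name].append(value)
            else:
                warnings.warn(f"{name} undefined for class {cls}; excluded from the macro average")
    report["macro"] = {m: float(np.mean(v)) if v else float("nan") for m, v in macro_acc.items()}
    return report


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Step-curve (FPR, TPR) points by descending-score threshold sweep."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(~sorted_labels)
    # collapse ties: keep the last point of each distinct score
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / max(int(labels.sum()), 1)]
    fpr = np.r_[0.0, fps[distinct] / max(int((~labels).sum()), 1)]
    return fpr, tpr


def interp_roc(fold_curves: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """Mean ROC curve over folds on the common FPR grid [0, 0.01, ..., 1].

    Each fold curve is linearly interpolated onto the grid; TPR is averaged
    pointwise; endpoints are pinned to (0, 0) and (1, 1).
    """
    if not fold_curves:
        raise ValueError("need at least one ROC curve")
    interpolated = []
    for fpr, tpr in fold_curves:
        fpr = np.asarray(fpr, dtype=float)
        tpr = np.asarray(tpr, dtype=float)
        if fpr.size == 0 or fpr.size != tpr.size:
            raise ValueError("each curve needs matching, non-empty FPR/TPR arrays")
        interpolated.append(np.interp(FPR_GRID, fpr, tpr))
    mean_tpr = np.mean(interpolated, axis=0)
    mean_tpr[0] = 0.0
    mean_tpr[-1] = 1.0
    return FPR_GRID.copy(), mean_tpr
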