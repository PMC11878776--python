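"""Aggregation, cross-validation splits, AUROC and threshold metrics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import softmax
from sklearn.metrics import roc_auc_score

from hiwsi.evaluate import (
    SlidePrediction,
    aggregate_slide,
    classification_metrics,
    fold_ci,
    interp_roc,
    kfold_split,
    macro_auroc,
    roc_auc,
    roc_curve_points,
)
from hiwsi.synthetic import SUBTYPES, SyntheticCohortSpec, plan_cohort


# ---------------------------------------------------------------------------
# soft voting


def test_single_patch_slide_is_its_own_softmax():
    z = np.array([[1.0, 2.0, 0.5, -1.0]])
    pred = aggregate_slide(z, "s")
    np.testing.assert_allclose(pred.probs, softmax(z[0]), atol=1e-12)
    assert pred.n_patches == 1


def test_two_extreme_patches_average_to_half_half():
    z = np.array([[1000.0, 0, 0, 0], [0, 1000.0, 0, 0]])
    np.testing.assert_allclose(aggregate_slide(z, "s").probs, [0.5, 0.5, 0, 0], atol=1e-12)


def test_aggregation_matches_brute_force_mean_of_softmax(rng):
    z = rng.normal(size=(7, 4))
    acc = np.zeros(4)
    for row in z:
        e = np.exp(row - row.max())
        acc += e / e.sum()
    np.testing.assert_allclose(aggregate_slide(z, "s").probs, acc / 7, atol=1e-12)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, derandomize=True)
def test_aggregation_is_permutation_invariant_and_normalized(seed):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(6, 4)) * 3
    a = aggregate_slide(z, "s").probs
    b = aggregate_slide(z[rng.permutation(6)], "s").probs
    np.testing.assert_allclose(a, b, atol=1e-12)
    assert abs(a.sum() - 1.0) < 1e-9


def test_empty_logit_list_names_the_slide():
    with pytest.raises(ValueError, match="slide_77"):
        aggregate_slide(np.empty((0, 4)), "slide_77")


# ---------------------------------------------------------------------------
# cross-validation splits


def _manifest(n_per_class=1, two_slide=False):
    rows = []
    for cls in SUBTYPES:
        for i in range(n_per_class):
            pid = f"{cls}_pt{i // 2 if two_slide else i}"
            rows.append({"slide_id": f"{cls}_{i}", "patient_id": pid, "subtype": cls})
    return pd.DataFrame(rows)


def test_ten_single_slide_patients_split_two_per_fold():
    man = pd.DataFrame(
        {
            "slide_id": [f"s{i}" for i in range(10)],
            "patient_id": [f"p{i}" for i in range(10)],
            "subtype": (["MMRd", "NSMP", "p53abn", "POLEmut", "MMRd"] * 2),
        }
    )
    folds = kfold_split(man, k=5, seed=0)
    test_sets = [set(f.test_slide_ids) for f in folds]
    assert all(len(t) == 2 for t in test_sets)
    assert set().union(*test_sets) == set(man["slide_id"])
    assert sum(len(t) for t in test_sets) == 10  # disjoint partition


def test_two_slide_patient_never_straddles_a_split():
    man = _manifest(n_per_class=4, two_slide=True)
    for fold in kfold_split(man, k=4, seed=1):
        patients_train = set(man[man.slide_id.isin(fold.train_slide_ids)].patient_id)
        patients_test = set(man[man.slide_id.isin(fold.test_slide_ids)].patient_id)
        assert not patients_train & patients_test


def test_fold_class_proportions_within_one_slide_of_global():
    plan = plan_cohort(SyntheticCohortSpec(two_slide_patient_fraction=0.5, seed=3))
    man = plan[["slide_id", "patient_id", "subtype"]]
    folds = kfold_split(man, k=5, seed=4)
    for fold in folds:
        counts = man[man.slide_id.isin(fold.test_slide_ids)]["subtype"].value_counts()
        for cls in SUBTYPES:
            assert abs(counts.get(cls, 0) - 2) <= 1  # 10 slides/class over 5 folds


def test_fewer_patients_than_folds_is_a_split_error():
    man = _manifest(n_per_class=1)
    with pytest.raises(ValueError, match="patients"):
        kfold_split(man, k=5, seed=0)


def test_no_patient_leakage_over_a_hundred_seeded_splits():
    plan = plan_cohort(SyntheticCohortSpec(two_slide_patient_fraction=0.5, seed=3))
    man = plan[["slide_id", "patient_id", "subtype"]]
    for seed in range(100):
        for fold in kfold_split(man, k=5, seed=seed):
            tr = set(man[man.slide_id.isin(fold.train_slide_ids)].patient_id)
            te = set(man[man.slide_id.isin(fold.test_slide_ids)].patient_id)
            assert not tr & te


# ---------------------------------------------------------------------------
# AUROC


def test_perfect_separation_gives_one():
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0


def test_all_ties_give_half():
    assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5


def test_hand_written_pairs_with_a_tie_match_pair_enumeration():
    scores = np.array([0.9, 0.8, 0.8, 0.4, 0.3, 0.1])
    labels = np.array([1, 1, 0, 0, 1, 0])
    total = 0.0
    for sp in scores[labels == 1]:
        for sn in scores[labels == 0]:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    expected = total / (3 * 3)
    assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)


def test_auroc_matches_pair_counting_oracle_on_random_instances(rng):
    for _ in range(50):
        n = int(rng.integers(4, 50))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        oracle = wins / (len(pos) * len(neg))
        assert abs(roc_auc(scores, labels) - oracle) < 1e-12
        assert abs(roc_auc(scores, labels) - roc_auc_score(labels, scores)) < 1e-12


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, derandomize=True)
def test_auroc_monotone_invariance_and_label_complement(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=20)
    labels = np.r_[np.ones(8, dtype=int), np.zeros(12, dtype=int)]
    base = roc_auc(scores, labels)
    assert roc_auc(np.exp(scores) + 3, labels) == pytest.approx(base, abs=1e-12)
    assert roc_auc(scores, 1 - labels) == pytest.approx(1 - base, abs=1e-12)


def test_single_class_labels_are_undefined():
    with pytest.raises(ValueError, match="both"):
        roc_auc([0.1, 0.9], [1, 1])


def test_macro_auroc_is_the_arithmetic_mean(rng):
    assert macro_auroc([1, 1, 1, 1]) == 1.0
    assert macro_auroc([0.6, 0.7, 0.8, 0.9]) == pytest.approx(0.75)
    v = rng.random(4)
    assert macro_auroc(v) == pytest.approx(sum(v) / 4, abs=1e-12)
    with pytest.raises(ValueError):
        macro_auroc([0.5, 0.5, np.nan, 0.5])


# ---------------------------------------------------------------------------
# fold CIs


def test_identical_fold_values_collapse_the_interval():
    assert fold_ci([0.8, 0.8, 0.8]) == pytest.approx((0.8, 0.8, 0.8))


def test_two_fold_interval_matches_the_closed_form():
    mean, lo, hi = fold_ci([0.8, 0.9])
    sd = np.std([0.8, 0.9], ddof=1)
    half = 1.96 * sd / np.sqrt(2)
    assert (mean, lo, hi) == pytest.approx((0.85, 0.85 - half, 0.85 + half))


def test_interval_is_clipped_to_the_unit_range():
    _, _, hi = fold_ci([0.99, 1.0, 1.0, 0.98, 1.0])
    assert hi <= 1.0


def test_single_fold_has_no_interval():
    with pytest.raises(ValueError):
        fold_ci([0.9])


def test_bootstrap_interval_contains_the_mean():
    mean, lo, hi = fold_ci([0.7, 0.8, 0.9, 0.85, 0.75], method="bootstrap")
    assert lo <= mean <= hi


# ---------------------------------------------------------------------------
# threshold metrics


def _pred(slide_id, cls_idx):
    probs = np.full(4, 0.1)
    probs[cls_idx] = 0.7
    return SlidePrediction(slide_id, probs, 5)


def test_all_correct_predictions_score_perfectly():
    preds = [_pred(f"s{i}", i % 4) for i in range(8)]
    labels = {f"s{i}": SUBTYPES[i % 4] for i in range(8)}
    report = classification_metrics(preds, labels)
    assert report["accuracy"] == 1.0
    for cls in SUBTYPES:
        assert report["per_class"][cls]["f1"] == 1.0


def test_toy_confusion_matrix_arithmetic():
    """TP=3, FP=1, TN=5, FN=1 for MMRd: precision 0.75, recall 0.75,
    specificity 5/6, NPV 5/6."""
    preds, labels = [], {}
    i = 0

    def add(pred_cls, true_cls):
        nonlocal i
        sid = f"s{i}"
        preds.append(_pred(sid, SUBTYPES.index(pred_cls)))
        labels[sid] = true_cls
        i += 1

    for _ in range(3):
        add("MMRd", "MMRd")          # TP
    add("MMRd", "NSMP")              # FP
    add("NSMP", "MMRd")              # FN
    for _ in range(5):
        add("NSMP", "NSMP")          # TN
    m = classification_metrics(preds, labels)["per_class"]["MMRd"]
    assert (m["tp"], m["fp"], m["tn"], m["fn"]) == (3, 1, 5, 1)
    assert m["precision"] == pytest.approx(0.75)
    assert m["recall"] == pytest.approx(0.75)
    assert m["specificity"] == pytest.approx(5 / 6)
    assert m["npv"] == pytest.approx(5 / 6)


def test_metrics_match_independent_confusion_tally(rng):
    preds = [_pred(f"s{i}", int(rng.integers(0, 4))) for i in range(20)]
    labels = {f"s{i}": SUBTYPES[int(rng.integers(0, 4))] for i in range(20)}
    report = classification_metrics(preds, labels)
    y_true = np.array([labels[p.slide_id] for p in preds])
    y_pred = np.array([SUBTYPES[int(np.argmax(p.probs))] for p in preds])
    assert report["accuracy"] == (y_true == y_pred).mean()
    for cls in SUBTYPES:
        tp = int(((y_pred == cls) & (y_true == cls)).sum())
        fp = int(((y_pred == cls) & (y_true != cls)).sum())
        fn = int(((y_pred != cls) & (y_true == cls)).sum())
        m = report["per_class"][cls]
        if tp + fp:
            assert m["precision"] == pytest.approx(tp / (tp + fp))
        else:
            assert np.isnan(m["precision"])
        if tp + fn:
            assert m["recall"] == pytest.approx(tp / (tp + fn))


def test_zero_denominator_cells_are_nan_not_zero():
    preds = [_pred("s0", 0), _pred("s1", 0)]
    labels = {"s0": "MMRd", "s1": "MMRd"}
    with pytest.warns(UserWarning, match="undefined"):
        report = classification_metrics(preds, labels)
    assert np.isnan(report["per_class"]["NSMP"]["precision"])


def test_empty_prediction_list_is_an_error():
    with pytest.raises(ValueError):
        classification_metrics([], {})


# ---------------------------------------------------------------------------
# ROC interpolation


def test_perfect_curve_means_unit_tpr_beyond_the_origin():
    fpr, tpr = roc_curve_points(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
    grid, mean_tpr = interp_roc([(fpr, tpr)])
    assert mean_tpr[0] == 0.0
    np.testing.assert_allclose(mean_tpr[1:], 1.0)


def test_identical_curves_average_to_themselves():
    curve = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.75, 1.0]))
    _, mean_tpr = interp_roc([curve, curve])
    np.testing.assert_allclose(mean_tpr[50], 0.75)


def test_two_hand_built_step_curves_average_pointwise():
    c1 = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.5, 1.0]))
    c2 = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 1.0, 1.0]))
    _, mean_tpr = interp_roc([c1, c2])
    # at FPR 0.25: c1 interpolates to 0.25, c2 to 0.5 -> mean 0.375
    assert mean_tpr[25] == pytest.approx(0.375)
    assert mean_tpr[50] == pytest.approx(0.75)
    assert mean_tpr[-1] == 1.0


def test_empty_curve_list_is_an_error():
    with pytest.raises(ValueError):
        interp_roc([])
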