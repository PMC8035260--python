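"""Confusion matrix, one-vs-rest rates, macro-F1 and OvR curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apdiff.metrics import (
    confusion_matrix,
    evaluate,
    macro_f1,
    ovr_curves,
    per_class_metrics,
)

# Per-class F1 scores as printed for the full-grid classifier: six classes
# perfect, GbNa 0.930, GNa 0.981, GK1 0.964, GbCa 0.974.
PRINTED_F1 = [1.0, 1.0, 0.964, 0.981, 0.930, 1.0, 0.974, 1.0, 1.0, 1.0]


def test_confusion_matrix_small_example():
    cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], n_classes=2)
    assert cm[0, 0] == 1 and cm[0, 1] == 1 and cm[1, 1] == 2
    assert cm.sum() == 4


def test_confusion_matrix_perfect_is_diagonal():
    y = np.repeat(np.arange(10), 3)
    cm = confusion_matrix(y, y)
    assert np.array_equal(cm, np.diag(np.bincount(y)))


def test_confusion_matrix_rejects_out_of_range():
    with pytest.raises(ValueError):
        confusion_matrix([0, 10], [0, 1])
    with pytest.raises(ValueError):
        confusion_matrix([0, 1], [0])


@settings(deadline=None, max_examples=30)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_row_sums_equal_class_counts(seed):
    rng = np.random.default_rng(seed)
    y_true = rng.integers(0, 10, 200)
    y_pred = rng.integers(0, 10, 200)
    cm = confusion_matrix(y_true, y_pred)
    assert cm.sum() == 200
    assert np.array_equal(cm.sum(axis=1), np.bincount(y_true, minlength=10))


def test_per_class_metrics_match_sklearn(rng):
    from sklearn.metrics import precision_recall_fscore_support

    y_true = rng.integers(0, 10, 500)
    y_pred = rng.integers(0, 10, 500)
    cm = confusion_matrix(y_true, y_pred)
    pc = per_class_metrics(cm)
    p, r, f, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=range(10), zero_division=np.nan)
    np.testing.assert_allclose(pc["precision"], p, atol=1e-12)
    np.testing.assert_allclose(pc["recall"], r, atol=1e-12)
    np.testing.assert_allclose(pc["f1"], f, atol=1e-12)


def test_printed_per_class_f1s_average_to_0985():
    assert macro_f1(PRINTED_F1) == pytest.approx(0.985, abs=5e-4)


def test_macro_f1_is_permutation_invariant(rng):
    vals = rng.uniform(0, 1, 10)
    assert macro_f1(vals) == pytest.approx(macro_f1(vals[::-1]))
    assert macro_f1(np.ones(10)) == 1.0


def test_macro_f1_refuses_missing_classes():
    with pytest.raises(ValueError):
        macro_f1([1.0] * 9 + [float("nan")])


@settings(deadline=None, max_examples=30)
@given(st.floats(min_value=0.01, max_value=1.0))
def test_f1_equals_p_when_precision_equals_recall(p):
    # harmonic-mean identity via a constructed confusion matrix
    # TP chosen so recall = precision = p: TP=p*100, FN=FP=(1-p)*100
    tp = int(round(p * 100))
    fn = 100 - tp
    cm = np.array([[tp, fn], [fn, 10_000]])
    pc = per_class_metrics(cm)
    expected = tp / 100
    assert pc["f1"][0] == pytest.approx(expected, abs=1e-12)
    # harmonic <= arithmetic mean of precision and recall
    am = 0.5 * (pc["precision"][0] + pc["recall"][0])
    assert pc["f1"][0] <= am + 1e-12


def test_all_wrong_class_has_zero_f1():
    cm = confusion_matrix([0, 0, 1, 1], [1, 1, 1, 1], n_classes=2)
    pc = per_class_metrics(cm)
    assert pc["f1"][0] == 0.0


def test_empty_class_reported_as_missing_not_zero():
    cm = confusion_matrix([1, 1], [1, 1], n_classes=3)
    pc = per_class_metrics(cm)
    assert np.isnan(pc["recall"][0])
    assert pc["recall"][1] == 1.0


def test_specificity_and_accuracy():
    cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], n_classes=2)
    pc = per_class_metrics(cm)
    # class 0: TP=1 FN=1 FP=0 TN=2
    assert pc["specificity"][0] == 1.0
    assert pc["accuracy"][0] == pytest.approx(0.75)
    # micro accuracy equals trace/N
    rep = evaluate([0, 0, 1, 1], [0, 1, 1, 1], n_classes=2)
    assert rep.accuracy == pytest.approx(np.trace(cm) / cm.sum())


def test_perfect_classifier_curves(rng):
    y = np.repeat(np.arange(10), 5)
    proba = np.full((50, 10), 0.01)
    proba[np.arange(50), y] = 1 - 0.09
    curves = ovr_curves(y, proba)
    for c, cv in curves.items():
        assert cv["roc_auc"] == pytest.approx(1.0)
        # PR curve reaches precision 1 at recall 1
        assert cv["pr_auc"] == pytest.approx(1.0)


def test_random_classifier_auc_near_half(rng):
    y = rng.integers(0, 10, 3000)
    raw = rng.uniform(size=(3000, 10))
    proba = raw / raw.sum(axis=1, keepdims=True)
    curves = ovr_curves(y, proba)
    aucs = [cv["roc_auc"] for cv in curves.values()]
    assert abs(np.mean(aucs) - 0.5) < 0.05


def test_ovr_curves_validation(rng):
    y = np.array([0, 1])
    with pytest.raises(ValueError):
        ovr_curves(y, np.array([[0.5, 0.2], [0.5, 0.5]]), n_classes=2)
    with pytest.warns(UserWarning):
        curves = ovr_curves(np.zeros(4, dtype=int),
                            np.tile([0.6, 0.4], (4, 1)), n_classes=2)
    assert 1 not in curves


def test_report_serialization(tmp_path, rng):
    y = np.repeat(np.arange(10), 4)
    rep = evaluate(y, y)
    path = tmp_path / "report.json"
    rep.save(path)
    import json
    data = json.loads(path.read_text())
    assert data["macro_f1"] == 1.0
    assert len(data["confusion_matrix"]) == 10
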