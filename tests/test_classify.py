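"""Splitting, random forest, confusion matrices, metrics, ROC/AUC."""

import numpy as np
import pytest

from epidisc import ConfusionMatrix, confusion, metrics, roc_auc, stratified_split, train_rf
from epidisc.classify import predict_scores


def test_split_matches_study_counts():
    labels = np.array([0] * 100 + [1] * 540)
    train, test = stratified_split(labels, seed=0)
    assert (labels[train] == 0).sum() == 66
    assert (labels[train] == 1).sum() == 360
    assert (labels[test] == 0).sum() == 34
    assert (labels[test] == 1).sum() == 180
    assert len(test) == 214
    # disjoint and exhaustive
    assert np.array_equal(np.sort(np.concatenate([train, test])), np.arange(640))


def test_split_small_classes_and_determinism():
    labels = np.array([0, 0, 0, 1, 1, 1])
    train, test = stratified_split(labels, seed=5)
    for cls in (0, 1):
        assert (labels[train] == cls).sum() == 2
        assert (labels[test] == cls).sum() == 1
    t2, s2 = stratified_split(labels, seed=5)
    assert np.array_equal(train, t2) and np.array_equal(test, s2)
    with pytest.raises(ValueError):
        stratified_split(np.array([0, 0, 1, 1, 1]))


def test_metrics_worked_examples():
    """The two published test confusion matrices map to their printed
    sensitivity/specificity/accuracy at 2-decimal percent precision."""
    sens, spec, acc = metrics(ConfusionMatrix(tp=175, fn=5, fp=6, tn=28))
    assert (round(100 * sens, 2), round(100 * spec, 2), round(100 * acc, 2)) == (
        97.22, 82.35, 94.86,
    )
    sens, spec, acc = metrics(ConfusionMatrix(tp=178, fn=2, fp=1, tn=33))
    assert (round(100 * sens, 2), round(100 * spec, 2), round(100 * acc, 2)) == (
        98.89, 97.06, 98.60,
    )


def test_metrics_balanced_and_undefined():
    sens, spec, acc = metrics(ConfusionMatrix(tp=10, fn=10, fp=7, tn=7))
    assert sens == spec == acc == 0.5
    with pytest.raises(ZeroDivisionError):
        metrics(ConfusionMatrix(tp=0, fn=0, fp=1, tn=1))


def test_confusion_counts():
    cm = confusion([1] * 180 + [0] * 34, [1] * 180 + [0] * 34)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (180, 0, 0, 34)
    cm = confusion(np.ones(214), [1] * 180 + [0] * 34)
    assert (cm.fp, cm.fn) == (34, 0)
    with pytest.raises(ValueError):
        confusion([1, 0], [1, 0, 1])
    with pytest.raises(ValueError):
        ConfusionMatrix(tp=-1, fn=0, fp=0, tn=0)


def test_confusion_brute_force(rng):
    pred = rng.integers(0, 2, size=200)
    true = rng.integers(0, 2, size=200)
    cm = confusion(pred, true)
    tally = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    for p, t in zip(pred, true):
        key = ("t" if p == t else "f") + ("p" if p == 1 else "n")
        tally[key] += 1
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (
        tally["tp"], tally["fn"], tally["fp"], tally["tn"],
    )
    assert cm.total == 200


def test_roc_auc_extremes():
    auc, roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert auc == 1.0
    auc, _ = roc_auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0])
    assert auc == 0.5
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


def concordance(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def test_roc_auc_equals_concordance(rng):
    scores = rng.random(50).round(2)  # rounding forces some ties
    labels = rng.integers(0, 2, size=50)
    while labels.sum() in (0, 50):
        labels = rng.integers(0, 2, size=50)
    auc, roc = roc_auc(scores, labels)
    assert auc == pytest.approx(concordance(scores, labels), abs=1e-12)
    # ROC is monotone in both coordinates
    assert np.all(np.diff(roc[:, 0]) >= 0)
    assert np.all(np.diff(roc[:, 1]) >= 0)


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.random(80)
    labels = np.r_[np.ones(40), np.zeros(40)].astype(int)
    a1, _ = roc_auc(scores, labels)
    a2, _ = roc_auc(np.exp(5 * scores), labels)
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_relabeling_swaps_sensitivity_specificity():
    cm = ConfusionMatrix(tp=175, fn=5, fp=6, tn=28)
    swapped = ConfusionMatrix(tp=cm.tn, fn=cm.fp, fp=cm.fn, tn=cm.tp)
    s1, p1, a1 = metrics(cm)
    s2, p2, a2 = metrics(swapped)
    assert (s2, p2) == (p1, s1)
    assert a1 == a2


def test_rf_separable_and_null(rng):
    X = np.vstack([rng.normal(0, 0.1, (100, 2)), rng.normal(5, 0.1, (100, 2))])
    y = np.r_[np.zeros(100), np.ones(100)].astype(int)
    model = train_rf(X, y, seed=0)
    assert (model.predict(X) == y).all()
    # pure-noise features: test AUC hovers at chance
    Xn = rng.normal(size=(200, 3))
    yn = np.r_[np.zeros(100), np.ones(100)].astype(int)
    perm = rng.permutation(200)
    tr, te = perm[:140], perm[140:]
    model = train_rf(Xn[tr], yn[tr], seed=1)
    scores = predict_scores(model, Xn[te])
    auc, _ = roc_auc(scores, yn[te])
    assert abs(auc - 0.5) < 0.15
    with pytest.raises(ValueError):
        train_rf(X[:100], y[:100], seed=0)  # single class
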