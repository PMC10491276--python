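"""Cohort splits, metric formulas, classifier bank, published-row audits."""

import numpy as np
import pytest

import phenopipe as pp
from phenopipe.phenotype import (
    ConfusionMatrix,
    SplitSpec,
    check_metric_row_consistency,
    compute_metrics,
    evaluate,
    make_splits,
    reconstruct_confusion,
    render_report_tsv,
    train_bank,
)


def _labels(n_pos, n_neg):
    out = {f"a{i:04d}": True for i in range(n_pos)}
    out.update({f"b{i:04d}": False for i in range(n_neg)})
    return out


class TestMakeSplits:
    def test_cohort_of_137_positives_splits_109_28(self):
        labels = _labels(137, 1789)
        split = make_splits(labels, SplitSpec(seed=0, n_unbalanced_negatives=63))
        lab = split.labels
        train_pos = sum(lab[p] for p in split.train)
        assert (train_pos, len(split.train) - train_pos) == (109, 109)
        bal_pos = sum(lab[p] for p in split.balanced_test)
        assert (bal_pos, len(split.balanced_test) - bal_pos) == (28, 28)
        unbal_pos = sum(lab[p] for p in split.unbalanced_test)
        assert (unbal_pos, len(split.unbalanced_test) - unbal_pos) == (28, 63)

    def test_default_unbalanced_negative_rule(self):
        # round(28 * 0.7 / 0.3) = 65 without the explicit override
        split = make_splits(_labels(137, 1789), SplitSpec(seed=0))
        n_neg = sum(not split.labels[p] for p in split.unbalanced_test)
        assert n_neg == 65

    def test_degenerate_small_cohort(self):
        split = make_splits(_labels(10, 50),
                            SplitSpec(unbalanced_prevalence=0.5, seed=1))
        assert len(split.balanced_test) == 4  # 2 + 2
        assert len(split.unbalanced_test) == 4

    def test_no_negative_reused_and_test_positives_shared(self):
        split = make_splits(_labels(30, 300), SplitSpec(seed=2))
        neg = lambda pids: {p for p in pids if not split.labels[p]}
        pos = lambda pids: {p for p in pids if split.labels[p]}
        assert neg(split.train).isdisjoint(neg(split.balanced_test))
        assert neg(split.train).isdisjoint(neg(split.unbalanced_test))
        assert neg(split.balanced_test).isdisjoint(neg(split.unbalanced_test))
        assert pos(split.balanced_test) == pos(split.unbalanced_test)
        assert pos(split.train).isdisjoint(pos(split.balanced_test))

    def test_insufficient_negatives_error_states_requirement(self):
        with pytest.raises(ValueError, match="need"):
            make_splits(_labels(100, 100), SplitSpec(seed=0))

    def test_deterministic_under_seed(self):
        a = make_splits(_labels(30, 300), SplitSpec(seed=4))
        b = make_splits(_labels(30, 300), SplitSpec(seed=4))
        assert (a.train, a.balanced_test, a.unbalanced_test) == \
               (b.train, b.balanced_test, b.unbalanced_test)


class TestComputeMetrics:
    def test_balanced_test_row_reconstruction(self):
        m = compute_metrics(ConfusionMatrix(tp=21, fp=4, fn=7, tn=24))
        assert round(m["accuracy"], 4) == 0.8036
        assert round(m["f1"], 4) == 0.7925
        assert round(m["npv"], 4) == 0.7742
        assert round(m["specificity"], 4) == 0.8571

    def test_prevalence_matched_row_reconstruction(self):
        m = compute_metrics(ConfusionMatrix(tp=21, fp=15, fn=7, tn=48))
        assert round(m["accuracy"], 4) == 0.7582
        assert round(m["npv"], 4) == 0.8727
        assert round(m["specificity"], 4) == 0.7619

    def test_zero_denominators_are_undefined(self):
        m = compute_metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=5))
        assert m["accuracy"] == 1.0
        assert m["precision"] is None and m["recall"] is None
        assert "undefined" in render_report_tsv(
            {"dummy": {"cm": ConfusionMatrix(0, 5, 0, 0),
                       "metrics": m}})

    def test_equals_arithmetic_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 50, size=4))
            m = compute_metrics(ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn))
            total = tp + tn + fp + fn
            if total:
                assert m["accuracy"] == (tp + tn) / total
            if tp + fp:
                assert m["precision"] == tp / (tp + fp)
            if tp + fn:
                assert m["recall"] == tp / (tp + fn)
            if tn + fn:
                assert m["npv"] == tn / (tn + fn)
            if tn + fp:
                assert m["specificity"] == tn / (tn + fp)
            if tp + fp and tp + fn and tp:
                p, r = tp / (tp + fp), tp / (tp + fn)
                assert m["f1"] == pytest.approx(2 * p * r / (p + r))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, tn=0, fp=0, fn=0)


class TestRowConsistencyAudit:
    def test_consistent_published_rows_reproduce_to_4_decimals(self):
        row_balanced = {"accuracy": 0.8036, "precision": 0.8400,
                        "recall": 0.7500, "f1": 0.7925, "npv": 0.7742,
                        "specificity": 0.8571}
        assert all(check_metric_row_consistency(28, 28, row_balanced).values())
        row_unbalanced = {"accuracy": 0.7582, "precision": 0.5833,
                          "recall": 0.7500, "f1": 0.6563, "npv": 0.8727,
                          "specificity": 0.7619}
        assert all(check_metric_row_consistency(28, 63, row_unbalanced).values())

    def test_inconsistent_specificity_column_is_detected(self):
        # a published balanced-test row whose specificity contradicts its own
        # accuracy/precision/recall at 28+28 (implied TN=20 -> 0.7143)
        row = {"accuracy": 0.7321, "precision": 0.7241, "recall": 0.7500,
               "specificity": 0.7500}
        checks = check_metric_row_consistency(28, 28, row)
        assert checks["accuracy"] and checks["precision"] and checks["recall"]
        assert not checks["specificity"]

    def test_reconstruction_inverts_metrics(self):
        cm = reconstruct_confusion(28, 28, precision=0.8400, recall=0.7500)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (21, 4, 7, 24)


def _separable_vectors(n=150, seed=0):
    """Patient vectors where label == UKWP rule on a noiseless binary vector."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    while len(y) < n or len(set(y)) < 2:
        vec = rng.integers(0, 2, size=8)
        lab = int(vec[4] and vec[[1, 2, 3, 6]].sum() >= 3)
        X.append(vec)
        y.append(lab)
    return np.array(X, dtype=float), np.array(y)


class TestTrainBank:
    def test_every_model_separates_rule_based_vectors(self):
        X, y = _separable_vectors(200)
        bank = train_bank(X, y, seed=0)
        assert set(bank.models) == {
            "Logistic Regression", "SVM", "Decision Tree", "Random Forest",
            "KNN", "XGBoost", "AdaBoost", "Stacking Classifier"}
        Xt, yt = _separable_vectors(100, seed=99)
        for name, model in bank.models.items():
            acc = (model.predict(Xt) == yt).mean()
            assert acc >= 0.95, name

    def test_fixed_seed_reproduces_hyperparameters(self):
        X, y = _separable_vectors(120, seed=3)
        a = train_bank(X, y, seed=7)
        b = train_bank(X, y, seed=7)
        assert a.chosen_params == b.chosen_params

    def test_single_model_menu_skips_stacking_with_warning(self):
        X, y = _separable_vectors(100, seed=1)
        with pytest.warns(UserWarning, match="stacking"):
            bank = train_bank(X, y, menu=("KNN",), seed=0)
        assert set(bank.models) == {"KNN"}

    def test_minority_class_below_folds_rejected(self):
        X = np.ones((10, 8))
        y = np.array([1] * 3 + [0] * 7)
        with pytest.raises(ValueError, match="5-fold"):
            train_bank(X, y, seed=0)


class TestEvaluate:
    def test_perfect_model_scores_one_everywhere(self):
        X, y = _separable_vectors(150, seed=5)
        bank = train_bank(X, y, menu=("Decision Tree",), seed=0)
        pids = [f"p{i}" for i in range(len(y))]
        report = evaluate(
            bank, {"train_as_test": pids},
            {p: X[i] for i, p in enumerate(pids)},
            {p: bool(y[i]) for i, p in enumerate(pids)},
        )
        metrics = report["train_as_test"]["Decision Tree"]["metrics"]
        assert all(v == 1.0 for v in metrics.values())

    def test_majority_class_predictor_scores_half_on_balanced_set(self):
        cm = ConfusionMatrix.from_predictions(
            [True] * 28 + [False] * 28, [False] * 56)
        assert compute_metrics(cm)["accuracy"] == 0.5
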