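import numpy as np
import pandas as pd
import pytest

import stenoscope as st
from stenoscope.classify import (
    GBM_GRID,
    GBM_GRID_FAST,
    SVM_GRID,
    Split,
    evaluate,
    participant_split,
    tune_gbm,
    tune_svm,
)
from stenoscope.io import manifest_from_rows
from stenoscope.records import CLASS_ORDER
from stenoscope.stats import auc_mann_whitney

from conftest import PAPER_TEST_COUNTS


def _manifest_75():
    rows = []
    spec = [(0, 10), (30, 10), (45, 10), (55, 15), (72, 10), (85, 10), (92, 10)]
    i = 0
    for s, n in spec:
        for _ in range(n):
            rows.append({"participant_id": f"p{i:03d}", "stenosis_pct": float(s), "path": ""})
            i += 1
    return manifest_from_rows(rows)


class TestStenosisToClass:
    @pytest.mark.parametrize(
        "pct,label",
        [(0, "mild"), (30, "mild"), (49.9, "mild"), (50, "moderate"),
         (75, "moderate"), (75.1, "severe"), (95, "severe")],
    )
    def test_boundaries(self, pct, label):
        assert st.stenosis_to_class(pct) == label

    @pytest.mark.parametrize("bad", [-0.1, 100.5])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            st.stenosis_to_class(bad)


class TestParticipantSplit:
    def test_paper_allocation(self):
        split = participant_split(_manifest_75(), 60, 15, seed=0,
                                  test_counts=dict(PAPER_TEST_COUNTS))
        assert len(split.train_ids) == 60 and len(split.test_ids) == 15
        manifest = _manifest_75()
        cls = manifest.table.set_index("participant_id")["stenosis_pct"].map(
            st.stenosis_to_class
        )
        counts = cls.loc[split.test_ids].value_counts().to_dict()
        assert counts == PAPER_TEST_COUNTS

    def test_no_overlap_and_determinism(self):
        a = participant_split(_manifest_75(), 60, 15, seed=3)
        b = participant_split(_manifest_75(), 60, 15, seed=3)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        assert not set(a.train_ids) & set(a.test_ids)

    def test_proportional_default(self):
        split = participant_split(_manifest_75(), 60, 15, seed=1)
        assert len(split.test_ids) == 15

    def test_infeasible(self):
        with pytest.raises(ValueError):
            participant_split(_manifest_75(), 70, 15, seed=0)

    def test_leaky_split_rejected(self):
        with pytest.raises(ValueError, match="both sides"):
            Split(train_ids=["a", "b"], test_ids=["b"])


def _separable_data(rng, n_participants=12, per=8):
    rows = []
    for i in range(n_participants):
        label = CLASS_ORDER[i % 3]
        center = {"mild": -3.0, "moderate": 0.0, "severe": 3.0}[label]
        for _ in range(per):
            rows.append({
                "x0": rng.normal(center, 0.1), "x1": rng.normal(center, 0.1),
                "pid": f"g{i}", "label": label,
            })
    df = pd.DataFrame(rows)
    return df[["x0", "x1"]].to_numpy(), df["label"].to_numpy(), df["pid"].to_numpy()


class TestTuning:
    def test_svm_grid_contains_reference_optimum(self):
        assert 1.0 in SVM_GRID["C"] and 0.01 in SVM_GRID["gamma"]

    def test_gbm_grid_contains_reference_optimum(self):
        assert 300 in GBM_GRID["n_estimators"]
        assert 0.05 in GBM_GRID["learning_rate"]
        assert 5 in GBM_GRID["max_depth"]
        assert 0.8 in GBM_GRID["subsample"]

    def test_one_candidate_grid(self, rng):
        X, y, groups = _separable_data(rng)
        model = tune_svm(X, y, groups, grid={"C": [2.0], "gamma": [0.05]})
        assert model.C == 2.0 and model.gamma == 0.05

    def test_separable_data_perfect_cv(self, rng):
        X, y, groups = _separable_data(rng)
        model = tune_svm(X, y, groups, grid={"C": [1.0], "gamma": [0.01]})
        assert np.mean(model.predict(X) == y) == 1.0

    def test_gbm_deterministic_selection(self, rng):
        X, y, groups = _separable_data(rng)
        grid = {"n_estimators": [10, 20], "learning_rate": [0.1], "max_depth": [2],
                "subsample": [0.8]}
        a = tune_gbm(X, y, groups, seed=5, grid=grid)
        b = tune_gbm(X, y, groups, seed=5, grid=grid)
        assert a.get_params() == b.get_params()

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            tune_svm(X, ["mild"] * 10, [f"g{i}" for i in range(10)])


class _FixedModel:
    """Stub with externally supplied predictions and per-class scores."""

    def __init__(self, classes, predictions, scores):
        self.classes_ = list(classes)
        self._pred = np.asarray(predictions)
        self._scores = np.asarray(scores, dtype=float)

    def predict(self, X):
        return self._pred

    def predict_proba(self, X):
        return self._scores


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.repeat(CLASS_ORDER, 10)
        scores = np.zeros((30, 3))
        for i, c in enumerate(CLASS_ORDER):
            scores[np.asarray(y) == c, i] = 1.0
        model = _FixedModel(CLASS_ORDER, y, scores)
        rep = evaluate(model, np.zeros((30, 1)), y)
        assert rep.accuracy == 1.0
        assert np.array_equal(rep.confusion, np.diag([10, 10, 10]))
        assert np.allclose(rep.per_class["auc"], 1.0)

    def test_constant_scores_auc_half(self):
        y = np.repeat(CLASS_ORDER, 10)
        model = _FixedModel(CLASS_ORDER, y, np.full((30, 3), 0.5))
        rep = evaluate(model, np.zeros((30, 1)), y)
        assert np.allclose(rep.per_class["auc"], 0.5)

    def test_hand_computed_confusion_metrics(self, rng):
        cm = np.array([[8, 1, 1], [2, 6, 2], [0, 1, 9]])
        y_true, y_pred = [], []
        for i, row in enumerate(cm):
            for j, count in enumerate(row):
                y_true += [CLASS_ORDER[i]] * count
                y_pred += [CLASS_ORDER[j]] * count
        model = _FixedModel(CLASS_ORDER, y_pred, rng.uniform(size=(30, 3)))
        rep = evaluate(model, np.zeros((30, 1)), np.asarray(y_true))
        assert np.array_equal(rep.confusion, cm)
        assert rep.accuracy == pytest.approx(23 / 30)
        mild = rep.per_class.loc["mild"]
        assert mild["precision"] == pytest.approx(0.8)
        assert mild["recall"] == pytest.approx(0.8)
        assert mild["specificity"] == pytest.approx(0.9)
        assert mild["f1"] == pytest.approx(0.8)
        moderate = rep.per_class.loc["moderate"]
        assert moderate["precision"] == pytest.approx(0.75)
        assert moderate["recall"] == pytest.approx(0.6)
        assert moderate["f1"] == pytest.approx(2 / 3)
        severe = rep.per_class.loc["severe"]
        assert severe["recall"] == pytest.approx(0.9)
        assert severe["specificity"] == pytest.approx(0.85)

    def test_confusion_rows_sum_to_class_counts(self, default_run):
        for rep in default_run.reports.values():
            test_rows = default_run.features[
                default_run.features.participant_id.isin(default_run.split.test_ids)
            ]
            class_counts = test_rows["label"].value_counts()
            for i, c in enumerate(rep.classes):
                assert rep.confusion[i].sum() == class_counts[c]

    def test_auc_matches_mann_whitney_identity(self, rng):
        y = np.array(list(np.repeat(CLASS_ORDER, 10)))
        scores = rng.uniform(size=(30, 3))
        model = _FixedModel(CLASS_ORDER, y, scores)
        rep = evaluate(model, np.zeros((30, 1)), y)
        for i, c in enumerate(CLASS_ORDER):
            expected = auc_mann_whitney(scores[:, i], y == c)
            assert rep.per_class.loc[c, "auc"] == pytest.approx(expected)

    def test_permuting_test_rows_leaves_report_unchanged(self, rng):
        y = np.array(list(np.repeat(CLASS_ORDER, 10)))
        scores = rng.uniform(size=(30, 3))
        perm = rng.permutation(30)
        model_a = _FixedModel(CLASS_ORDER, y, scores)
        model_b = _FixedModel(CLASS_ORDER, y[perm], scores[perm])
        rep_a = evaluate(model_a, np.zeros((30, 1)), y)
        rep_b = evaluate(model_b, np.zeros((30, 1)), y[perm])
        assert np.array_equal(rep_a.confusion, rep_b.confusion)
        assert rep_a.accuracy == rep_b.accuracy
        pd.testing.assert_frame_equal(rep_a.per_class, rep_b.per_class)

    def test_empty_test_set(self):
        model = _FixedModel(CLASS_ORDER, [], np.zeros((0, 3)))
        with pytest.raises(ValueError):
            evaluate(model, np.zeros((0, 1)), np.array([]))
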