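import numpy as np
import pytest

from circstack.selection import FeatureMatrix, InputError
from circstack.stacking import (
    ConfusionMatrix,
    StackedModel,
    StackingConfig,
    base_meta_features,
    evaluate,
    fit_stacked,
    load_model,
    metrics_from_confusion,
    predict_stacked,
    save_model,
)


def matrix_with_ids(n, rng, labels=None):
    """Feature matrix whose first column is a unique row id (for stub learners)."""
    labels = rng.integers(0, 2, n) if labels is None else labels
    values = np.column_stack([np.arange(n, dtype=float), labels.astype(float),
                              rng.random(n)])
    return FeatureMatrix(values=values, feature_names=["row_id", "label_leak", "noise"],
                         ids=[f"r{i}" for i in range(n)], labels=labels)


class LabelEchoStub:
    """Predicts probability equal to the label column of X (second feature)."""

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p = X[:, 1]
        return np.column_stack([1 - p, p])


class MembershipStub:
    """Records training row ids; predicts 1.0 for rows it was trained on."""

    def fit(self, X, y):
        self.train_ids = set(X[:, 0].tolist())
        return self

    def predict_proba(self, X):
        p = np.array([1.0 if i in self.train_ids else 0.0 for i in X[:, 0]])
        return np.column_stack([1 - p, p])


class ConstantStub:
    def __init__(self, value):
        self.value = value

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p = np.full(len(X), self.value)
        return np.column_stack([1 - p, p])


def stub_config(factory):
    return StackingConfig(base_learners=tuple((f"s{i}", factory) for i in range(3)))


class TestFitStacked:
    def test_perfect_stub_meta_features_equal_labels(self, rng):
        m = matrix_with_ids(50, rng)
        model = fit_stacked(m, stub_config(lambda seed: LabelEchoStub()), seed=0)
        assert np.array_equal(model.oof_meta_features,
                              np.column_stack([m.labels] * 3).astype(float))
        # meta-learner separates perfectly on its training data
        probs, calls = predict_stacked(model, m)
        # stubs echo the label column at prediction time too
        assert evaluate(calls, m.labels)["acc"] == 1.0

    def test_out_of_fold_meta_features_never_come_from_own_fold(self, rng):
        """Leakage audit: a stub that flags its own training rows must
        produce an all-zero out-of-fold matrix."""
        m = matrix_with_ids(60, rng)
        model = fit_stacked(m, stub_config(lambda seed: MembershipStub()), seed=1)
        assert np.all(model.oof_meta_features == 0.0)

    def test_every_row_assigned_exactly_one_fold(self, rng):
        m = matrix_with_ids(53, rng)
        model = fit_stacked(m, stub_config(lambda seed: ConstantStub(0.5)), seed=2)
        assert model.fold_assignment.shape == (53,)
        assert set(model.fold_assignment) == set(range(5))

    def test_deterministic_under_seed(self, rng):
        m = matrix_with_ids(40, rng)
        cfg = stub_config(lambda seed: LabelEchoStub())
        m1 = fit_stacked(m, cfg, seed=9)
        m2 = fit_stacked(m, cfg, seed=9)
        assert np.array_equal(m1.fold_assignment, m2.fold_assignment)
        assert np.allclose(m1.meta_model.coef_, m2.meta_model.coef_)

    def test_errors(self, rng):
        single = matrix_with_ids(20, rng, labels=np.ones(20, dtype=int))
        with pytest.raises(InputError):
            fit_stacked(single, stub_config(lambda s: ConstantStub(0.5)))
        tiny = matrix_with_ids(6, rng, labels=np.array([0, 1] * 3))
        with pytest.raises(InputError):
            fit_stacked(tiny, stub_config(lambda s: ConstantStub(0.5)))


class TestPredictStacked:
    def _fitted(self, rng, factory):
        m = matrix_with_ids(30, rng, labels=np.array([0, 1] * 15))
        return m, fit_stacked(m, stub_config(factory), seed=0)

    def test_all_half_stubs_give_half_meta_input(self, rng):
        m, model = self._fitted(rng, lambda s: ConstantStub(0.5))
        meta = base_meta_features(model, m)
        assert np.allclose(meta, 0.5)

    def test_fold_averaging_is_arithmetic_mean(self, rng):
        m, model = self._fitted(rng, lambda s: ConstantStub(0.5))
        # overwrite one base learner's five fold models with fixed outputs
        model.fold_models["s0"] = [ConstantStub(v) for v in (0.2, 0.4, 0.6, 0.8, 1.0)]
        meta = base_meta_features(model, m)
        assert np.allclose(meta[:, 0], 0.6)

    def test_probabilities_bounded(self, rng):
        m, model = self._fitted(rng, lambda s: LabelEchoStub())
        probs, calls = predict_stacked(model, m)
        assert np.all((probs >= 0) & (probs <= 1))
        assert set(calls) <= {0, 1}

    def test_empty_input_gives_empty_output(self, rng):
        m, model = self._fitted(rng, lambda s: ConstantStub(0.5))
        empty = m.rows(np.zeros(30, dtype=bool))
        probs, calls = predict_stacked(model, empty)
        assert len(probs) == 0 and len(calls) == 0

    def test_column_mismatch_rejected(self, rng):
        m, model = self._fitted(rng, lambda s: ConstantStub(0.5))
        renamed = FeatureMatrix(values=m.values, feature_names=["a", "b", "c"],
                                ids=m.ids, labels=m.labels)
        with pytest.raises(InputError, match="row_id"):
            predict_stacked(model, renamed)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 0, 1])
        m = evaluate(y, y)
        for key in ("acc", "precision", "recall", "f1", "mcc", "specificity"):
            assert m[key] == 1.0

    def test_balanced_confusion(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=1, tn=1, fp=1, fn=1))
        assert m["acc"] == 0.5
        assert m["precision"] == 0.5
        assert m["recall"] == 0.5
        assert m["f1"] == 0.5
        assert m["mcc"] == 0.0

    def test_all_positive_calls_degenerate_mcc(self):
        calls = np.ones(10, dtype=int)
        labels = np.array([1] * 6 + [0] * 4)
        with pytest.warns(UserWarning, match="MCC"):
            m = evaluate(calls, labels)
        assert m["specificity"] == 0.0
        assert m["mcc"] == 0.0

    def test_mcc_bounds_and_f1_harmonic_mean(self, rng):
        for _ in range(20):
            calls = rng.integers(0, 2, 40)
            labels = rng.integers(0, 2, 40)
            cm = ConfusionMatrix.from_calls(calls, labels)
            if (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn) == 0:
                continue
            m = metrics_from_confusion(cm)
            assert -1 <= m["mcc"] <= 1
            if m["precision"] > 0 and m["recall"] > 0:
                hm = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
                assert m["f1"] == pytest.approx(hm)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            evaluate(np.zeros(3), np.zeros(4))


class TestPersistence:
    def test_save_load_round_trip(self, rng, tmp_path):
        from sklearn.tree import DecisionTreeClassifier

        def tree_factory(seed):
            return DecisionTreeClassifier(random_state=seed, max_depth=3)

        labels = np.array([0, 1] * 20)
        values = np.column_stack([labels + rng.normal(0, 0.3, 40), rng.random(40)])
        m = FeatureMatrix(values=values, feature_names=["sig", "noise"],
                          ids=[str(i) for i in range(40)], labels=labels)
        cfg = StackingConfig(base_learners=tuple((f"t{i}", tree_factory) for i in range(3)))
        model = fit_stacked(m, cfg, seed=4)
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        p1, c1 = predict_stacked(model, m)
        p2, c2 = predict_stacked(back, m)
        assert np.allclose(p1, p2)
        assert np.array_equal(c1, c2)
        assert back.feature_names == model.feature_names
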