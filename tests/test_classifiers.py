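"""Classifier contract: hand-computed oracles, symmetries, serialization."""

import numpy as np
import pytest

from qsarnet import (
    ClassifierSpec,
    DescriptorMatrix,
    PropertyLabels,
    TrainedModel,
    plsda_fit,
    prediction_table,
    train_classifier,
)


def dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"c{i}" for i in range(values.shape[0])]
    return DescriptorMatrix(ids, [f"d{j}" for j in range(values.shape[1])], values)


class TestSpecValidation:
    def test_unknown_algorithm(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            ClassifierSpec("GBM")

    def test_unknown_hyperparameter(self):
        with pytest.raises(ValueError, match="unknown hyperparameters"):
            ClassifierSpec("KNN", {"n_neighbors": 5})

    def test_defaults_resolved(self):
        assert ClassifierSpec("KNN").resolved()["k"] == 5
        assert ClassifierSpec("RF", {"n_trees": 10}).resolved()["n_trees"] == 10


class TestTraining:
    def test_separable_clusters_train_accuracy_one(self, separable_xy, any_spec):
        X, y = separable_xy
        model = train_classifier(X, y, any_spec)
        assert model.training_accuracy == 1.0

    def test_single_class_rejected(self):
        X = dm(np.random.default_rng(0).normal(size=(10, 2)))
        y = PropertyLabels(X.compound_ids, "OB", ["+"] * 10)
        with pytest.raises(ValueError, match="single class"):
            train_classifier(X, y, ClassifierSpec("KNN"))

    def test_length_mismatch_rejected(self):
        X = dm(np.zeros((4, 2)))
        y = PropertyLabels(["a", "b", "c"], "OB", ["+", "-", "+"])
        with pytest.raises(ValueError, match="labels"):
            train_classifier(X, y, ClassifierSpec("KNN"))


class TestKNN:
    def test_k1_predicts_own_label(self):
        rng = np.random.default_rng(1)
        X = dm(rng.normal(size=(12, 3)))
        y = PropertyLabels(X.compound_ids, "HIA", ["+", "-"] * 6)
        model = train_classifier(X, y, ClassifierSpec("KNN", {"k": 1}))
        assert model.predict(X) == y.classes

    def test_k3_matches_manual_distance_table(self):
        # fixed 2-D points and query; the oracle recomputes the Euclidean
        # distance table by hand in the model's documented metric
        # (z-scored columns) and takes the majority of the 3 nearest
        pts = np.array([[1.0, 0], [2, 0], [0, 2], [3, 3], [0, 3], [-1, 0], [0, -2], [-3, -3]])
        labels = ["+", "+", "-", "-", "-", "+", "-", "+"]
        X = dm(pts)
        y = PropertyLabels(X.compound_ids, "OB", labels)
        model = train_classifier(X, y, ClassifierSpec("KNN", {"k": 3}))
        query = np.array([[0.05, 0.0]])
        mu, sd = pts.mean(axis=0), pts.std(axis=0)
        d2 = ((((pts - mu) / sd) - ((query - mu) / sd)) ** 2).sum(axis=1)
        nearest = np.argsort(d2, kind="stable")[:3]
        manual = max("+-", key=[labels[i] for i in nearest].count)
        assert model.predict(query) == [manual]


class TestPLSDA:
    def test_first_weight_proportional_to_xty(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        Xc = X - X.mean(axis=0)
        y = rng.integers(0, 2, size=30).astype(float)
        W, T, P, B = plsda_fit(Xc, y, 1)
        direct = Xc.T @ (y - y.mean())
        direct /= np.linalg.norm(direct)
        np.testing.assert_allclose(W[:, 0], direct, atol=1e-12)

    def test_zero_components_predicts_majority(self):
        rng = np.random.default_rng(3)
        X = dm(rng.normal(size=(10, 3)))
        y = PropertyLabels(X.compound_ids, "OB", ["+"] * 7 + ["-"] * 3)
        model = train_classifier(X, y, ClassifierSpec("PLSDA", {"n_components": 0}))
        assert model.predict(X) == ["+"] * 10
        # balanced labels: decision value sits exactly on 0.5 -> tie -> "-"
        yb = PropertyLabels(X.compound_ids, "OB", ["+"] * 5 + ["-"] * 5)
        model = train_classifier(X, yb, ClassifierSpec("PLSDA", {"n_components": 0}))
        assert model.predict(X) == ["-"] * 10

    def test_rank_deficiency_raises(self):
        X = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        Xc = X - X.mean(axis=0)
        with pytest.raises(ValueError):
            plsda_fit(Xc, np.array([0, 1, 0, 1, 0, 1.0]), 2)

    def test_deflation_orthogonal_scores(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 6))
        Xc = X - X.mean(axis=0)
        y = rng.integers(0, 2, size=25).astype(float)
        _, T, _, _ = plsda_fit(Xc, y, 3)
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8


class TestPredictionContract:
    def test_empty_query_gives_empty_labels(self, separable_xy):
        X, y = separable_xy
        model = train_classifier(X, y, ClassifierSpec("KNN", {"k": 3}))
        assert model.predict(np.empty((0, 2))) == []

    def test_column_mismatch_rejected(self, separable_xy):
        X, y = separable_xy
        model = train_classifier(X, y, ClassifierSpec("KNN", {"k": 3}))
        bad = DescriptorMatrix(["q"], ["other1", "other2"], np.zeros((1, 2)))
        with pytest.raises(ValueError, match="descriptors"):
            model.predict(bad)

    def test_rf_interpolates_training_data(self, separable_xy):
        X, y = separable_xy
        model = train_classifier(X, y, ClassifierSpec("RF", {"n_trees": 50}, seed=0))
        assert model.predict(X) == y.classes

    def test_repeated_predictions_identical(self, separable_xy, any_spec):
        X, y = separable_xy
        model = train_classifier(X, y, any_spec)
        assert model.predict(X) == model.predict(X)

    @pytest.mark.parametrize("alg", ["KNN", "SVM", "PLSDA"])
    def test_label_flip_symmetry(self, alg):
        rng = np.random.default_rng(5)
        X = dm(rng.normal(size=(30, 3)))
        cls = ["+" if v else "-" for v in rng.integers(0, 2, size=30)]
        if cls.count("+") < 2 or cls.count("-") < 2:
            pytest.skip("degenerate draw")
        y = PropertyLabels(X.compound_ids, "OB", cls)
        q = rng.normal(size=(10, 3))
        spec = ClassifierSpec(alg, {"k": 3} if alg == "KNN" else {}, seed=0)
        a = train_classifier(X, y, spec).predict(q)
        b = train_classifier(X, y.flipped(), spec).predict(q)
        assert b == ["-" if c == "+" else "+" for c in a]

    @pytest.mark.parametrize("alg", ["KNN", "SVM", "PLSDA"])
    def test_row_permutation_invariance(self, alg):
        rng = np.random.default_rng(6)
        X = dm(rng.normal(size=(24, 3)))
        y = PropertyLabels(X.compound_ids, "OB", ["+", "-"] * 12)
        perm = rng.permutation(24)
        Xp = DescriptorMatrix([X.compound_ids[i] for i in perm],
                              X.descriptor_names, X.values[perm])
        yp = PropertyLabels(Xp.compound_ids, "OB", [y.classes[i] for i in perm])
        q = rng.normal(size=(8, 3))
        spec = ClassifierSpec(alg, {"k": 3} if alg == "KNN" else {}, seed=0)
        assert train_classifier(X, y, spec).predict(q) == \
            train_classifier(Xp, yp, spec).predict(q)

    def test_serialization_round_trip(self, separable_xy, any_spec, tmp_path):
        X, y = separable_xy
        model = train_classifier(X, y, any_spec)
        rng = np.random.default_rng(7)
        q = rng.normal(size=(20, 2)) * 3
        path = tmp_path / "model.joblib"
        model.save(path)
        reloaded = TrainedModel.load(path)
        assert reloaded.predict(q) == model.predict(q)


def test_prediction_table_layout(separable_xy):
    X, y = separable_xy
    models = {}
    for prop in ("OB", "HIA", "Caco2", "PGPS", "PGPI"):
        yp = PropertyLabels(y.compound_ids, prop, y.classes)
        models[prop] = train_classifier(X, yp, ClassifierSpec("KNN", {"k": 3}))
    table = prediction_table(models, X)
    assert list(table.columns) == ["Caco2", "PGPS", "PGPI", "OB", "HIA"]
    assert table.shape == (40, 5)
    assert table.isin(["+", "-"]).all().all()
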