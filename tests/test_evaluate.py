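"""Splits, cross-validation oracles, the model factorial, leverage AD."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold

from qsarnet import (
    ClassifierSpec,
    DescriptorMatrix,
    GAConfig,
    PropertyLabels,
    applicability_domain,
    cross_validate,
    factorial_evaluate,
    select_best_models,
    split_dataset,
    train_classifier,
)


def toy_xy(n=10, seed=0, pos=5):
    rng = np.random.default_rng(seed)
    X = DescriptorMatrix([f"c{i}" for i in range(n)],
                         ["d0", "d1"], rng.normal(size=(n, 2)))
    y = PropertyLabels(X.compound_ids, "OB", ["+"] * pos + ["-"] * (n - pos))
    return X, y


class TestSplit:
    def test_sizes_ten_compounds(self):
        X, y = toy_xy(10, pos=5)
        split = split_dataset(X, y, (0.6, 0.2, 0.2), seed=0)
        assert split.sizes() == {"TRS": 6, "TES": 2, "VAS": 2}

    def test_stratification_within_one(self):
        X, y = toy_xy(30, pos=18)
        split = split_dataset(X, y, (0.6, 0.2, 0.2), seed=1)
        overall = 18 / 30
        for part in ("TRS", "TES", "VAS"):
            ids = split.ids(part)
            frac = np.mean([y.classes[y.compound_ids.index(c)] == "+" for c in ids])
            assert abs(frac * len(ids) - overall * len(ids)) <= 1.0

    def test_partitions_disjoint_exhaustive(self):
        X, y = toy_xy(25, pos=12)
        split = split_dataset(X, y, (0.6, 0.2, 0.2), seed=2)
        parts = [set(split.ids(p)) for p in ("TRS", "TES", "VAS")]
        assert set().union(*parts) == set(y.compound_ids)
        assert sum(len(p) for p in parts) == 25

    def test_seed_reproducibility(self):
        X, y = toy_xy(20, pos=10)
        a = split_dataset(X, y, (0.6, 0.2, 0.2), seed=3)
        b = split_dataset(X, y, (0.6, 0.2, 0.2), seed=3)
        assert a.assignment == b.assignment

    def test_infeasible_stratification_raises(self):
        X, y = toy_xy(10, pos=2)  # only 2 positives for 3 partitions
        with pytest.raises(ValueError, match="partition"):
            split_dataset(X, y, (0.6, 0.2, 0.2), seed=0)

    def test_bad_ratios_rejected(self):
        X, y = toy_xy(10, pos=5)
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset(X, y, (0.5, 0.2, 0.2), seed=0)


class TestCrossValidation:
    def test_loo_perfect_on_duplicated_points(self):
        # every point has an identical labelled twin -> 1-NN LOO is perfect
        base = np.array([[0.0, 0], [1, 5], [4, 1], [2, 2], [5, 5]])
        X = np.vstack([base, base])
        y = PropertyLabels([f"c{i}" for i in range(10)], "OB",
                           ["+", "-", "+", "-", "+"] * 2)
        acc = cross_validate(X, y, ClassifierSpec("KNN", {"k": 1}), scheme="loo")
        assert acc == 1.0

    def test_majority_predictor_scores_base_rate(self):
        # 0-component PLS-DA predicts the training majority; with 7 "+" of
        # 10, every LOO training fold still has "+" majority -> accuracy 0.7
        X, y = toy_xy(10, pos=7)
        acc = cross_validate(X, y, ClassifierSpec("PLSDA", {"n_components": 0}),
                             scheme="loo")
        assert acc == pytest.approx(0.7)

    def test_five_fold_matches_manual_fold_by_fold(self):
        X, y = toy_xy(10, pos=5, seed=4)
        spec = ClassifierSpec("KNN", {"k": 3})
        acc = cross_validate(X, y, spec, scheme="kfold", k=5, seed=7)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=7)
        correct = 0
        for tr, te in skf.split(X.values, y.y):
            y_tr = PropertyLabels([y.compound_ids[i] for i in tr], "OB",
                                  [y.classes[i] for i in tr])
            model = train_classifier(X.values[tr], y_tr, spec)
            pred = model.predict(X.values[te])
            correct += sum(p == y.classes[i] for p, i in zip(pred, te))
        assert acc == pytest.approx(correct / 10)

    def test_loo_equals_nfold(self):
        X, y = toy_xy(12, pos=6, seed=5)
        spec = ClassifierSpec("KNN", {"k": 3})
        assert cross_validate(X, y, spec, scheme="loo") == \
            cross_validate(X, y, spec, scheme="kfold", k=12)

    def test_invalid_scheme(self):
        X, y = toy_xy()
        with pytest.raises(ValueError, match="scheme"):
            cross_validate(X, y, ClassifierSpec("KNN"), scheme="bootstrap")


class TestFactorial:
    def test_minimal_factorial_single_row(self):
        X, y = toy_xy(30, pos=15, seed=6)
        table = factorial_evaluate(
            {"OB": (X, y)}, {"KNN": ClassifierSpec("KNN", {"k": 3})},
            GAConfig(population_size=6, generations=2, cv_folds=3, seed=0),
            seed=0, loo=True, include_ga=False,
        )
        assert len(table) == 1
        row = table.iloc[0]
        assert not row["failed"]
        for col in ("trs_accuracy", "tes_accuracy", "vas_accuracy",
                    "loo_accuracy", "cv5_accuracy"):
            assert 0.0 <= row[col] <= 1.0

    def test_best_model_selection_tie_rules(self):
        table = pd.DataFrame([
            # vas ties at 0.9 -> fewer features wins
            dict(property="OB", algorithm="RF", ga_used=False, n_features=10,
                 vas_accuracy=0.9, failed=False),
            dict(property="OB", algorithm="SVM", ga_used=True, n_features=4,
                 vas_accuracy=0.9, failed=False),
            # full tie on vas and features -> algorithm order (KNN first)
            dict(property="HIA", algorithm="EBPT", ga_used=False, n_features=5,
                 vas_accuracy=0.8, failed=False),
            dict(property="HIA", algorithm="KNN", ga_used=False, n_features=5,
                 vas_accuracy=0.8, failed=False),
            # failed rows are never selected
            dict(property="PGPS", algorithm="KNN", ga_used=False, n_features=5,
                 vas_accuracy=np.nan, failed=True),
            dict(property="PGPS", algorithm="RF", ga_used=False, n_features=9,
                 vas_accuracy=0.6, failed=False),
        ])
        best = select_best_models(table)
        by_prop = best.set_index("property")
        assert by_prop.loc["OB", "algorithm"] == "SVM"
        assert by_prop.loc["HIA", "algorithm"] == "KNN"
        assert by_prop.loc["PGPS", "algorithm"] == "RF"


class TestApplicabilityDomain:
    def test_warning_leverage_closed_form(self):
        rng = np.random.default_rng(7)
        report = applicability_domain(rng.normal(size=(30, 2)))
        assert report.h_star == pytest.approx(3 * (2 + 1) / 30)

    def test_training_leverages_sum_to_p_plus_one(self):
        rng = np.random.default_rng(8)
        report = applicability_domain(rng.normal(size=(10, 3)))
        assert report.train_leverages.sum() == pytest.approx(4.0, abs=1e-8)
        assert (report.train_leverages >= 0).all()

    def test_centroid_query_leverage(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 3))
        report = applicability_domain(X, X.mean(axis=0, keepdims=True))
        assert report.leverages[0] == pytest.approx(1 / 20)
        assert report.in_domain[0]

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(25, 3))
        q = rng.normal(size=(5, 3))
        a = applicability_domain(X, q)
        scale = np.array([2.0, 0.5, 10.0])
        shift = np.array([1.0, -3.0, 7.0])
        b = applicability_domain(X * scale + shift, q * scale + shift)
        np.testing.assert_allclose(a.leverages, b.leverages, atol=1e-8)

    def test_singular_design_raises(self):
        x = np.arange(12.0)
        X = np.column_stack([x, 2 * x])  # collinear
        with pytest.raises(np.linalg.LinAlgError):
            applicability_domain(X)

    def test_too_few_training_rows(self):
        with pytest.raises(ValueError, match="n_train"):
            applicability_domain(np.ones((3, 3)))
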