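"""Classifier training, evaluation metrics, hyperparameter sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import precision_recall_fscore_support

from accelethogram import classify
from accelethogram.errors import DegenerateTrainingError, InvalidArgumentError


def _toy_features(n_per_class=60, seed=0, classes=("swim", "feed"), sep=5.0):
    """Two well-separated Gaussian blobs in a 3-predictor space."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, cls in enumerate(classes):
        x = rng.standard_normal((n_per_class, 3)) + i * sep
        for row in x:
            rows.append({"a_mean": row[0], "b_mean": row[1], "c_mean": row[2],
                         "behaviour": cls})
    df = pd.DataFrame(rows)
    df.insert(0, "window_start", np.arange(len(df), dtype=float))
    df.insert(1, "fish_id", "T1")
    return df


class TestSplit:
    def test_partition_arithmetic(self):
        df = _toy_features(n_per_class=500)
        train, test = classify.split_train_test(df, 0.7, seed=5)
        assert len(train) == 700 and len(test) == 300
        merged = pd.concat([train, test]).sort_values("window_start")
        np.testing.assert_array_equal(
            merged["window_start"].to_numpy(), df["window_start"].to_numpy()
        )

    def test_deterministic_per_seed(self):
        df = _toy_features()
        a1, b1 = classify.split_train_test(df, 0.7, seed=9)
        a2, b2 = classify.split_train_test(df, 0.7, seed=9)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_class_proportions_preserved_at_scale(self):
        df = _toy_features(n_per_class=5000)
        train, _ = classify.split_train_test(df, 0.7, seed=3)
        pooled = df["behaviour"].value_counts(normalize=True)
        got = train["behaviour"].value_counts(normalize=True)
        assert abs(pooled["swim"] - got["swim"]) < 0.05

    def test_missing_class_warns_not_fails(self):
        df = _toy_features(n_per_class=2)
        df.loc[df.index[-1], "behaviour"] = "chafe"  # single chafe row
        with pytest.warns(UserWarning, match="absent"):
            for seed in range(20):  # some seed puts the chafe row in test
                classify.split_train_test(df, 0.5, seed=seed)


class TestTrainForest:
    def test_separable_classes_near_zero_oob(self):
        model = classify.train_forest(_toy_features(), ntree=200, seed=1)
        assert model.oob_error < 0.01
        assert model.mtry == 1  # floor(sqrt(3))
        assert model.predictors == ["a_mean", "b_mean", "c_mean"]

    def test_single_class_rejected(self):
        df = _toy_features(classes=("swim",))
        with pytest.raises(DegenerateTrainingError):
            classify.train_forest(df, ntree=10)

    def test_seeded_training_reproducible(self):
        df = _toy_features()
        m1 = classify.train_forest(df, ntree=50, seed=2)
        m2 = classify.train_forest(df, ntree=50, seed=2)
        np.testing.assert_array_equal(m1.predict(df), m2.predict(df))

    def test_prediction_rejects_mismatched_columns(self):
        model = classify.train_forest(_toy_features(), ntree=20, seed=1)
        with pytest.raises(InvalidArgumentError, match="lacks predictors"):
            model.predict(pd.DataFrame({"a_mean": [0.0]}))

    def test_noise_predictor_ranks_below_signal(self):
        rng = np.random.default_rng(4)
        df = _toy_features(n_per_class=150, seed=4)
        df["noise_mean"] = rng.permutation(df["a_mean"].to_numpy())
        model = classify.train_forest(df, ntree=200, seed=4, compute_importance=True)
        ranking = list(model.importance.index)
        assert ranking.index("noise_mean") > ranking.index("a_mean")


class TestSweep:
    def test_grid_shape_and_consistency(self):
        df = _toy_features(n_per_class=40)
        table = classify.sweep_hyperparameters(
            df, ntree_grid=(50, 100), mtry_grid=(1, 2), seed=6, plateau_after=50
        )
        assert len(table) == 4
        single = classify.sweep_hyperparameters(
            df, ntree_grid=(100,), mtry_grid=(2,), seed=6
        )
        direct = classify.train_forest(df, ntree=100, mtry=2, seed=6)
        assert single["oob_error"].iloc[0] == pytest.approx(direct.oob_error)

    def test_forests_stabilise_with_trees(self, experiment):
        sub = experiment.train.sample(n=800, random_state=0)
        table = classify.sweep_hyperparameters(
            sub, ntree_grid=(100, 400), mtry_grid=(8,), seed=6, plateau_after=100
        )
        errs = table.set_index("ntree")["oob_error"]
        assert errs[400] <= errs[100] + 0.01


class TestEvaluate:
    def test_chafe_worked_example(self):
        assert classify.round_half_up(classify.f1_score(0.90, 0.31)) == 0.46

    @given(st.floats(0.01, 1.0))
    def test_harmonic_mean_identity(self, x):
        assert classify.f1_score(x, x) == pytest.approx(x)

    def test_f1_zero_when_both_zero(self):
        assert classify.f1_score(0.0, 0.0) == 0.0

    def test_diagonal_confusion_is_perfect(self):
        confusion = pd.DataFrame(np.diag([5, 3, 2]), index=list("abc"), columns=list("abc"))
        per_class, acc = classify.confusion_metrics(confusion)
        assert acc == 1.0
        assert (per_class["f1"] == 1.0).all()

    def test_f1_bounded_by_precision_and_recall(self):
        confusion = pd.DataFrame(
            [[8, 2, 0], [1, 5, 4], [0, 3, 7]], index=list("abc"), columns=list("abc")
        )
        per_class, _ = classify.confusion_metrics(confusion)
        for _, row in per_class.iterrows():
            assert min(row["precision"], row["recall"]) - 1e-12 <= row["f1"]
            assert row["f1"] <= max(row["precision"], row["recall"]) + 1e-12

    def test_matches_sklearn_oracle(self):
        df = _toy_features(n_per_class=80, seed=3, sep=1.2)  # imperfect separation
        train, test = classify.split_train_test(df, 0.7, seed=1)
        model = classify.train_forest(train, ntree=100, seed=1)
        report = classify.evaluate(model, test)
        predicted = model.predict(test)
        p, r, f1, _ = precision_recall_fscore_support(
            test["behaviour"], predicted, labels=report.confusion.index.tolist(),
            zero_division=0,
        )
        np.testing.assert_allclose(report.per_class["precision"], p, atol=1e-12)
        np.testing.assert_allclose(report.per_class["recall"], r, atol=1e-12)
        np.testing.assert_allclose(report.per_class["f1"], f1, atol=1e-12)

    def test_marginals_conserve_test_counts(self, experiment):
        report = experiment.report
        actual_counts = experiment.test["behaviour"].value_counts()
        for cls in report.confusion.index:
            assert report.confusion.loc[cls].sum() == actual_counts.get(cls, 0)
        assert report.confusion.to_numpy().sum() == len(experiment.test)
        trace = np.trace(report.confusion.to_numpy())
        assert report.overall_accuracy == pytest.approx(
            trace / report.confusion.to_numpy().sum()
        )

    def test_unlabelled_test_rows_rejected(self):
        model = classify.train_forest(_toy_features(), ntree=20, seed=1)
        bad = _toy_features().assign(behaviour=None)
        with pytest.raises(InvalidArgumentError):
            classify.evaluate(model, bad)

    def test_rounding_convention_half_up(self):
        assert classify.round_half_up(0.125) == 0.13
        assert classify.round_half_up(0.375, 2) == 0.38
        assert classify.round_half_up(37.5, 0) == 38.0
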