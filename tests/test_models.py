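"""Tests for label policies, grid search, cross-validation and final models."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import ParameterGrid

from imuscore.features import feature_columns
from imuscore.models import (
    DEFAULT_GRID,
    CvProtocol,
    apply_label_policy,
    cross_validate,
    grid_search,
    make_policy,
    predict_scores,
    sensor_columns,
    train_final,
)
from imuscore.synth import TaskLabel


def blob_table(n_per_class=40, n_features=6, separation=4.0, seed=0, task="PS"):
    """Two-class synthetic feature table with the required label columns."""
    rng = np.random.default_rng(seed)
    cols = [f"accel_magnitude_1_f{i}" for i in range(n_features)]
    x0 = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    x1 = rng.normal(separation, 1.0, size=(n_per_class, n_features))
    df = pd.DataFrame(np.vstack([x0, x1]), columns=cols)
    df.insert(0, "participant", [f"P{i:03d}" for i in range(2 * n_per_class)])
    df.insert(1, "group", "PD")
    df.insert(2, "hand", "right")
    df.insert(3, "task", task)
    df.insert(4, "score", [0] * n_per_class + [1] * n_per_class)
    return df, cols


class TestLabelPolicy:
    def test_default_grid_cardinality(self):
        assert len(ParameterGrid(DEFAULT_GRID)) == 29 * 4 * 3 * 3

    def test_binary_policy_drops_rare_scores_for_rest_task(self):
        df, _ = blob_table()
        df["task"] = "AR"
        df["score"] = ([0] * 30 + [1] * 30 + [2] * 10 + [3] * 10)
        out = apply_label_policy(df, make_policy("binary_score", "AR"))
        assert set(out["score"]) == {0, 1}
        assert set(out["target"]) == {0, 1}
        assert (out.loc[out["score"] == 0, "target"] == 0).all()
        assert (out.loc[out["score"] == 1, "target"] == 1).all()

    def test_multiclass_policy_retains_all_nonzero_scores_for_ps(self):
        df, _ = blob_table(n_per_class=50)
        df["score"] = ([0] * 20 + [1] * 20 + [2] * 20 + [3] * 20 + [4] * 20)
        out = apply_label_policy(df, make_policy("multiclass_score", "PS"))
        assert sorted(set(out["target"])) == [1, 2, 3, 4]

    def test_policy_emptying_table_raises(self):
        df, _ = blob_table()
        df["task"] = "AR"
        df["score"] = [2] * 40 + [3] * 40  # both excluded for AR
        with pytest.raises(ValueError):
            apply_label_policy(df, make_policy("binary_score", "AR"))

    def test_task_policy_targets_task_labels(self):
        df, _ = blob_table()
        out = apply_label_policy(df, make_policy("task_id"))
        assert (out["target"] == out["task"]).all()

    def test_design_validation(self):
        with pytest.raises(ValueError):
            make_policy("tertiary")
        with pytest.raises(ValueError):
            make_policy("binary_score")  # task required


class TestSensorColumns:
    def test_subset_selection_preserves_order(self):
        cols = feature_columns("magnitude")
        sub = sensor_columns(cols, ["accel", "mag"])
        assert len(sub) == 52
        assert sub == [c for c in cols if not c.startswith("gyro")]

    def test_invalid_subset_rejected(self):
        with pytest.raises(ValueError):
            sensor_columns(feature_columns("magnitude"), [])


class TestCrossValidate:
    def test_exactly_twenty_folds_with_stratification(self):
        df, cols = blob_table(n_per_class=30, separation=1.0)
        protocol = CvProtocol(seed=3)
        report = cross_validate(df, make_policy("binary_score", "PS"), cols,
                                protocol=protocol)
        assert len(report.fold_values) == protocol.n_evaluations == 20
        n = 60
        for y_true, _ in report.fold_predictions:
            n_test = len(y_true)
            for cls in (0, 1):
                expected = n_test * 30 / n
                assert abs(np.sum(y_true == cls) - expected) <= 1.0

    def test_permuted_labels_at_chance(self):
        rng = np.random.default_rng(7)
        df, cols = blob_table(n_per_class=60, separation=3.0, seed=7)
        df["score"] = rng.permutation(df["score"].to_numpy())
        report = cross_validate(df, make_policy("binary_score", "PS"), cols,
                                protocol=CvProtocol(seed=7))
        assert abs(report.mean - 0.5) < 0.1

    def test_bit_stable_given_seed(self):
        df, cols = blob_table(separation=1.5)
        kw = dict(protocol=CvProtocol(seed=11))
        a = cross_validate(df, make_policy("binary_score", "PS"), cols, **kw)
        b = cross_validate(df, make_policy("binary_score", "PS"), cols, **kw)
        assert a.fold_values == b.fold_values

    def test_rare_class_fails_loudly(self):
        df, cols = blob_table(n_per_class=30)
        df.loc[df.index[:57], "score"] = 0  # leaves 3 positives < 4 folds
        with pytest.raises(ValueError, match="stratify"):
            cross_validate(df, make_policy("binary_score", "PS"), cols)


class TestGridSearch:
    def test_single_point_grid_returned(self):
        df, cols = blob_table(n_per_class=20)
        point = {"n_estimators": [25], "max_depth": [5]}
        best, trace = grid_search(df, make_policy("binary_score", "PS"), cols,
                                  grid=point, protocol=CvProtocol(seed=1))
        assert best == {"n_estimators": 25, "max_depth": 5}
        assert len(trace) == 1

    def test_separable_problem_reaches_high_auroc(self):
        df, cols = blob_table(n_per_class=30, separation=5.0)
        grid = {"n_estimators": [25, 50], "max_depth": [5]}
        best, trace = grid_search(df, make_policy("binary_score", "PS"), cols,
                                  grid=grid, protocol=CvProtocol(seed=2))
        assert trace["mean_metric"].max() >= 0.99
        # tie-break: the winner is the first row attaining the maximum
        first_best = trace.loc[trace["mean_metric"].idxmax()]
        assert best["n_estimators"] == first_best["n_estimators"]


class TestTrainFinal:
    def test_training_accuracy_on_separable_data(self):
        df, cols = blob_table(separation=5.0)
        model = train_final(df, make_policy("binary_score", "PS"), cols, seed=1)
        pred = model.predict(apply_label_policy(df, make_policy("binary_score", "PS")))
        truth = apply_label_policy(df, make_policy("binary_score", "PS"))["target"]
        assert (pred == truth.to_numpy()).mean() >= 0.99

    def test_save_load_roundtrip(self, tmp_path):
        df, cols = blob_table()
        model = train_final(df, make_policy("binary_score", "PS"), cols, seed=4)
        path = tmp_path / "model.joblib"
        model.save(path)
        again = type(model).load(path)
        probe = apply_label_policy(df, make_policy("binary_score", "PS")).head(10)
        assert np.array_equal(model.predict(probe), again.predict(probe))
        assert path.with_suffix(".joblib.json").exists()

    def test_schema_mismatch_raises(self):
        df, cols = blob_table()
        model = train_final(df, make_policy("binary_score", "PS"), cols, seed=4)
        model.schema_hash = "0" * 16
        with pytest.raises(ValueError, match="schema"):
            model.predict(df)


class TestRegression:
    def regression_table(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for score in (1, 2, 3, 4):
            for i in range(25):
                rows.append({"score": score, "value": score + rng.normal(0, 0.3)})
        df = pd.DataFrame(rows)
        df["participant"] = [f"P{i:03d}" for i in range(len(df))]
        df["group"] = "PD"
        df["hand"] = "right"
        df["task"] = "PS"
        df["accel_magnitude_1_f0"] = df["value"]
        return df, ["accel_magnitude_1_f0"]

    def test_monotone_medians_recovered(self):
        df, cols = self.regression_table()
        model = train_final(df, make_policy("regression", "PS"), cols, seed=0)
        out = predict_scores(model, df)
        medians = out.groupby("score")["predicted"].median()
        assert medians.is_monotonic_increasing
        assert len(out) == len(df)  # grouping covers every row exactly once

    def test_constant_features_give_constant_predictions(self):
        df, cols = self.regression_table()
        df[cols[0]] = 1.0
        model = train_final(df, make_policy("regression", "PS"), cols, seed=0)
        pred = model.predict(df)
        assert np.allclose(pred, pred[0])

    def test_classification_model_rejected(self):
        df, cols = self.regression_table()
        clf = train_final(df, make_policy("binary_score", "PS"), cols, seed=0)
        with pytest.raises(ValueError):
            predict_scores(clf, df)


def test_svm_comparator_runs(feature_table):
    cols = feature_columns("magnitude")
    report = cross_validate(
        feature_table, make_policy("binary_score", TaskLabel.PS), cols,
        hyperparameters={"C": 10.0, "gamma": "scale"}, learner="svm",
        protocol=CvProtocol(seed=1),
    )
    assert len(report.fold_values) == 20
    assert report.mean > 0.7  # separable generator: well above chance

class TestNoLeakage:
    """The standardizer must only ever be fitted on training-fold rows."""

    def test_scaler_fit_sizes_match_training_folds(self, monkeypatch):
        import imuscore.models as models_mod
        from sklearn.preprocessing import StandardScaler as RealScaler

        seen_sizes = []

        class RecordingScaler(RealScaler):
            def fit(self, X, y=None, **kw):
                seen_sizes.append(len(X))
                return super().fit(X, y, **kw)

        monkeypatch.setattr(models_mod, "StandardScaler", RecordingScaler)
        df, cols = blob_table(n_per_class=30)
        protocol = CvProtocol(folds=3, repeats=2, seed=0)
        cross_validate(df, make_policy("binary_score", "PS"), cols,
                       protocol=protocol)
        n = 60
        assert len(seen_sizes) == protocol.n_evaluations
        for size in seen_sizes:
            assert size < n  # never the full table
            assert size in (n - n // 3, n - n // 3 - n % 3, 2 * n // 3)
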