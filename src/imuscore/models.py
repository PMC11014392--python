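"""Model designs, label policies, grid search and the repeated stratified
cross-validation protocol.

Four designs are supported on the per-recording feature table:

* ``task_id`` — six-class classification of the movement task itself;
* ``binary_score`` — score 0 (patients and controls) vs non-zero score,
  per task;
* ``multiclass_score`` — non-zero scores as separate classes, per task;
* ``regression`` — continuous prediction of the non-zero score, per task.

Rare score categories are excluded per task before modelling (scores 2 and
3 for AR, 2 for OA, 4 for HM and FT) to avoid classes too small to
stratify.  All supervised fitting runs inside a scikit-learn pipeline whose
first step is the z-score standardizer, so per-feature statistics are
learned from training folds only — never from held-out rows.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import accuracy_score, mean_absolute_error, roc_auc_score
from sklearn.model_selection import ParameterGrid, RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .evaluate import AverageAuroc, average_auroc
from .synth import TaskLabel

__all__ = [
    "DEFAULT_GRID",
    "DEFAULT_RF_PARAMS",
    "DEFAULT_SVM_GRID",
    "SCORE_EXCLUSIONS",
    "LabelPolicy",
    "CvProtocol",
    "CvReport",
    "TrainedModel",
    "make_policy",
    "apply_label_policy",
    "sensor_columns",
    "cross_validate",
    "grid_search",
    "train_final",
    "predict_scores",
]

#: Random-forest hyperparameter search space: 29 x 4 x 3 x 3 = 1044 points.
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": list(range(10, 151, 5)),
    "max_depth": [5, 16, 28, 40],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
}

#: Dependable mid-grid defaults used when a full search is not requested.
DEFAULT_RF_PARAMS: dict[str, object] = {
    "n_estimators": 100,
    "max_depth": 16,
    "min_samples_split": 2,
    "min_samples_leaf": 1,
}

#: RBF-kernel comparator search space (regularization x kernel width).
DEFAULT_SVM_GRID: dict[str, list] = {
    "C": [1.0, 10.0, 100.0],
    "gamma": ["scale", 0.01, 0.1],
}

#: Score categories excluded per task before score modelling (too rare to
#: stratify in the reference cohort profile).
SCORE_EXCLUSIONS: dict[TaskLabel, frozenset[int]] = {
    TaskLabel.AR: frozenset({2, 3}),
    TaskLabel.OA: frozenset({2}),
    TaskLabel.FN: frozenset(),
    TaskLabel.HM: frozenset({4}),
    TaskLabel.PS: frozenset(),
    TaskLabel.FT: frozenset({4}),
}

DESIGNS = ("task_id", "binary_score", "multiclass_score", "regression")
SENSORS = ("accel", "gyro", "mag")


@dataclass(frozen=True)
class LabelPolicy:
    """Row filtering and target construction for one model design."""

    design: str
    task: TaskLabel | None = None
    excluded_scores: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.design != "task_id" and self.task is None:
            raise ValueError(f"design {self.design!r} requires a task")


def make_policy(design: str, task: TaskLabel | str | None = None) -> LabelPolicy:
    """Standard policy for a design, with the per-task score exclusions."""
    task = TaskLabel(task) if task is not None else None
    excluded = SCORE_EXCLUSIONS.get(task, frozenset()) if task else frozenset()
    return LabelPolicy(design=design, task=task, excluded_scores=excluded)


def apply_label_policy(table: pd.DataFrame, policy: LabelPolicy) -> pd.DataFrame:
    """Filter rows per the policy and attach a ``target`` column.

    binary_score: 0 for score 0, 1 for retained non-zero scores.
    multiclass_score / regression: retained non-zero scores as the target
    (integer classes / float response); score 0 rows are excluded.
    """
    df = table
    if policy.design == "task_id":
        out = df.copy()
        out["target"] = out["task"]
        return out
    df = df[df["task"] == policy.task.value]
    df = df[~df["score"].isin(policy.excluded_scores)]
    if policy.design == "binary_score":
        out = df.copy()
        out["target"] = (out["score"] > 0).astype(int)
    else:
        out = df[df["score"] > 0].copy()
        out["target"] = (
            out["score"].astype(float) if policy.design == "regression" else out["score"]
        )
    if len(out) == 0:
        raise ValueError(f"no rows left after applying policy {policy}")
    return out


def sensor_columns(columns: Iterable[str], sensors: Sequence[str]) -> list[str]:
    """Feature columns belonging to a sensor subset, in table order."""
    sensors = tuple(sensors)
    if not sensors or any(s not in SENSORS for s in sensors):
        raise ValueError(f"sensors must be a non-empty subset of {SENSORS}")
    return [c for c in columns if c.split("_", 1)[0] in sensors]


@dataclass(frozen=True)
class CvProtocol:
    """Repeated stratified k-fold: 4 folds x 5 repeats = 20 evaluations."""

    folds: int = 4
    repeats: int = 5
    stratified: bool = True
    seed: int = 0
    grouping: str = "none"  # or "by_participant"

    @property
    def n_evaluations(self) -> int:
        return self.folds * self.repeats


@dataclass
class CvReport:
    """Per-fold metric values with their mean and 95 % CI, plus the raw
    per-fold predictions needed to draw ROC curves."""

    metric: str
    fold_values: list[float]
    summary: AverageAuroc
    fold_predictions: list[tuple[np.ndarray, np.ndarray]]  # (y_true, y_score) per fold
    classes: list | None = None

    @property
    def mean(self) -> float:
        return self.summary.mean


def _make_estimator(learner: str, design: str, params: Mapping, seed: int):
    params = dict(params)
    if learner == "random_forest":
        cls = RandomForestRegressor if design == "regression" else RandomForestClassifier
        return cls(bootstrap=True, random_state=seed, **params)
    if learner == "svm":
        if design == "regression":
            return SVR(kernel="rbf", **params)
        return SVC(kernel="rbf", probability=True, random_state=seed, **params)
    raise ValueError(f"unknown learner {learner!r}")


def _pipeline(learner: str, design: str, params: Mapping, seed: int) -> Pipeline:
    # standardizer inside the pipeline => fitted on training folds only
    return Pipeline(
        [("scale", StandardScaler()), ("model", _make_estimator(learner, design, params, seed))]
    )


def _fold_score(design: str, metric: str, model, X_test, y_test) -> tuple[float, np.ndarray]:
    if design == "regression":
        pred = model.predict(X_test)
        if metric == "neg_mae":
            return -float(mean_absolute_error(y_test, pred)), pred
        raise ValueError(f"unsupported regression metric {metric!r}")
    if metric == "accuracy":
        pred = model.predict(X_test)
        return float(accuracy_score(y_test, pred)), pred
    proba = model.predict_proba(X_test)
    if metric == "auroc":
        score = proba[:, 1]
        return float(roc_auc_score(y_test, score)), score
    if metric == "auroc_ovr":
        if proba.shape[1] == 2:
            # two retained classes: one-vs-rest macro AUROC reduces to the
            # plain binary AUROC (the two one-vs-rest curves mirror each other)
            value = roc_auc_score(y_test == model.classes_[1], proba[:, 1])
        else:
            value = roc_auc_score(
                y_test, proba, multi_class="ovr", average="macro", labels=model.classes_
            )
        return float(value), proba
    raise ValueError(f"unsupported metric {metric!r}")


def default_metric(design: str) -> str:
    return {
        "task_id": "accuracy",
        "binary_score": "auroc",
        "multiclass_score": "auroc_ovr",
        "regression": "neg_mae",
    }[design]


def _check_splittable(y: np.ndarray, protocol: CvProtocol, design: str) -> None:
    if design == "regression":
        return
    counts = pd.Series(y).value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two classes after the label policy")
    if counts.min() < protocol.folds:
        raise ValueError(
            f"class {counts.idxmin()!r} has only {counts.min()} rows; "
            f"cannot stratify into {protocol.folds} folds — relax the policy "
            "or merge classes explicitly"
        )


def _iter_splits(X: np.ndarray, y: np.ndarray, groups: np.ndarray | None, protocol: CvProtocol):
    if protocol.grouping == "by_participant":
        if groups is None:
            raise ValueError("by_participant grouping requires participant labels")
        # repeated grouped stratification: independent GroupKFold-like shuffles
        from sklearn.model_selection import StratifiedGroupKFold

        for rep in range(protocol.repeats):
            skf = StratifiedGroupKFold(
                n_splits=protocol.folds, shuffle=True, random_state=protocol.seed + rep
            )
            yield from skf.split(X, y, groups)
    else:
        strat = y
        if not protocol.stratified:
            strat = np.zeros(len(y), dtype=int)
        rskf = RepeatedStratifiedKFold(
            n_splits=protocol.folds, n_repeats=protocol.repeats, random_state=protocol.seed
        )
        yield from rskf.split(X, strat)


def _stratify_target(y: np.ndarray, design: str, folds: int) -> np.ndarray:
    if design != "regression":
        return y
    # regression folds stratify on the integer score so rare scores spread
    # across folds; if a score is rarer than the fold count, fall back to
    # plain shuffled folds rather than failing
    sy = y.astype(int)
    if pd.Series(sy).value_counts().min() >= folds:
        return sy
    return np.zeros(len(y), dtype=int)


def cross_validate(
    table: pd.DataFrame,
    policy: LabelPolicy,
    feature_cols: Sequence[str],
    hyperparameters: Mapping | None = None,
    protocol: CvProtocol | None = None,
    learner: str = "random_forest",
    metric: str | None = None,
) -> CvReport:
    """Evaluate one design under the repeated stratified CV protocol.

    Returns exactly folds × repeats fold-level metric values together with
    each fold's held-out predictions.  Standardization and model fitting
    see training-fold rows only.
    """
    protocol = protocol or CvProtocol()
    metric = metric or default_metric(policy.design)
    params = dict(hyperparameters or (DEFAULT_RF_PARAMS if learner == "random_forest" else {}))
    df = apply_label_policy(table, policy)
    X = df[list(feature_cols)].to_numpy(dtype=float)
    y = df["target"].to_numpy()
    groups = df["participant"].to_numpy() if "participant" in df else None
    strat_y = _stratify_target(y, policy.design, protocol.folds)
    if policy.design != "regression":
        _check_splittable(strat_y, protocol, policy.design)

    fold_values: list[float] = []
    fold_predictions: list[tuple[np.ndarray, np.ndarray]] = []
    classes: list | None = None
    for train_idx, test_idx in _iter_splits(X, strat_y, groups, protocol):
        model = _pipeline(learner, policy.design, params, protocol.seed)
        model.fit(X[train_idx], y[train_idx])
        value, score = _fold_score(policy.design, metric, model, X[test_idx], y[test_idx])
        fold_values.append(value)
        fold_predictions.append((y[test_idx], score))
        if classes is None and policy.design != "regression":
            classes = list(model.classes_)
    summary = average_auroc(fold_values)
    return CvReport(
        metric=metric,
        fold_values=fold_values,
        summary=summary,
        fold_predictions=fold_predictions,
        classes=classes,
    )


def grid_search(
    table: pd.DataFrame,
    policy: LabelPolicy,
    feature_cols: Sequence[str],
    grid: Mapping[str, Sequence] | None = None,
    protocol: CvProtocol | None = None,
    learner: str = "random_forest",
    metric: str | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive search over the hyperparameter grid.

    Every grid point is evaluated with the full CV protocol; the point with
    the highest mean fold metric wins, ties broken by enumeration order
    (first wins).  Returns (best parameters, full search trace).
    """
    grid = dict(grid) if grid is not None else (
        DEFAULT_GRID if learner == "random_forest" else DEFAULT_SVM_GRID
    )
    records = []
    best_params: dict | None = None
    best_value = -np.inf
    for params in ParameterGrid(grid):
        report = cross_validate(
            table, policy, feature_cols, params, protocol, learner=learner, metric=metric
        )
        records.append({**params, "mean_metric": report.mean})
        if report.mean > best_value:
            best_value = report.mean
            best_params = dict(params)
    trace = pd.DataFrame(records)
    assert best_params is not None
    return best_params, trace


def _schema_hash(feature_cols: Sequence[str]) -> str:
    return hashlib.sha256("\n".join(feature_cols).encode()).hexdigest()[:16]


@dataclass
class TrainedModel:
    """A fitted pipeline with full provenance for safe reuse."""

    pipeline: Pipeline
    design: str
    task: str | None
    learner: str
    sensors: tuple[str, ...]
    variant: str
    hyperparameters: dict
    feature_cols: list[str]
    schema_hash: str
    seed: int

    def _check_schema(self, feature_cols: Sequence[str]) -> None:
        if _schema_hash(feature_cols) != self.schema_hash:
            raise ValueError("feature schema mismatch: model was trained on different columns")

    def predict(self, table: pd.DataFrame):
        self._check_schema([c for c in self.feature_cols if c in table.columns])
        return self.pipeline.predict(table[self.feature_cols].to_numpy(dtype=float))

    def predict_proba(self, table: pd.DataFrame):
        if self.design == "regression":
            raise ValueError("regression models have no class probabilities")
        self._check_schema([c for c in self.feature_cols if c in table.columns])
        return self.pipeline.predict_proba(table[self.feature_cols].to_numpy(dtype=float))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump(self, path)
        manifest = {
            "design": self.design,
            "task": self.task,
            "learner": self.learner,
            "sensors": list(self.sensors),
            "variant": self.variant,
            "hyperparameters": {k: v for k, v in self.hyperparameters.items()},
            "schema_hash": self.schema_hash,
            "n_features": len(self.feature_cols),
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=2))

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        return joblib.load(path)


def train_final(
    table: pd.DataFrame,
    policy: LabelPolicy,
    feature_cols: Sequence[str],
    hyperparameters: Mapping | None = None,
    learner: str = "random_forest",
    seed: int = 0,
    sensors: Sequence[str] = SENSORS,
    variant: str = "magnitude",
) -> TrainedModel:
    """Fit on all provided rows and package the model with provenance."""
    params = dict(hyperparameters or (DEFAULT_RF_PARAMS if learner == "random_forest" else {}))
    df = apply_label_policy(table, policy)
    X = df[list(feature_cols)].to_numpy(dtype=float)
    y = df["target"].to_numpy()
    model = _pipeline(learner, policy.design, params, seed)
    model.fit(X, y)
    return TrainedModel(
        pipeline=model,
        design=policy.design,
        task=policy.task.value if policy.task else None,
        learner=learner,
        sensors=tuple(sensors),
        variant=variant,
        hyperparameters=params,
        feature_cols=list(feature_cols),
        schema_hash=_schema_hash(feature_cols),
        seed=seed,
    )


def predict_scores(model: TrainedModel, table: pd.DataFrame) -> pd.DataFrame:
    """Continuous score predictions of a regression model, grouped by the
    ground-truth score for boxplot-style summaries."""
    if model.design != "regression":
        raise ValueError("predict_scores requires a regression model")
    pred = model.predict(table)
    return pd.DataFrame({"score": table["score"].to_numpy(), "predicted": pred})
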