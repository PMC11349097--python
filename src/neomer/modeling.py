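"""Classification stage: scaling, importance-ranked feature exclusion,
grid-search tuning and held-out evaluation.

This stage is deliberately thin over scikit-learn. Samples carry the eight
RTp proportions plus clinical covariates (age, sex, clinical class,
optionally ApoE E4 count); the binary label is high vs low brain amyloid
(centiloid >= 30). Features are zero-mean scaled on the training split
only; models are tuned by exhaustive grid search with stratified 4-fold
cross-validation maximising accuracy; the least-important feature is
dropped between iterations; evaluation happens once per iteration on the
predefined test split at a 0.5 probability threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import clone
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

DEFAULT_CENTILOID_THRESHOLD = 30.0


def label_from_centiloid(value: float, threshold: float = DEFAULT_CENTILOID_THRESHOLD) -> int:
    """1 (high amyloid) iff centiloid >= threshold; the boundary counts as high."""
    if not math.isfinite(value):
        raise ValueError("centiloid value must be finite")
    return int(value >= threshold)


@dataclass
class FeatureTable:
    """Samples x features with binary labels and a predefined train/test split."""

    features: pd.DataFrame  # indexed by sample_id
    labels: pd.Series
    split: pd.Series  # 'train' | 'test'

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        if not self.labels.index.equals(self.features.index):
            raise ValueError("labels must align with features")
        if not set(self.split.unique()) <= {"train", "test"}:
            raise ValueError("split values must be 'train' or 'test'")

    def subset(self, which: str) -> tuple[pd.DataFrame, pd.Series]:
        mask = self.split == which
        return self.features.loc[mask], self.labels.loc[mask]


@dataclass
class ScalingRecord:
    means: pd.Series
    scales: pd.Series
    zero_variance: tuple[str, ...]


def zero_mean_scale(table: FeatureTable) -> tuple[FeatureTable, ScalingRecord]:
    """Standardise every feature to zero mean / unit variance on the train split.

    The transform is fitted on the training samples only and applied
    unchanged to the test samples, so no information about the held-out
    split leaks into preprocessing. Constant features are centred and left
    with zero variance, flagged in the record.
    """
    train_X, _ = table.subset("train")
    if train_X.empty:
        raise ValueError("train split is empty")
    scaler = StandardScaler().fit(train_X.to_numpy())
    zero_var = tuple(train_X.columns[np.asarray(scaler.var_) == 0.0])
    scaled = pd.DataFrame(
        scaler.transform(table.features.to_numpy()),
        index=table.features.index,
        columns=table.features.columns,
    )
    record = ScalingRecord(
        means=pd.Series(scaler.mean_, index=train_X.columns),
        scales=pd.Series(scaler.scale_, index=train_X.columns),
        zero_variance=zero_var,
    )
    return FeatureTable(scaled, table.labels, table.split), record


@dataclass
class ModelReport:
    model_name: str
    excluded_features: tuple[str, ...]
    hyperparameters: dict
    train_accuracy: float
    test_sensitivity: float
    test_specificity: float
    test_accuracy: float
    test_auroc: float
    feature_importances: dict[str, float]
    importance_source: str = ""


# estimator menu: name -> (factory, default hyperparameter grid)
def default_estimators(seed: int = 0) -> dict[str, tuple[Callable, dict]]:
    return {
        "LogisticRegression": (
            lambda: LogisticRegression(max_iter=2000, random_state=seed),
            {"C": [0.01, 0.1, 1.0, 10.0]},
        ),
        "DecisionTreeClassifier": (
            lambda: DecisionTreeClassifier(random_state=seed),
            {"max_depth": [2, 4, 8, None]},
        ),
        "RandomForestClassifier": (
            lambda: RandomForestClassifier(n_estimators=200, random_state=seed),
            {"max_depth": [4, 8, None]},
        ),
        "ExtraTreesClassifier": (
            lambda: ExtraTreesClassifier(n_estimators=200, random_state=seed),
            {"max_depth": [4, 8, None]},
        ),
        "GradientBoostingClassifier": (
            lambda: GradientBoostingClassifier(random_state=seed),
            {"learning_rate": [0.05, 0.1], "n_estimators": [100, 200]},
        ),
        "KNeighborsClassifier": (
            lambda: KNeighborsClassifier(),
            {"n_neighbors": [3, 5, 9]},
        ),
        "SVC": (
            lambda: SVC(probability=True, random_state=seed),
            {"C": [0.1, 1.0, 10.0]},
        ),
        "GaussianNB": (lambda: GaussianNB(), {}),
        "MLPClassifier": (
            lambda: MLPClassifier(max_iter=1000, random_state=seed),
            {"hidden_layer_sizes": [(16,), (32, 16)], "alpha": [1e-4, 1e-2]},
        ),
        "RidgeClassifier": (
            lambda: RidgeClassifier(random_state=seed),
            {"alpha": [0.1, 1.0, 10.0]},
        ),
    }


def _scores(model, X: np.ndarray) -> np.ndarray:
    """Probability-like score for the positive class in [0, 1]."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return expit(model.decision_function(X))


def evaluate(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    prob_threshold: float = 0.5,
) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and AUROC on held-out data.

    Sensitivity is recall of the high-amyloid class (label 1); predictions
    are thresholded at ``prob_threshold`` on the positive-class score.
    """
    scores = _scores(model, X_test)
    pred = (scores >= prob_threshold).astype(int)
    y = np.asarray(y_test, dtype=int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (tn + fp) if tn + fp else math.nan
    acc = (tp + tn) / len(y)
    auroc = roc_auc_score(y, scores) if len(np.unique(y)) == 2 else math.nan
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "auroc": float(auroc),
    }


def _importances(model, X: np.ndarray, y: np.ndarray, names, seed: int):
    """Per-feature importance and the convention used to obtain it.

    Impurity-based importances for tree models, absolute coefficients for
    linear models on standardised features, permutation importance (on the
    training data) otherwise. Values are clipped at zero and normalised to
    sum 1.
    """
    if hasattr(model, "feature_importances_"):
        imp = np.asarray(model.feature_importances_, dtype=float)
        source = "impurity"
    elif hasattr(model, "coef_"):
        imp = np.abs(np.asarray(model.coef_).ravel())
        source = "abs_coefficient"
    else:
        imp = permutation_importance(
            model, X, y, n_repeats=5, random_state=seed
        ).importances_mean
        source = "permutation"
    imp = np.clip(imp, 0.0, None)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return dict(zip(names, imp.astype(float))), source


def sequential_feature_exclusion(
    table: FeatureTable,
    estimator_name: str = "ExtraTreesClassifier",
    grid: Optional[dict] = None,
    folds: int = 4,
    seed: int = 0,
    min_features: int = 1,
    prob_threshold: float = 0.5,
) -> list[ModelReport]:
    """Importance-ranked sequential feature exclusion with grid-search tuning.

    Iteration 0 fits the estimator with default hyperparameters on all
    features to obtain an importance ranking; every iteration tunes the
    hyperparameters by exhaustive grid search under stratified k-fold
    cross-validation (accuracy criterion), refits on the training split,
    evaluates on the test split, and then drops the currently
    least-important feature before the next round. Deterministic given the
    seed.
    """
    menu = default_estimators(seed)
    if estimator_name not in menu:
        raise ValueError(f"unknown estimator {estimator_name!r}")
    factory, default_grid = menu[estimator_name]
    grid = default_grid if grid is None else grid

    X_train_df, y_train = table.subset("train")
    X_test_df, y_test = table.subset("test")
    if y_train.nunique() < 2:
        raise ValueError("training split contains a single class")
    features = list(X_train_df.columns)
    excluded: list[str] = []
    reports: list[ModelReport] = []
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    while len(features) >= max(min_features, 1):
        Xtr = X_train_df[features].to_numpy()
        Xte = X_test_df[features].to_numpy()
        ytr = y_train.to_numpy()
        if grid:
            search = GridSearchCV(factory(), grid, cv=cv, scoring="accuracy")
            search.fit(Xtr, ytr)
            model = search.best_estimator_
            best_params = search.best_params_
        else:
            model = factory().fit(Xtr, ytr)
            best_params = {}
        train_metrics = evaluate(model, Xtr, ytr, prob_threshold)
        test_metrics = evaluate(model, Xte, y_test.to_numpy(), prob_threshold)
        imps, source = _importances(model, Xtr, ytr, features, seed)
        reports.append(
            ModelReport(
                model_name=estimator_name,
                excluded_features=tuple(excluded),
                hyperparameters=dict(best_params),
                train_accuracy=train_metrics["accuracy"],
                test_sensitivity=test_metrics["sensitivity"],
                test_specificity=test_metrics["specificity"],
                test_accuracy=test_metrics["accuracy"],
                test_auroc=test_metrics["auroc"],
                feature_importances=imps,
                importance_source=source,
            )
        )
        if len(features) == max(min_features, 1):
            break
        # drop the currently least-important feature (ties: last in order)
        worst = min(features, key=lambda f: (imps[f], -features.index(f)))
        features.remove(worst)
        excluded.append(worst)
    return reports


def reports_to_frame(reports: Sequence[ModelReport]) -> pd.DataFrame:
    """Summary table, one row per iteration, mirroring the usual report layout."""
    return pd.DataFrame(
        {
            "Model": r.model_name,
            "Excluded Features": ", ".join(r.excluded_features),
            "Training Accuracy": r.train_accuracy,
            "Testing Sensitivity": r.test_sensitivity,
            "Testing Specificity": r.test_specificity,
            "Testing AUROC": r.test_auroc,
        }
        for r in reports
    )
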