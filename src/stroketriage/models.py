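"""Specialist classifier training: preprocessing, splits, SMOTE, tuning.

Wraps the model zoo (decision tree, random forest, gradient boosting,
k-NN, logistic regression, SVM) behind a uniform preprocessing pipeline
(identifier columns dropped, categoricals one-hot encoded, numerics
median-imputed with a missing indicator and standardized), a stratified
70/30 split, minority-class SMOTE balancing, and cost-sensitive
hyperparameter tuning via budgeted random search with three-fold
cross-validation. Reference configurations reproduce the named
specialist models (gini depth-2 tree for ischemic, k=2 nearest
neighbours for hemorrhagic, 600-tree gradient boosting for LVO).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (
    RandomizedSearchCV,
    StratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from stroketriage.cohort import ValidationError

__all__ = [
    "ModelSpec",
    "TuningConfig",
    "TrainedModel",
    "REFERENCE_MODELS",
    "stratified_split",
    "SMOTESampler",
    "smote_balance",
    "make_preprocessor",
    "tune_and_fit",
    "predict_proba",
]

_SCORING = {"f1": "f1", "auc": "roc_auc", "precision": "precision", "recall": "recall"}

_FAMILIES: dict[str, type[BaseEstimator]] = {
    "decision_tree": DecisionTreeClassifier,
    "random_forest": RandomForestClassifier,
    "gradient_boosting": GradientBoostingClassifier,
    "knn": KNeighborsClassifier,
    "logistic_regression": LogisticRegression,
    "svm": SVC,
}

_DEFAULT_SPACES: dict[str, dict[str, list]] = {
    "decision_tree": {
        "criterion": ["gini", "entropy"],
        "max_depth": [2, 3, 4, 6, 8, None],
        "min_samples_leaf": [1, 2, 5, 10, 20],
    },
    "random_forest": {
        "n_estimators": [100, 200, 400],
        "max_depth": [2, 4, 8, None],
        "min_samples_leaf": [1, 2, 5],
    },
    "gradient_boosting": {
        "n_estimators": [100, 300, 600],
        "max_depth": [2, 3, 4],
        "learning_rate": [0.01, 0.05, 0.1],
    },
    "knn": {"n_neighbors": [2, 3, 5, 7, 11], "weights": ["uniform", "distance"]},
    "logistic_regression": {"C": [0.01, 0.1, 1.0, 10.0]},
    "svm": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", "auto"]},
}


@dataclass(frozen=True)
class ModelSpec:
    """One model family plus its search space and optional fixed config."""

    family: str
    search_space: Mapping[str, list] | None = None
    reference_config: Mapping[str, object] | None = None

    def validate(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}; expected {sorted(_FAMILIES)}")
        space = self.search_space if self.search_space is not None else _DEFAULT_SPACES[self.family]
        if not space:
            raise ValidationError("search space must be non-empty")

    def make_estimator(self, seed: int | None = None) -> BaseEstimator:
        self.validate()
        kwargs: dict[str, object] = dict(self.reference_config or {})
        cls = _FAMILIES[self.family]
        if self.family == "logistic_regression":
            kwargs.setdefault("max_iter", 2000)
        if self.family == "svm":
            kwargs.setdefault("probability", True)
        est = cls(**kwargs)
        if "random_state" in est.get_params():
            est.set_params(random_state=seed)
        return est


#: Reference configurations of the named specialist models.
REFERENCE_MODELS: dict[str, ModelSpec] = {
    "ischemic": ModelSpec(
        "decision_tree",
        reference_config={"criterion": "gini", "max_depth": 2, "min_samples_leaf": 10},
    ),
    "hemorrhagic": ModelSpec("knn", reference_config={"n_neighbors": 2}),
    "lvo": ModelSpec(
        "gradient_boosting",
        reference_config={"n_estimators": 600, "max_depth": 4, "learning_rate": 0.1},
    ),
}


@dataclass(frozen=True)
class TuningConfig:
    """Cross-validated tuning policy (three folds, 70/30 split by default)."""

    cv_folds: int = 3
    search_method: str = "random"
    scoring: str = "f1"
    budget: int = 20
    train_fraction: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.budget < 1:
            raise ValidationError("budget must be >= 1")
        if self.scoring not in _SCORING:
            raise ValidationError(f"scoring must be one of {sorted(_SCORING)}")
        if self.search_method not in ("random", "bayesian"):
            raise ValidationError("search_method must be 'random' or 'bayesian'")


def stratified_split(
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    train_fraction: float = 0.7,
    seed: int = 0,
):
    """Class-stratified train/test partition; train size = floor(n * fraction)."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("stratified split needs at least two classes")
    if counts.min() < 2:
        raise ValidationError("every class needs at least 2 rows to stratify")
    return train_test_split(
        X, y, train_size=train_fraction, stratify=y, random_state=seed, shuffle=True
    )


class SMOTESampler(BaseEstimator):
    """Synthetic Minority Oversampling: interpolate minority rows to parity.

    Each synthetic row is a convex combination of a minority row and one
    of its ``k_neighbors`` nearest minority neighbours (Euclidean, in the
    encoded numeric feature space). Original rows are preserved; already
    balanced input is returned unchanged.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int = 0) -> None:
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        X_arr = np.asarray(X, dtype=float)
        y_arr = np.asarray(y)
        classes, counts = np.unique(y_arr, return_counts=True)
        if len(classes) != 2:
            raise ValidationError("SMOTE supports binary targets only")
        minority = classes[np.argmin(counts)]
        n_min, n_maj = counts.min(), counts.max()
        if n_min == n_maj:
            return X_arr.copy(), y_arr.copy()
        if n_min <= self.k_neighbors:
            raise ValidationError(
                f"minority class has {n_min} rows, not enough for k_neighbors="
                f"{self.k_neighbors}; use a smaller k"
            )
        X_min = X_arr[y_arr == minority]
        nn = NearestNeighbors(n_neighbors=self.k_neighbors + 1).fit(X_min)
        _, idx = nn.kneighbors(X_min)  # column 0 is the point itself

        rng = np.random.default_rng(self.random_state)
        n_syn = n_maj - n_min
        base = rng.integers(0, n_min, size=n_syn)
        neigh = idx[base, rng.integers(1, self.k_neighbors + 1, size=n_syn)]
        gaps = rng.random(n_syn)[:, None]
        synthetic = X_min[base] + gaps * (X_min[neigh] - X_min[base])

        X_out = np.vstack([X_arr, synthetic])
        y_out = np.concatenate([y_arr, np.full(n_syn, minority, dtype=y_arr.dtype)])
        return X_out, y_out


def smote_balance(X, y, k_neighbors: int = 5, seed: int = 0):
    """Functional wrapper over :class:`SMOTESampler`."""
    return SMOTESampler(k_neighbors=k_neighbors, random_state=seed).fit_resample(X, y)


# ---------------------------------------------------------------------------
# preprocessing + tuned fits

def make_preprocessor(X: pd.DataFrame, drop: Sequence[str] = ("patient_id", "event_time")):
    """Encoder + standardizer over a feature frame.

    Identifier columns are dropped; numeric columns are median-imputed
    with a missing indicator and standardized (constant columns map to
    0); categoricals are most-frequent-imputed and one-hot encoded.
    """
    cols = [c for c in X.columns if c not in drop]
    numeric = [c for c in cols if pd.api.types.is_numeric_dtype(X[c])]
    categorical = [c for c in cols if c not in numeric]
    transformers = []
    if numeric:
        transformers.append(
            (
                "num",
                Pipeline(
                    [
                        ("impute", SimpleImputer(strategy="median", add_indicator=True)),
                        ("scale", StandardScaler()),
                    ]
                ),
                numeric,
            )
        )
    if categorical:
        transformers.append(
            (
                "cat",
                Pipeline(
                    [
                        ("impute", SimpleImputer(strategy="most_frequent")),
                        ("onehot", OneHotEncoder(handle_unknown="ignore", sparse_output=False)),
                    ]
                ),
                categorical,
            )
        )
    return ColumnTransformer(transformers, remainder="drop")


@dataclass
class TrainedModel:
    """A fitted preprocessing + classifier pipeline with its CV summary."""

    pipeline: Pipeline
    family: str
    chosen_params: dict
    cv_mean: float
    cv_sd: float
    cv_ci: tuple[float, float]
    scoring: str
    feature_names: list[str] = field(default_factory=list)

    def _check_schema(self, rows: pd.DataFrame) -> pd.DataFrame:
        if isinstance(rows, pd.DataFrame) and self.feature_names:
            missing = [c for c in self.feature_names if c not in rows.columns]
            if missing:
                raise ValidationError(f"rows lack required column(s): {missing}")
            return rows[self.feature_names]
        return rows

    def predict(self, rows) -> np.ndarray:
        return self.pipeline.predict(self._check_schema(rows))

    def predict_proba(self, rows) -> np.ndarray:
        return self.pipeline.predict_proba(self._check_schema(rows))

    def positive_proba(self, rows) -> np.ndarray:
        """Probability of the positive (label 1) class per row."""
        proba = self.predict_proba(rows)
        pos_idx = list(self.pipeline.classes_).index(1)
        return proba[:, pos_idx]


def tune_and_fit(
    X_train: pd.DataFrame,
    y_train: Sequence,
    model_spec: ModelSpec,
    tuning: TuningConfig | None = None,
    smote: bool = False,
    smote_k: int = 5,
) -> TrainedModel:
    """Fit one specialist: optional SMOTE, then a tuned or reference model.

    With ``reference_config`` set on the spec the search is bypassed and
    that configuration fitted directly; otherwise a budgeted random
    search over the family's space picks hyperparameters by three-fold
    cross-validated score. The CV summary (mean, sd, normal-theory 95%
    CI) always refers to the finally chosen configuration.
    """
    tuning = tuning or TuningConfig()
    tuning.validate()
    model_spec.validate()
    if tuning.search_method == "bayesian":
        raise NotImplementedError(
            "Bayesian optimization is not implemented; use search_method='random'"
        )
    y_arr = np.asarray(y_train)
    if len(np.unique(y_arr)) < 2:
        raise ValidationError("training data must contain both classes")

    X_df = X_train if isinstance(X_train, pd.DataFrame) else pd.DataFrame(np.asarray(X_train))
    pre = make_preprocessor(X_df)
    Xt = pre.fit_transform(X_df)
    if smote:
        Xt, y_arr = smote_balance(Xt, y_arr, k_neighbors=smote_k, seed=tuning.seed)

    scoring = _SCORING[tuning.scoring]
    cv = StratifiedKFold(n_splits=tuning.cv_folds, shuffle=True, random_state=tuning.seed)
    base = model_spec.make_estimator(seed=tuning.seed)

    if model_spec.reference_config is not None:
        est = base
        chosen = dict(model_spec.reference_config)
    else:
        space = model_spec.search_space or _DEFAULT_SPACES[model_spec.family]
        n_combos = int(np.prod([len(v) for v in space.values()]))
        search = RandomizedSearchCV(
            base,
            space,
            n_iter=min(tuning.budget, n_combos),
            scoring=scoring,
            cv=cv,
            random_state=tuning.seed,
            refit=False,
        )
        search.fit(Xt, y_arr)
        chosen = dict(search.best_params_)
        est = clone(base).set_params(**chosen)

    scores = cross_val_score(clone(est), Xt, y_arr, cv=cv, scoring=scoring)
    mean, sd = float(np.mean(scores)), float(np.std(scores, ddof=1))
    half = 1.96 * sd / np.sqrt(tuning.cv_folds)
    est.fit(Xt, y_arr)

    # re-wrap preprocessing and classifier into one predict-time pipeline;
    # SMOTE only ever touches training rows
    pipeline = Pipeline([("preprocess", pre), ("classifier", est)])
    return TrainedModel(
        pipeline=pipeline,
        family=model_spec.family,
        chosen_params=chosen,
        cv_mean=mean,
        cv_sd=sd,
        cv_ci=(mean - half, mean + half),
        scoring=tuning.scoring,
        feature_names=list(X_df.columns),
    )


def predict_proba(model: TrainedModel, rows) -> np.ndarray:
    """Per-class probabilities (rows sum to 1) for conforming input rows."""
    return model.predict_proba(rows)
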