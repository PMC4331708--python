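"""Classifiers and the cross-validation protocol.

:class:`HairpinClassifier` wraps an RBF-kernel SVM (default) or a random
forest behind one scikit-learn estimator:

* features are scaled to [-1, 1] by training-set min/max (constant features
  map to 0);
* classes are weighted inversely to their frequencies, so heavily imbalanced
  negative sets (thousands of pseudo-hairpins against a few hundred true
  precursors) can be used verbatim;
* when SVM hyperparameters are not given, they are found by an inner
  grid search over C in 2^-5..2^15 and gamma in 2^-15..2^3 (log2 steps of 2)
  on the training data.

:func:`cross_validate` runs stratified five-fold CV with per-fold refitting
(scaling and any grid search included) and pools confusion counts across
folds.  Fold assignment hashes record ids with the seed: each class is
ordered by ``sha256(seed:id)`` and dealt round-robin, which keeps per-class
fold sizes within one of each other and is reproducible regardless of record
order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from ._version import __version__
from .exceptions import DataError
from .features import FEATURE_NAMES, HairpinFeaturizer
from .io import RnaSequence
from .metrics import ConfusionCounts, MetricsReport, compute_metrics

__all__ = [
    "HairpinClassifier",
    "cross_validate",
    "train",
    "predict_sequences",
    "save_model",
    "load_model",
]

SVM_C_GRID = [2.0**e for e in range(-5, 16, 2)]
SVM_GAMMA_GRID = [2.0**e for e in range(-15, 4, 2)]


class HairpinClassifier(ClassifierMixin, BaseEstimator):
    """SVM / random-forest classifier for hairpin candidates.

    Parameters
    ----------
    algorithm : {"svm_rbf", "random_forest"}
    C, gamma : float or None
        SVM hyperparameters; both None triggers an inner grid search.
    n_estimators, max_features :
        Random-forest size and features per split.
    feature_names : sequence of str or None
        Subset of canonical feature names to train on (None = all columns).
    inner_folds : int
        Folds of the hyperparameter grid search.
    random_state : int

    Attributes (after fit)
    ----------------------
    classes_ : ndarray
    scale_min_, scale_range_ : ndarray
        Training-set min and (max - min) per feature; zero-range features are
        mapped to 0.
    model_ : fitted sklearn estimator
    best_params_ : dict (SVM with grid search only)
    """

    def __init__(
        self,
        algorithm: str = "svm_rbf",
        C: float | None = None,
        gamma: float | None = None,
        n_estimators: int = 500,
        max_features: str | float = "sqrt",
        feature_names=None,
        inner_folds: int = 3,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.C = C
        self.gamma = gamma
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.feature_names = feature_names
        self.inner_folds = inner_folds
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _column_indices(self, X) -> np.ndarray | None:
        if self.feature_names is None:
            return None
        if isinstance(X, pd.DataFrame):
            cols = list(X.columns)
        else:
            cols = list(FEATURE_NAMES)
        missing = [n for n in self.feature_names if n not in cols]
        if missing:
            raise ValueError(f"unknown feature names: {missing}")
        return np.array([cols.index(n) for n in self.feature_names])

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D feature matrix")
        if not np.isfinite(X).all():
            raise ValueError("feature matrix contains non-finite values")
        return X

    def _scale(self, X: np.ndarray) -> np.ndarray:
        scaled = np.zeros_like(X)
        nz = self.scale_range_ > 0
        scaled[:, nz] = -1.0 + 2.0 * (X[:, nz] - self.scale_min_[nz]) / self.scale_range_[nz]
        return scaled

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        idx = self._column_indices(X)
        X = self._as_matrix(X)
        if idx is not None:
            X = X[:, idx]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("training data must contain exactly two classes")
        self.n_features_in_ = X.shape[1]

        self.scale_min_ = X.min(axis=0)
        self.scale_range_ = X.max(axis=0) - self.scale_min_
        Xs = self._scale(X)

        if self.algorithm == "svm_rbf":
            if self.C is None and self.gamma is None:
                search = GridSearchCV(
                    SVC(kernel="rbf", class_weight="balanced"),
                    param_grid={"C": SVM_C_GRID, "gamma": SVM_GAMMA_GRID},
                    scoring="balanced_accuracy",
                    cv=StratifiedKFold(
                        self.inner_folds, shuffle=True, random_state=self.random_state
                    ),
                    n_jobs=1,
                )
                search.fit(Xs, y)
                self.best_params_ = dict(search.best_params_)
                self.model_ = search.best_estimator_
            else:
                self.model_ = SVC(
                    kernel="rbf",
                    C=self.C if self.C is not None else 1.0,
                    gamma=self.gamma if self.gamma is not None else "scale",
                    class_weight="balanced",
                ).fit(Xs, y)
        elif self.algorithm == "random_forest":
            self.model_ = RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_features=self.max_features,
                class_weight="balanced",
                random_state=self.random_state,
                n_jobs=1,
            ).fit(Xs, y)
        else:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; use 'svm_rbf' or 'random_forest'"
            )
        self._column_idx_ = idx
        return self

    def _prepare(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = self._as_matrix(X)
        if self._column_idx_ is not None and X.shape[1] != self.n_features_in_:
            X = X[:, self._column_idx_]
        return self._scale(X)

    def predict(self, X) -> np.ndarray:
        if len(X) == 0:
            return np.array([], dtype=self.classes_.dtype if hasattr(self, "classes_") else int)
        return self.model_.predict(self._prepare(X))

    def decision_function(self, X) -> np.ndarray:
        """Monotone decision score (SVM margin; RF positive-class excess)."""
        if len(X) == 0:
            return np.array([])
        Xs = self._prepare(X)
        if self.algorithm == "svm_rbf":
            return self.model_.decision_function(Xs)
        proba = self.model_.predict_proba(Xs)
        return proba[:, -1] - 0.5


def _fold_of(record_id: str, seed: int) -> bytes:
    return hashlib.sha256(f"{seed}:{record_id}".encode()).digest()


def assign_folds(ids, y, folds: int, seed: int) -> np.ndarray:
    """Stratified fold labels keyed by hashed record ids.

    Within each class, records are ordered by ``sha256(seed:id)`` and dealt
    round-robin, so per-class fold sizes differ by at most one and the
    assignment does not depend on input order.
    """
    ids = list(ids)
    y = np.asarray(y)
    if len(set(ids)) != len(ids):
        raise DataError("record ids must be unique for fold assignment")
    fold = np.empty(len(ids), dtype=int)
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if len(members) < folds:
            raise ValueError(
                f"class {cls!r} has {len(members)} records, fewer than {folds} folds"
            )
        ordered = sorted(members, key=lambda k: _fold_of(ids[k], seed))
        for rank, k in enumerate(ordered):
            fold[k] = rank % folds
    return fold


def cross_validate(
    X,
    y,
    ids,
    estimator: HairpinClassifier | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[ConfusionCounts, MetricsReport]:
    """Stratified k-fold CV with pooled confusion counts.

    Scaling (and any hyperparameter search) is refitted inside each training
    fold; the pooled counts therefore reflect strictly out-of-fold
    predictions.  Positive class is ``y == 1``.
    """
    estimator = estimator if estimator is not None else HairpinClassifier()
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    fold = assign_folds(ids, y, folds=folds, seed=seed)
    pooled = ConfusionCounts(tp=0, fp=0, tn=0, fn=0)
    for f in range(folds):
        test = fold == f
        model = clone(estimator).fit(X[~test], y[~test])
        pred = model.predict(X[test])
        pooled = pooled + ConfusionCounts.from_labels(y[test], pred)
    return pooled, compute_metrics(pooled)


# -- functional wrappers over sequences -------------------------------------


@dataclass
class TrainedModel:
    """A fitted classifier bundled with its featurizer and selection manifest."""

    classifier: HairpinClassifier
    featurizer: HairpinFeaturizer
    selected_features: list[str] | None
    threshold: float | None
    version: str = __version__
    config_hash: str | None = None

    def manifest(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "algorithm": self.classifier.algorithm,
            "threshold": self.threshold,
            "selected_features": self.selected_features,
            "classifier_params": self.classifier.get_params(),
            "featurizer_params": self.featurizer.get_params(),
        }


def train(
    features: pd.DataFrame,
    y,
    featurizer: HairpinFeaturizer | None = None,
    estimator: HairpinClassifier | None = None,
    selected_features: list[str] | None = None,
    threshold: float | None = None,
) -> TrainedModel:
    """Fit a classifier on an extracted feature table."""
    estimator = estimator if estimator is not None else HairpinClassifier()
    if selected_features is not None:
        estimator = clone(estimator)
        estimator.set_params(feature_names=list(selected_features))
    estimator.fit(features, np.asarray(y).astype(int))
    return TrainedModel(
        classifier=estimator,
        featurizer=featurizer if featurizer is not None else HairpinFeaturizer(),
        selected_features=selected_features,
        threshold=threshold,
    )


def predict_sequences(
    model: TrainedModel, sequences: list[RnaSequence]
) -> pd.DataFrame:
    """Per-record predicted label and decision score.

    Records shorter than 3 nt are skipped with a warning (no features exist
    for them); the output frame has columns ``label`` and ``score`` indexed
    by record id.
    """
    import logging

    usable = []
    for seq in sequences:
        if len(seq) < 3:
            logging.getLogger(__name__).warning(
                "record %r shorter than 3 nt: skipped", seq.id
            )
            continue
        usable.append(seq)
    if not usable:
        return pd.DataFrame(columns=["label", "score"])
    features = model.featurizer.transform(usable)
    pred = model.classifier.predict(features)
    score = model.classifier.decision_function(features)
    return pd.DataFrame(
        {
            "label": ["positive" if p == 1 else "negative" for p in pred],
            "score": score,
        },
        index=pd.Index([s.id for s in usable], name="id"),
    )


def save_model(model: TrainedModel, path) -> None:
    """Serialise a trained model (joblib archive with manifest)."""
    joblib.dump({"manifest": model.manifest(), "model": model}, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    return payload["model"]
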