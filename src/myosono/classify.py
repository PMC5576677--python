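"""Ensemble-of-random-decision-trees classifier over feature vectors.

A thin, reproducible surface over scikit-learn's random forest.  Each tree is
trained on a bootstrap resample and considers a random feature subset at every
split; prediction pools one vote per tree, so the positive-class score is
exactly (votes for positive) / n_trees.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import DegenerateTrainingError, DimensionMismatchError


@dataclass(frozen=True)
class ClassifierConfig:
    """Forest hyperparameters; defaults are standard random-forest practice."""

    n_trees: int = 500
    features_per_split: int | str = "sqrt"
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise DegenerateTrainingError("n_trees must be >= 1")


@dataclass
class TrainedEnsemble:
    """A fitted forest plus the config and a fingerprint of its training set."""

    model: RandomForestClassifier
    config: ClassifierConfig
    n_features: int
    training_fingerprint: str


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    digest = hashlib.sha256()
    digest.update(np.ascontiguousarray(X, dtype=np.float64).tobytes())
    digest.update(np.ascontiguousarray(y, dtype=np.int64).tobytes())
    return digest.hexdigest()[:16]


def train_ensemble(
    X: np.ndarray, y: np.ndarray, config: ClassifierConfig | None = None
) -> TrainedEnsemble:
    """Fit the forest on feature rows ``X`` with binary labels ``y`` (0/1)."""
    config = config or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DimensionMismatchError(
            f"X {X.shape} and y {y.shape} are not aligned 2-D/1-D arrays"
        )
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise DegenerateTrainingError(
            f"need >= 2 examples per class, got counts {counts.tolist()}"
        )
    if np.isnan(X).any():
        raise DegenerateTrainingError("feature matrix contains missing values")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.features_per_split,
        max_depth=config.max_depth,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return TrainedEnsemble(
        model=model,
        config=config,
        n_features=X.shape[1],
        training_fingerprint=_fingerprint(X, y),
    )


def predict(
    ensemble: TrainedEnsemble, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vote-pooled prediction.

    Returns ``(labels, scores)`` where ``scores[i]`` is the fraction of trees
    voting class 1 for row ``i`` and ``labels[i] = scores[i] >= 0.5``.
    A single feature vector may be passed; outputs are then length-1 arrays.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != ensemble.n_features:
        raise DimensionMismatchError(
            f"feature vector length {X.shape[1]} != training length "
            f"{ensemble.n_features}"
        )
    classes = ensemble.model.classes_
    votes = np.zeros(X.shape[0])
    for tree in ensemble.model.estimators_:
        votes += classes[np.argmax(tree.predict_proba(X), axis=1)] == 1
    scores = votes / len(ensemble.model.estimators_)
    labels = (scores >= 0.5).astype(int)
    return labels, scores
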