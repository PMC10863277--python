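"""Bagged heterogeneous base learners combined by a greedy weighted ensemble.

Four learner families are registered — gradient-boosted trees (LightGBM),
random forest, k-nearest neighbors, and multinomial logistic regression (the
latter two behind a standardizing scaler).  Each learner is trained with
stratified k-fold bagging (default k = 5): one model per fold, out-of-fold
class probabilities collected for every training sample, and prediction-time
probabilities averaged over the k fold models.

Ensemble weights are found by Caruana-style greedy forward selection with
replacement on the out-of-fold probabilities: repeatedly add the learner that
most improves out-of-fold accuracy, then convert selection frequencies into
weights.  The best prefix of the greedy path is kept, so the ensemble's
out-of-fold accuracy never falls below the best single learner's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .io import CLASS_LABELS, ValidationError

__all__ = [
    "BaseLearnerSpec",
    "DEFAULT_LEARNERS",
    "make_learner",
    "train_bagged",
    "fit_ensemble_weights",
    "TrainedEnsemble",
    "train_ensemble",
    "predict",
    "PredictionResult",
]


@dataclass(frozen=True)
class BaseLearnerSpec:
    """A registered learner family plus its hyperparameters and seed."""

    name: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0


DEFAULT_LEARNERS = (
    BaseLearnerSpec("gradient_boosted_trees"),
    BaseLearnerSpec("random_forest"),
    BaseLearnerSpec("k_nearest_neighbors"),
    BaseLearnerSpec("multinomial_logistic"),
)


def make_learner(spec: BaseLearnerSpec):
    """Instantiate a registered base learner as a fit/predict_proba estimator."""
    hp = dict(spec.hyperparameters)
    if spec.name == "gradient_boosted_trees":
        from lightgbm import LGBMClassifier

        params = {
            "n_estimators": 150,
            "num_leaves": 15,
            "min_child_samples": 3,
            "random_state": spec.seed,
            "n_jobs": 1,
            "verbose": -1,
        }
        params.update(hp)
        return LGBMClassifier(**params)
    if spec.name == "random_forest":
        params = {"n_estimators": 300, "random_state": spec.seed, "n_jobs": 1}
        params.update(hp)
        return RandomForestClassifier(**params)
    if spec.name == "k_nearest_neighbors":
        params = {"n_neighbors": 5}
        params.update(hp)
        return make_pipeline(StandardScaler(), KNeighborsClassifier(**params))
    if spec.name == "multinomial_logistic":
        params = {"max_iter": 5000, "C": 1.0}
        params.update(hp)
        return make_pipeline(StandardScaler(), LogisticRegression(**params))
    raise ValidationError(f"unknown base learner {spec.name!r}")


def _aligned_proba(model, X: np.ndarray, class_order: Sequence[str]) -> np.ndarray:
    """predict_proba re-indexed to the fixed class order (absent classes -> 0)."""
    proba = model.predict_proba(X)
    classes = list(model.classes_) if hasattr(model, "classes_") else list(model[-1].classes_)
    out = np.zeros((X.shape[0], len(class_order)))
    for j, c in enumerate(classes):
        out[:, class_order.index(c)] = proba[:, j]
    return out


@dataclass
class BaggedLearner:
    spec: BaseLearnerSpec
    fold_models: list
    oof_proba: np.ndarray  # (n_train, n_classes), aligned to class_order

    def predict_proba(self, X: np.ndarray, class_order: Sequence[str]) -> np.ndarray:
        probs = [_aligned_proba(m, X, class_order) for m in self.fold_models]
        return np.mean(probs, axis=0)


def train_bagged(
    X: np.ndarray,
    y: Sequence[str],
    k: int = 5,
    learners: Sequence[BaseLearnerSpec] = DEFAULT_LEARNERS,
    seed: int = 0,
    class_order: Sequence[str] | None = None,
) -> tuple[list[BaggedLearner], list[str]]:
    """Stratified k-fold bagging for each base learner.

    Every training sample receives exactly one out-of-fold prediction per
    learner.  If the smallest class has fewer than k members, k is reduced
    with a warning (k >= 2 always).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    labels = sorted(set(y), key=lambda c: CLASS_LABELS.index(c) if c in CLASS_LABELS else 99)
    if len(labels) < 2:
        raise ValidationError("training labels contain a single class")
    if class_order is None:
        class_order = labels
    class_order = list(class_order)
    min_count = min(np.sum(y == c) for c in labels)
    if min_count < k:
        warnings.warn(f"smallest class has {min_count} members; reducing bag folds to match")
        k = max(2, int(min_count))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    bagged: list[BaggedLearner] = []
    for spec in learners:
        fold_models = []
        oof = np.zeros((len(y), len(class_order)))
        for train_idx, hold_idx in folds:
            model = make_learner(spec)
            model.fit(X[train_idx], y[train_idx])
            fold_models.append(model)
            oof[hold_idx] = _aligned_proba(model, X[hold_idx], class_order)
        bagged.append(BaggedLearner(spec, fold_models, oof))
    return bagged, class_order


def fit_ensemble_weights(
    oof_probas: Sequence[np.ndarray], labels: Sequence[str], class_order: Sequence[str], rounds: int = 25
) -> np.ndarray:
    """Greedy forward selection (with replacement) maximizing out-of-fold accuracy.

    Weights are the selection frequencies of the best-scoring greedy prefix,
    which guarantees the ensemble's out-of-fold accuracy is at least the best
    single learner's.
    """
    if len(oof_probas) == 0:
        raise ValidationError("need at least one learner")
    y_idx = np.array([list(class_order).index(c) for c in labels])

    def acc(proba_sum: np.ndarray, count: int) -> float:
        pred = np.argmax(proba_sum, axis=1)
        return float(np.mean(pred == y_idx))

    n_learners = len(oof_probas)
    counts = np.zeros(n_learners, dtype=int)
    proba_sum = np.zeros_like(oof_probas[0])
    best_counts, best_acc = None, -1.0
    for _ in range(rounds):
        scores = [acc(proba_sum + oof_probas[m], counts.sum() + 1) for m in range(n_learners)]
        pick = int(np.argmax(scores))  # ties -> lowest index
        counts[pick] += 1
        proba_sum += oof_probas[pick]
        if scores[pick] > best_acc:
            best_acc = scores[pick]
            best_counts = counts.copy()
    weights = best_counts / best_counts.sum()
    return weights


@dataclass
class TrainedEnsemble:
    """Fold models, ensemble weights, and the frozen feature/class contracts."""

    learners: list[BaggedLearner]
    weights: np.ndarray
    class_order: list[str]
    feature_names: list[str]
    oof_accuracy: float

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs = np.zeros((X.shape[0], len(self.class_order)))
        for w, learner in zip(self.weights, self.learners):
            if w > 0:
                probs += w * learner.predict_proba(X, self.class_order)
        return probs


@dataclass
class PredictionResult:
    """Per-sample class probabilities, the argmax call, and the runner-up."""

    sample_ids: list[str]
    class_order: list[str]
    probabilities: np.ndarray
    predicted: list[str]
    runner_up: list[str]
    runner_up_probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities, index=self.sample_ids, columns=self.class_order)
        df.insert(0, "predicted", self.predicted)
        df["runner_up"] = self.runner_up
        df["runner_up_probability"] = self.runner_up_probability
        return df


def train_ensemble(
    features: pd.DataFrame,
    labels: Sequence[str],
    k: int = 5,
    learners: Sequence[BaseLearnerSpec] = DEFAULT_LEARNERS,
    seed: int = 0,
) -> TrainedEnsemble:
    """Bag each learner, then fit greedy ensemble weights on out-of-fold probas."""
    bagged, class_order = train_bagged(features.to_numpy(), labels, k, learners, seed)
    weights = fit_ensemble_weights([b.oof_proba for b in bagged], labels, class_order)
    oof = np.zeros_like(bagged[0].oof_proba)
    for w, b in zip(weights, bagged):
        oof += w * b.oof_proba
    y_idx = np.array([class_order.index(c) for c in labels])
    oof_acc = float(np.mean(np.argmax(oof, axis=1) == y_idx))
    return TrainedEnsemble(bagged, weights, class_order, list(features.columns), oof_acc)


def predict(ensemble: TrainedEnsemble, features: pd.DataFrame) -> PredictionResult:
    """Weighted-ensemble class probabilities and calls for new samples.

    Feature columns must match the training columns exactly; argmax ties break
    toward the earlier class in the fixed class order.
    """
    if list(features.columns) != ensemble.feature_names:
        missing = [c for c in ensemble.feature_names if c not in features.columns]
        extra = [c for c in features.columns if c not in ensemble.feature_names]
        raise ValidationError(
            f"feature columns do not match training columns; missing={missing[:5]}, "
            f"extra={extra[:5]}"
        )
    probs = ensemble.predict_proba(features.to_numpy())
    order = np.argsort(-probs, axis=1, kind="stable")  # stable: ties -> earlier class
    top = order[:, 0]
    second = order[:, 1] if probs.shape[1] > 1 else order[:, 0]
    return PredictionResult(
        sample_ids=list(features.index),
        class_order=ensemble.class_order,
        probabilities=probs,
        predicted=[ensemble.class_order[i] for i in top],
        runner_up=[ensemble.class_order[i] for i in second],
        runner_up_probability=probs[np.arange(len(top)), second],
    )
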