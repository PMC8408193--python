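"""Random-forest mapping from high-dimensional features to behavior groups.

Once clusters are discovered, a multi-class random forest learns the map
from the 36-dimensional feature space to the group labels. The forest is
what transfers to new sessions: prediction needs no re-embedding, is fast,
and generalizes across animals because it is trained on pose relationships
rather than embedding coordinates. Hyperparameters are scikit-learn
defaults (100 trees, Gini, unlimited depth, sqrt(P) features per split),
which suffice for this mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.stats import sem
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import KFold, train_test_split

from .errors import InsufficientDataError, ParameterError, SchemaError
from .features import FeatureMatrix

__all__ = ["BehaviorClassifier", "train", "crossvalidate", "predict"]

NOISE = -1


@dataclass
class BehaviorClassifier:
    """Trained forest plus the feature schema it expects."""

    forest_state: RandomForestClassifier
    classes: list[int]
    feature_names: list[str]
    training_report: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "BehaviorClassifier":
        return joblib.load(path)


def _non_noise(features: FeatureMatrix, labels: np.ndarray):
    labels = np.asarray(labels)
    if labels.shape[0] != features.n_bins:
        raise ParameterError("labels must have one entry per feature bin")
    keep = labels != NOISE
    return features.values[keep], labels[keep]


def train(
    features: FeatureMatrix,
    labels: np.ndarray,
    holdout: float = 0.2,
    seed: int = 0,
    stratify: bool = False,
    n_estimators: int = 100,
) -> BehaviorClassifier:
    """Fit the forest on (1 - holdout) of non-noise bins and report held-out
    accuracy, confusion matrix and per-class precision/recall."""
    x, y = _non_noise(features, labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InsufficientDataError(
            "training needs at least 2 behavior groups after removing noise"
        )
    if counts.min() < 10:
        raise InsufficientDataError(
            f"smallest group has {counts.min()} bins; need >= 10 per group"
        )
    x_tr, x_te, y_tr, y_te = train_test_split(
        x,
        y,
        test_size=holdout,
        random_state=seed,
        shuffle=True,
        stratify=y if stratify else None,
    )
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    forest.fit(x_tr, y_tr)
    y_hat = forest.predict(x_te)
    acc = float((y_hat == y_te).mean())
    cm = pd.DataFrame(
        confusion_matrix(y_te, y_hat, labels=classes), index=classes, columns=classes
    )
    prec, rec, f1, support = precision_recall_fscore_support(
        y_te, y_hat, labels=classes, zero_division=0
    )
    report = dict(
        holdout=holdout,
        holdout_accuracy=acc,
        confusion_matrix=cm,
        per_class=pd.DataFrame(
            dict(precision=prec, recall=rec, f1=f1, support=support), index=classes
        ),
        n_train=len(y_tr),
        n_test=len(y_te),
        seed=seed,
    )
    return BehaviorClassifier(
        forest, [int(c) for c in classes], list(features.feature_names), report
    )


def crossvalidate(
    features: FeatureMatrix,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    n_estimators: int = 100,
) -> dict:
    """k-fold cross-validated accuracy on shuffled non-noise bins."""
    x, y = _non_noise(features, labels)
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ParameterError(
            f"k={k} folds exceed the smallest group count ({counts.min()})"
        )
    accs = []
    for fold, (tr, te) in enumerate(
        KFold(n_splits=k, shuffle=True, random_state=seed).split(x)
    ):
        forest = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed + fold, n_jobs=1
        )
        forest.fit(x[tr], y[tr])
        accs.append(float((forest.predict(x[te]) == y[te]).mean()))
    accs = np.asarray(accs)
    return dict(
        fold_accuracies=accs,
        mean=float(accs.mean()),
        sem=float(sem(accs)) if k > 1 else 0.0,
    )


def predict(model: BehaviorClassifier, features: FeatureMatrix) -> np.ndarray:
    """One group label per bin; prediction never emits the noise label."""
    if list(features.feature_names) != list(model.feature_names):
        missing = set(model.feature_names) - set(features.feature_names)
        extra = set(features.feature_names) - set(model.feature_names)
        raise SchemaError(
            "feature schema mismatch: "
            f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            if missing or extra
            else "feature columns are ordered differently than at training"
        )
    if features.n_bins == 0:
        return np.empty(0, dtype=int)
    return model.forest_state.predict(features.values).astype(int)
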