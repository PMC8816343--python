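"""Binary proposal classifiers mapping feature vectors to cell probabilities.

Two classifier families are supported, mirroring their reference settings:

* random forest (``kind="rf"``): 128 trees, Gini criterion, fit on the union
  of the training and validation splits (no hyperparameters need tuning);
* multilayer perceptron (``kind="mlp"``): hidden layers 50/50/20/20 with
  rectified activations, trained with the log (cross-entropy) loss and Adam
  for up to 200 epochs; the epoch with the best validation accuracy is kept.

Predicted probabilities are class-1 posteriors in [0, 1]; downstream, the
positive set is every proposal with p >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier

from .features import FeatureLayout

__all__ = ["ClassifierModel", "fit_classifier", "predict_probabilities"]


@dataclass
class ClassifierModel:
    """A fitted proposal classifier plus the feature layout it expects."""

    kind: str
    estimator: object
    layout: FeatureLayout | None = None
    n_features: int = 0
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "ClassifierModel":
        return joblib.load(path)


def fit_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    kind: str = "rf",
    val_features: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    seed: int = 0,
    layout: FeatureLayout | None = None,
) -> ClassifierModel:
    """Fit a proposal classifier.

    The RF is fit on train+validation pooled; the MLP is fit on the training
    split with per-epoch checkpoint selection by validation accuracy (when a
    validation split is given).  Raises on single-class labels.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int).ravel()
    if features.ndim != 2 or features.shape[0] != labels.shape[0]:
        raise ValueError("features must be (n, d) with one label per row")
    if np.unique(labels).size < 2:
        raise ValueError("degenerate training data: a single class present")
    meta = {"seed": seed, "n_train": int(labels.size)}
    if kind == "rf":
        X, y = features, labels
        if val_features is not None and len(val_features):
            X = np.vstack([X, val_features])
            y = np.concatenate([y, np.asarray(val_labels, dtype=int).ravel()])
        est = RandomForestClassifier(
            n_estimators=128, criterion="gini", random_state=seed, n_jobs=1
        )
        est.fit(X, y)
    elif kind == "mlp":
        est = MLPClassifier(
            hidden_layer_sizes=(50, 50, 20, 20),
            activation="relu",
            solver="adam",
            max_iter=1,
            warm_start=True,
            random_state=seed,
        )
        import warnings

        best_acc, best_state = -1.0, None
        n_epochs = 200
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-epoch fit emits convergence noise
            for epoch in range(n_epochs):
                est.fit(features, labels)
                if val_features is not None and len(val_features):
                    acc = est.score(val_features, np.asarray(val_labels).ravel())
                    if acc > best_acc:
                        best_acc = acc
                        best_state = (
                            [w.copy() for w in est.coefs_],
                            [b.copy() for b in est.intercepts_],
                            epoch,
                        )
        if best_state is not None:
            est.coefs_, est.intercepts_, best_epoch = best_state
            meta["best_epoch"] = best_epoch
            meta["val_accuracy"] = best_acc
    else:
        raise ValueError("kind must be 'rf' or 'mlp'")
    return ClassifierModel(
        kind=kind,
        estimator=est,
        layout=layout,
        n_features=features.shape[1],
        metadata=meta,
    )


def predict_probabilities(model: ClassifierModel, features: np.ndarray) -> np.ndarray:
    """Per-proposal probability of being a cell, in [0, 1]."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] == 0:
        return np.empty(0)
    if features.shape[1] != model.n_features:
        raise ValueError(
            f"feature layout mismatch: expected {model.n_features} features, "
            f"got {features.shape[1]}"
        )
    proba = model.estimator.predict_proba(features)
    classes = list(model.estimator.classes_)
    return proba[:, classes.index(1)]
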