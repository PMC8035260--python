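"""One-hidden-layer softmax network over AP difference shapes.

Architecture: one fully connected hidden layer of 130 rectified-linear
units, a 10-unit softmax output, categorical cross-entropy loss, Adam
with learning rate 0.001.  Training, splitting and cross-validation are
seeded and reproducible.  The optimizer and backprop are delegated to
scikit-learn's MLPClassifier; this module owns the data handling,
architecture fixing and the evaluation contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier

from .ap_features import DifferenceSample
from .metrics import EvaluationReport, evaluate

__all__ = ["MLPConfig", "TrainedModel", "split_dataset", "train", "predict",
           "cross_validate", "as_arrays"]


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters of the difference-shape classifier."""

    hidden_units: int = 130
    learning_rate: float = 0.001
    epochs: int = 500
    batch_size: int = 32
    seed: int = 0
    split_fraction: float = 0.8          # train share
    early_stopping: bool = False
    validation_fraction: float = 0.1     # carve-out when early stopping is on
    patience: int = 25
    standardize: bool = False            # z-score inputs (off: raw mV)

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainedModel:
    """Fitted network plus training provenance."""

    estimator: MLPClassifier
    config: MLPConfig
    loss_history: list[float]
    n_features: int
    mean: np.ndarray | None = None   # standardization, if enabled
    std: np.ndarray | None = None

    @property
    def weights(self) -> list[np.ndarray]:
        return self.estimator.coefs_

    @property
    def biases(self) -> list[np.ndarray]:
        return self.estimator.intercepts_

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"input has {X.shape[1]} features, model expects "
                f"{self.n_features}")
        if self.mean is not None:
            X = (X - self.mean) / self.std
        return X

    def save(self, path) -> None:
        """Flat .npz weight dump (documented: coefs_i, intercepts_i)."""
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"coefs_{i}"] = w
            arrays[f"intercepts_{i}"] = b
        if self.mean is not None:
            arrays["mean"] = self.mean
            arrays["std"] = self.std
        np.savez(path, n_features=self.n_features, **arrays)


def as_arrays(samples: Sequence[DifferenceSample] | tuple[np.ndarray, np.ndarray]
              ) -> tuple[np.ndarray, np.ndarray]:
    """Accept either DifferenceSample lists or prepared (X, y) arrays."""
    if isinstance(samples, tuple):
        X, y = samples
        return np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    X = np.asarray([s.diff for s in samples], dtype=float)
    y = np.asarray([s.label for s in samples], dtype=int)
    return X, y


def split_dataset(samples, config: MLPConfig
                  ) -> tuple[tuple[np.ndarray, np.ndarray],
                             tuple[np.ndarray, np.ndarray]]:
    """Stratified random train/test split, seeded.

    With N = 1,980 and an 0.8 train fraction this yields the reference
    1,584 / 396 partition.  Raises if any class is missing from either
    side.
    """
    X, y = as_arrays(samples)
    classes = np.unique(y)
    if len(y) < 10 or classes.size < 2:
        raise ValueError("need samples spanning multiple classes")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=config.split_fraction, stratify=y,
        random_state=config.seed)
    for name, part in (("train", y_tr), ("test", y_te)):
        missing = set(classes) - set(part)
        if missing:
            raise ValueError(f"classes {sorted(missing)} absent from {name} split")
    return (X_tr, y_tr), (X_te, y_te)


def train(train_set, config: MLPConfig) -> TrainedModel:
    """Fit the network; deterministic given ``config.seed``."""
    X, y = as_arrays(train_set)
    if X.size == 0:
        raise ValueError("empty training set")
    mean = std = None
    if config.standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        X = (X - mean) / std
    est = MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, len(y)),
        max_iter=config.epochs,
        shuffle=True,
        random_state=config.seed,
        early_stopping=config.early_stopping and len(y) >= 50,
        validation_fraction=config.validation_fraction,
        n_iter_no_change=config.patience,
        alpha=0.0,
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    if not np.isfinite(est.loss_):
        raise RuntimeError(
            f"training diverged (non-finite loss at epoch {est.n_iter_})")
    if est.loss_curve_[-1] > est.loss_curve_[0] * 10:
        raise RuntimeError("training diverged: loss increased 10-fold")
    return TrainedModel(estimator=est, config=config,
                        loss_history=list(est.loss_curve_),
                        n_features=X.shape[1], mean=mean, std=std)


def predict(model: TrainedModel, samples) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample class-probability vectors and argmax labels."""
    if isinstance(samples, tuple):
        X = np.asarray(samples[0], dtype=float)
    elif isinstance(samples, np.ndarray):
        X = samples
    else:
        X = np.asarray([s.diff for s in samples], dtype=float)
    X = model._prepare(X)
    proba = model.estimator.predict_proba(X)
    labels = model.estimator.classes_[np.argmax(proba, axis=1)]
    return proba, labels


def cross_validate(samples, config: MLPConfig, k: int = 10
                   ) -> tuple[list[EvaluationReport], dict[str, float]]:
    """Stratified k-fold cross-validation; folds disjoint and exhaustive.

    Returns the per-fold evaluation reports plus the mean/SD of macro-F1
    and accuracy across folds.
    """
    X, y = as_arrays(samples)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(y) < k:
        raise ValueError("k exceeds the number of samples")
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError("k exceeds the smallest class count")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    reports = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(X, y)):
        model = train((X[tr_idx], y[tr_idx]), config)
        proba, pred = predict(model, (X[te_idx], None))
        reports.append(evaluate(y[te_idx], pred, proba,
                                require_all_classes=False))
    f1s = np.array([r.macro_f1 for r in reports])
    accs = np.array([r.accuracy for r in reports])
    summary = {"macro_f1_mean": float(f1s.mean()),
               "macro_f1_sd": float(f1s.std(ddof=1)),
               "accuracy_mean": float(accs.mean()),
               "accuracy_sd": float(accs.std(ddof=1))}
    return reports, summary
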