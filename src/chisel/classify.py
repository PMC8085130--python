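"""Immunopositive/immunonegative nucleus classification.

A one-hidden-layer network (20 sigmoid units, softmax output over the two
classes) on the per-object feature vector of :mod:`chisel.features`.
Training uses a stratified 70/15/15 train/validation/test split,
Nguyen–Widrow layer initialization and full-batch scaled conjugate gradient
on the cross-entropy for a fixed number of epochs; features are z-scored on
the training split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .features import extract_features, feature_names  # noqa: F401  (re-export)
from .mlp import TinyMLP

CLASS_NAMES = ("positive", "negative")


@dataclass
class NucleusRecord:
    """One detected nucleus with its predicted class."""

    label_id: int
    centroid_x: float
    centroid_y: float
    area: int
    perimeter: float
    predicted_class: str
    probability: float


@dataclass
class ClassifierModel:
    """Trained nucleus classifier: scaler, network and training metadata."""

    mlp: TinyMLP
    mean: np.ndarray
    std: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES
    seed: int = 0
    epochs: int = 1000
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    validation_accuracy: float | None = None
    test_accuracy: float | None = None

    @property
    def n_features(self) -> int:
        return self.mlp.W1.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mlp": self.mlp.to_dict(),
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "class_names": list(self.class_names),
            "seed": self.seed,
            "epochs": self.epochs,
            "split": list(self.split),
            "validation_accuracy": self.validation_accuracy,
            "test_accuracy": self.test_accuracy,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mlp=TinyMLP.from_dict(d["mlp"]),
            mean=np.asarray(d["mean"]),
            std=np.asarray(d["std"]),
            class_names=tuple(d["class_names"]),
            seed=d["seed"],
            epochs=d["epochs"],
            split=tuple(d["split"]),
            validation_accuracy=d["validation_accuracy"],
            test_accuracy=d["test_accuracy"],
        )


def _stratified_split(y: np.ndarray, fracs, rng: np.random.Generator):
    idx_train, idx_val, idx_test = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = idx.size
        n_tr = int(round(fracs[0] * n))
        n_va = int(round(fracs[1] * n))
        idx_train.append(idx[:n_tr])
        idx_val.append(idx[n_tr : n_tr + n_va])
        idx_test.append(idx[n_tr + n_va :])
    return (np.concatenate(idx_train), np.concatenate(idx_val), np.concatenate(idx_test))


def train_classifier(
    features: np.ndarray,
    labels: list[str] | np.ndarray,
    seed: int = 0,
    epochs: int = 1000,
    hidden: int = 20,
) -> ClassifierModel:
    """Train the nucleus classifier on per-object feature vectors."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValidationError("features must be a 2-D array (objects x features)")
    labels = np.asarray([str(l) for l in labels])
    if X.shape[0] != labels.size:
        raise ValidationError("features/labels length mismatch")
    if X.shape[0] < 20:
        raise ValidationError("need at least 20 examples")
    unknown = set(labels) - set(CLASS_NAMES)
    if unknown:
        raise ValidationError(f"unknown class labels {unknown}")
    if len(set(labels)) < 2:
        raise ValidationError("both classes must be present")
    y = np.array([CLASS_NAMES.index(l) for l in labels])
    rng = np.random.default_rng(seed)
    split = (0.70, 0.15, 0.15)
    tr, va, te = _stratified_split(y, split, rng)
    mean = X[tr].mean(axis=0)
    std = X[tr].std(axis=0)
    std[std < 1e-12] = 1.0
    Xs = (X - mean) / std
    mlp = TinyMLP.train(Xs[tr], y[tr], n_classes=2, hidden=hidden, seed=seed, epochs=epochs)
    def _acc(idx):
        if idx.size == 0:
            return None
        return float(np.mean(mlp.predict_proba(Xs[idx]).argmax(axis=1) == y[idx]))
    return ClassifierModel(
        mlp=mlp, mean=mean, std=std, seed=seed, epochs=epochs, split=split,
        validation_accuracy=_acc(va), test_accuracy=_acc(te),
    )


def predict(model: ClassifierModel, fv: np.ndarray) -> tuple[str, float]:
    """Classify one feature vector: (class name, winning softmax value)."""
    fv = np.asarray(fv, dtype=np.float64)
    if fv.ndim != 1 or fv.size != model.n_features:
        raise ValidationError(
            f"feature length {fv.size} != model input size {model.n_features}"
        )
    p = model.mlp.predict_proba(((fv - model.mean) / model.std)[None, :])[0]
    k = int(np.argmax(p))  # argmax takes the first class on exact ties
    return model.class_names[k], float(p[k])


def predict_batch(model: ClassifierModel, X: np.ndarray) -> list[tuple[str, float]]:
    return [predict(model, fv) for fv in np.asarray(X, dtype=np.float64)]
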