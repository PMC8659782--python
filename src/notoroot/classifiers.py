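"""The three classical grade classifiers: RBF-SVM, ELM, and a BP network.

All models operate on z-scored features (statistics from the training set
only): RBF kernels and gradient descent are scale-pathological on raw pixel
and geometry units. Grade labels stay categorical throughout classification;
the numeric 1..4 coding exists only inside the RMSECV regression of the
selection module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import DivergenceError, InputError

__all__ = [
    "TrainedModel",
    "EvalReport",
    "BpConfig",
    "stratified_split",
    "train_svm",
    "train_elm",
    "train_bp",
    "predict",
    "evaluate",
    "cv_accuracy",
    "split_features",
]


def split_features(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) from a feature table with a 'grade' label column."""
    if "grade" not in table.columns:
        raise InputError("feature table must carry a 'grade' column")
    names = [c for c in table.columns if c != "grade"]
    return table[names].to_numpy(float), table["grade"].to_numpy()


@dataclass
class TrainedModel:
    """A fitted classifier plus its training-set feature scaling."""

    family: str  # svm | elm | bp
    classes: np.ndarray
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.scale_mean)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scale_mean) / self.scale_sd


@dataclass(frozen=True)
class EvalReport:
    """Accuracy, per-class accuracy, and the confusion matrix of one evaluation."""

    accuracy_pct: float
    per_class_pct: dict
    confusion: np.ndarray  # rows: true class, cols: predicted
    classes: tuple
    n: int

    @property
    def average_class_accuracy_pct(self) -> float:
        return float(np.mean(list(self.per_class_pct.values())))

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy_pct,
            "per_class_pct": {k: float(v) for k, v in self.per_class_pct.items()},
            "average_class_accuracy_pct": self.average_class_accuracy_pct,
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
            "n": self.n,
        }


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def stratified_split(
    table: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class split at ``train_fraction`` (rounded per class), seeded."""
    if not 0 < train_fraction < 1:
        raise InputError("train_fraction must be in (0, 1)")
    if "grade" not in table.columns:
        raise InputError("feature table must carry a 'grade' column")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for _, group in table.groupby("grade", sort=True):
        if len(group) < 2:
            raise InputError("every class needs at least 2 samples")
        order = np.array(group.index)
        rng.shuffle(order)
        n_train = int(np.floor(train_fraction * len(order) + 0.5))
        n_train = min(max(n_train, 1), len(order) - 1)
        train_idx.extend(order[:n_train])
        test_idx.extend(order[n_train:])
    return (
        table.loc[sorted(train_idx)].reset_index(drop=True),
        table.loc[sorted(test_idx)].reset_index(drop=True),
    )


def train_svm(X: np.ndarray, y: np.ndarray, c: float = 1.0, g: float = 0.1) -> TrainedModel:
    """One-vs-one soft-margin SVM with kernel exp(-g * ||u - v||^2)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if c <= 0 or g <= 0:
        raise InputError("c and g must be positive")
    classes = np.unique(y)
    if len(classes) < 2:
        raise InputError("need at least 2 classes")
    mean, sd = _fit_scaler(X)
    clf = SVC(C=c, gamma=g, kernel="rbf")
    clf.fit((X - mean) / sd, y)
    return TrainedModel("svm", classes, mean, sd, {"clf": clf, "c": c, "g": g})


def train_elm(
    X: np.ndarray, y: np.ndarray, n_hidden: int = 100, seed: int = 0,
    ridge: float = 1e-6,
) -> TrainedModel:
    """Extreme learning machine: random sigmoid hidden layer, ridge output fit."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if n_hidden < 1:
        raise InputError("n_hidden must be >= 1")
    classes = np.unique(y)
    mean, sd = _fit_scaler(X)
    Xs = (X - mean) / sd
    rng = np.random.default_rng(seed)
    W = rng.normal(size=(X.shape[1], n_hidden))
    b = rng.normal(size=n_hidden)
    H = 1.0 / (1.0 + np.exp(-(Xs @ W + b)))
    T = (y[:, None] == classes[None, :]).astype(float)  # one-hot
    beta = np.linalg.solve(H.T @ H + ridge * np.eye(n_hidden), H.T @ T)
    return TrainedModel("elm", classes, mean, sd, {"W": W, "b": b, "beta": beta})


@dataclass(frozen=True)
class BpConfig:
    n_hidden: int = 20
    learning_rate: float = 0.01
    epochs: int = 1000


def train_bp(
    X: np.ndarray, y: np.ndarray, cfg: BpConfig | None = None, seed: int = 0
) -> TrainedModel:
    """Single-hidden-layer backpropagation network.

    Full-batch gradient descent on softmax cross-entropy with a tanh hidden
    layer; seeded initialization makes training reproducible.
    """
    cfg = cfg or BpConfig()
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    mean, sd = _fit_scaler(X)
    Xs = (X - mean) / sd
    n, d = Xs.shape
    k = len(classes)
    T = (y[:, None] == classes[None, :]).astype(float)
    rng = np.random.default_rng(seed)
    W1 = rng.normal(0, 1.0 / np.sqrt(d), size=(d, cfg.n_hidden))
    b1 = np.zeros(cfg.n_hidden)
    W2 = rng.normal(0, 1.0 / np.sqrt(cfg.n_hidden), size=(cfg.n_hidden, k))
    b2 = np.zeros(k)
    for _ in range(cfg.epochs):
        H = np.tanh(Xs @ W1 + b1)
        Z = H @ W2 + b2
        Z -= Z.max(axis=1, keepdims=True)
        P = np.exp(Z)
        P /= P.sum(axis=1, keepdims=True)
        loss = -np.mean(np.sum(T * np.log(P + 1e-12), axis=1))
        if not np.isfinite(loss):
            raise DivergenceError(
                "training loss became non-finite; lower the learning rate"
            )
        dZ = (P - T) / n
        dW2 = H.T @ dZ
        db2 = dZ.sum(axis=0)
        dH = dZ @ W2.T * (1 - H**2)
        dW1 = Xs.T @ dH
        db1 = dH.sum(axis=0)
        W1 -= cfg.learning_rate * dW1
        b1 -= cfg.learning_rate * db1
        W2 -= cfg.learning_rate * dW2
        b2 -= cfg.learning_rate * db2
    return TrainedModel(
        "bp", classes, mean, sd, {"W1": W1, "b1": b1, "W2": W2, "b2": b2}
    )


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    if X.shape[1] != model.n_features:
        raise InputError(
            f"feature count {X.shape[1]} does not match training ({model.n_features})"
        )
    Xs = model._scale(X)
    if model.family == "svm":
        return model.params["clf"].predict(Xs)
    if model.family == "elm":
        H = 1.0 / (1.0 + np.exp(-(Xs @ model.params["W"] + model.params["b"])))
        return model.classes[np.argmax(H @ model.params["beta"], axis=1)]
    if model.family == "bp":
        H = np.tanh(Xs @ model.params["W1"] + model.params["b1"])
        Z = H @ model.params["W2"] + model.params["b2"]
        return model.classes[np.argmax(Z, axis=1)]
    raise InputError(f"unknown model family {model.family!r}")


def evaluate(model: TrainedModel, X: np.ndarray, y: np.ndarray) -> EvalReport:
    """Accuracy, per-class accuracy, and confusion matrix on (X, y)."""
    y = np.asarray(y)
    unseen = set(np.unique(y)) - set(model.classes)
    if unseen:
        raise InputError(f"labels outside the training set: {sorted(unseen)}")
    yhat = predict(model, X)
    classes = tuple(model.classes)
    cm = _sk_confusion(y, yhat, labels=list(classes))
    total = cm.sum()
    accuracy = float(np.trace(cm) / total * 100.0)
    per_class = {}
    for i, cls in enumerate(classes):
        row = cm[i].sum()
        per_class[cls] = float(cm[i, i] / row * 100.0) if row else float("nan")
    assert np.isclose(accuracy, np.trace(cm) / total * 100.0)
    return EvalReport(
        accuracy_pct=accuracy,
        per_class_pct=per_class,
        confusion=cm,
        classes=classes,
        n=int(total),
    )


def cv_accuracy(
    X: np.ndarray, y: np.ndarray, c: float, g: float, k: int = 5, seed: int = 0
) -> float:
    """Mean held-out accuracy (%) of the RBF-SVM over stratified k folds."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if k < 2:
        raise InputError("k must be >= 2")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        model = train_svm(X[train], y[train], c, g)
        accs.append(np.mean(predict(model, X[test]) == y[test]))
    return float(np.mean(accs) * 100.0)
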