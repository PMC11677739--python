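"""MLP classification of descriptor vectors and the evaluation metric suite.

The classifier is a small fully connected feed-forward network — two hidden
layers of 10 rectifier units, softmax output, cross-entropy loss, trained by
backpropagation at learning rate 0.001 — evaluated with stratified 10-fold
cross-validation. Reported metrics: accuracy, macro recall, macro F1
(mean ± sd over folds), balanced accuracy, confusion matrices (raw and
row-normalized) and one-vs-rest macro ROC AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score, recall_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MLPConfig:
    """Network configuration (2 x 10 ReLU hidden layers, lr 0.001)."""

    hidden_layers: tuple[int, ...] = (10, 10)
    activation: str = "relu"
    learning_rate: float = 0.001
    epochs: int = 500
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if len(self.hidden_layers) < 1:
            raise ValueError("need at least one hidden layer")


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validation metrics."""

    fold_accuracy: np.ndarray
    fold_recall: np.ndarray
    fold_f1: np.ndarray
    accuracy: float
    accuracy_sd: float
    recall: float
    recall_sd: float
    f1: float
    f1_sd: float
    balanced_accuracy: float
    confusion: np.ndarray
    confusion_normalized: np.ndarray
    auc: float
    classes: np.ndarray

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "accuracy_sd": self.accuracy_sd,
            "recall": self.recall,
            "recall_sd": self.recall_sd,
            "f1": self.f1,
            "f1_sd": self.f1_sd,
            "balanced_accuracy": self.balanced_accuracy,
            "auc": self.auc,
            "classes": self.classes.tolist(),
            "confusion": self.confusion.tolist(),
        }


def make_mlp(config: MLPConfig = MLPConfig()) -> Pipeline:
    """Standardization + MLP pipeline (features z-scored with training statistics)."""
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=config.hidden_layers,
                    activation=config.activation,
                    solver=config.optimizer,
                    learning_rate_init=config.learning_rate,
                    max_iter=config.epochs,
                    random_state=int(config.seed) % (2**31),
                ),
            ),
        ]
    )


def train_mlp(features: np.ndarray, labels: np.ndarray, config: MLPConfig = MLPConfig()) -> Pipeline:
    """Fit the MLP; deterministic given the config seed."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training requires at least 2 classes")
    model = make_mlp(config)
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(np.asarray(features, float), labels)
    return model


def confusion(y_true, y_pred, classes=None) -> np.ndarray:
    """Raw confusion matrix with rows = true classes."""
    return _sk_confusion(y_true, y_pred, labels=classes)


def accuracy_from_confusion(conf: np.ndarray) -> float:
    """trace / total — exact accuracy identity."""
    conf = np.asarray(conf, float)
    return float(np.trace(conf) / conf.sum())


def balanced_accuracy(conf: np.ndarray) -> float:
    """Mean per-class recall (binary: (sensitivity + specificity) / 2).

    1 indicates perfect classification, 0.5 chance level for binary problems.
    Classes absent from the truth are skipped.
    """
    conf = np.asarray(conf, float)
    if conf.size == 0 or conf.sum() == 0:
        raise ValueError("empty confusion matrix")
    row_tot = conf.sum(axis=1)
    present = row_tot > 0
    recalls = np.diag(conf)[present] / row_tot[present]
    return float(recalls.mean())


def roc_auc(scores: np.ndarray, labels: np.ndarray, classes=None) -> float:
    """Trapezoidal AUC; one-vs-rest macro average for multi-class scores."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined for a single class")
    scores = np.asarray(scores, float)
    if scores.ndim == 1 or scores.shape[1] == 2:
        s = scores if scores.ndim == 1 else scores[:, 1]
        return float(roc_auc_score(labels, s))
    return float(roc_auc_score(labels, scores, multi_class="ovr", average="macro", labels=classes))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    config: MLPConfig = MLPConfig(),
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation with per-fold standardization.

    If the smallest class has fewer than ``k`` members, the number of folds
    is reduced to that count (graceful degradation) with a logged warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    k_eff = int(min(k, counts.min()))
    if k_eff < k:
        logger.warning("reducing folds from %d to %d (smallest class has %d members)", k, k_eff, counts.min())
    if k_eff < 2:
        raise ValueError("smallest class too small for cross-validation")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=int(seed) % (2**31))
    accs, recs, f1s = [], [], []
    conf_total = np.zeros((classes.size, classes.size), float)
    probs = np.zeros((y.size, classes.size))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = train_mlp(X[tr], y[tr], config)
        pred = model.predict(X[te])
        probs[te] = model.predict_proba(X[te])
        conf = confusion(y[te], pred, classes=classes)
        conf_total += conf
        accs.append(accuracy_from_confusion(conf))
        recs.append(recall_score(y[te], pred, average="macro", zero_division=0))
        f1s.append(f1_score(y[te], pred, average="macro", zero_division=0))
    accs, recs, f1s = np.array(accs), np.array(recs), np.array(f1s)
    row = conf_total.sum(axis=1, keepdims=True)
    conf_norm = np.divide(conf_total, row, out=np.zeros_like(conf_total), where=row > 0)
    try:
        auc = roc_auc(probs, y, classes=classes)
    except ValueError:
        auc = float("nan")
    return CVReport(
        fold_accuracy=accs,
        fold_recall=recs,
        fold_f1=f1s,
        accuracy=float(accs.mean()),
        accuracy_sd=float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
        recall=float(recs.mean()),
        recall_sd=float(recs.std(ddof=1)) if recs.size > 1 else 0.0,
        f1=float(f1s.mean()),
        f1_sd=float(f1s.std(ddof=1)) if f1s.size > 1 else 0.0,
        balanced_accuracy=balanced_accuracy(conf_total),
        confusion=conf_total,
        confusion_normalized=conf_norm,
        auc=auc,
        classes=classes,
    )
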