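"""MLP classifier and evaluation metrics.

The network is a fixed-width multilayer perceptron: two fully connected
ReLU layers (256 units each by default) with dropout 0.2 after each,
and a 2-unit softmax output.  Elastic-net (L1+L2) penalties apply to
kernels, biases and layer activations.  Training uses Adam on
categorical cross-entropy, minibatches of 32, at most 100 epochs, with
the learning rate cut to a quarter after three epochs without
validation-loss improvement; three further flat epochs after a cut stop
training and the best weights are restored.

Implemented directly on numpy so that runs are bit-deterministic for a
given seed (single-threaded; initialization, shuffling and dropout all
draw from one seeded generator).  The pipeline accepts any classifier
exposing ``fit`` / ``predict_proba``, so this model is a default, not a
requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import train_test_split

from .table import FeatureTable


@dataclass
class MLPSpec:
    """Architecture + regularization + schedule hyperparameters."""

    n_features: int
    hidden: tuple[int, int] = (256, 256)
    dropout: float = 0.2
    n_classes: int = 2
    l1: float = 1e-5
    l2: float = 1e-5
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    lr_factor: float = 0.25
    patience: int = 3

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")

    @property
    def layer_widths(self) -> list[int]:
        return [self.n_features, *self.hidden, self.n_classes]


def build_mlp(n_features: int, **overrides) -> MLPSpec:
    """Default spec; pass e.g. ``hidden=(n_features, n_features)`` for
    the width-equals-feature-count variant."""
    return MLPSpec(n_features=n_features, **overrides)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_balanced_accuracy: list[float] = field(default_factory=list)
    val_balanced_accuracy: list[float] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)
    stopped_epoch: int = -1
    best_epoch: int = -1


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLPClassifier:
    """Numpy MLP with the schedule described in the module docstring."""

    def __init__(self, spec: MLPSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        self.classes_: np.ndarray | None = None
        self._params: list[np.ndarray] = []

    # -------------------------------------------------------------- internals
    def _init_params(self, rng: np.random.Generator) -> list[np.ndarray]:
        widths = self.spec.layer_widths
        params = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            params += [w, np.zeros(fan_out)]
        return params

    def _forward(self, x, params, rng=None):
        """Returns (probabilities, cache).  Dropout active iff rng given."""
        p = self.spec.dropout
        w1, b1, w2, b2, w3, b3 = params
        z1 = x @ w1 + b1
        h1 = np.maximum(z1, 0.0)
        m1 = None
        if rng is not None and p > 0:
            m1 = (rng.random(h1.shape) >= p) / (1 - p)
            h1 = h1 * m1
        z2 = h1 @ w2 + b2
        h2 = np.maximum(z2, 0.0)
        m2 = None
        if rng is not None and p > 0:
            m2 = (rng.random(h2.shape) >= p) / (1 - p)
            h2 = h2 * m2
        probs = _softmax(h2 @ w3 + b3)
        return probs, (x, z1, h1, m1, z2, h2, m2)

    def _loss(self, probs, y_onehot, params, acts) -> float:
        n = len(probs)
        ce = -np.log(np.clip((probs * y_onehot).sum(axis=1), 1e-12, None)).mean()
        l1, l2 = self.spec.l1, self.spec.l2
        reg = sum(l1 * np.abs(p).sum() + l2 * (p**2).sum() for p in params)
        reg += sum((l1 * np.abs(a).sum() + l2 * (a**2).sum()) / n for a in acts)
        return float(ce + reg)

    def _backward(self, probs, y_onehot, params, cache):
        x, z1, h1, m1, z2, h2, m2 = cache
        w1, b1, w2, b2, w3, b3 = params
        n = len(probs)
        l1, l2 = self.spec.l1, self.spec.l2

        def act_grad(a):
            return (l1 * np.sign(a) + 2 * l2 * a) / n

        d3 = (probs - y_onehot) / n                      # dL/dz3
        gw3 = h2.T @ d3
        gb3 = d3.sum(axis=0)
        dh2 = d3 @ w3.T + act_grad(h2)
        if m2 is not None:
            dh2 = dh2 * m2
        dz2 = dh2 * (z2 > 0)
        gw2 = h1.T @ dz2
        gb2 = dz2.sum(axis=0)
        dh1 = dz2 @ w2.T + act_grad(h1)
        if m1 is not None:
            dh1 = dh1 * m1
        dz1 = dh1 * (z1 > 0)
        gw1 = x.T @ dz1
        gb1 = dz1.sum(axis=0)
        grads = [gw1, gb1, gw2, gb2, gw3, gb3]
        return [g + l1 * np.sign(p) + 2 * l2 * p for g, p in zip(grads, params)]

    # ------------------------------------------------------------------- fit
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        validation_fraction: float = 0.1,
        verbose: bool = False,
    ) -> TrainingHistory:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training set has a single class")
        if len(self.classes_) != self.spec.n_classes:
            raise ValueError(
                f"spec expects {self.spec.n_classes} classes, data has "
                f"{len(self.classes_)}"
            )
        y_idx = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(self.seed)

        xtr, xval, ytr, yval = train_test_split(
            x, y_idx, test_size=validation_fraction, random_state=self.seed,
            stratify=y_idx,
        )
        onehot_tr = np.eye(self.spec.n_classes)[ytr]
        onehot_val = np.eye(self.spec.n_classes)[yval]

        params = self._init_params(rng)
        mom = [np.zeros_like(p) for p in params]
        vel = [np.zeros_like(p) for p in params]
        lr = self.spec.learning_rate
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        hist = TrainingHistory()
        best_loss = np.inf
        best_params = [p.copy() for p in params]
        wait = 0
        just_reduced = False

        n = len(xtr)
        for epoch in range(self.spec.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.spec.batch_size):
                sel = order[start : start + self.spec.batch_size]
                probs, cache = self._forward(xtr[sel], params, rng)
                grads = self._backward(probs, onehot_tr[sel], params, cache)
                t += 1
                for k in range(len(params)):
                    mom[k] = beta1 * mom[k] + (1 - beta1) * grads[k]
                    vel[k] = beta2 * vel[k] + (1 - beta2) * grads[k] ** 2
                    mhat = mom[k] / (1 - beta1**t)
                    vhat = vel[k] / (1 - beta2**t)
                    params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

            ptr, cache_tr = self._forward(xtr, params)
            pval, cache_val = self._forward(xval, params)
            tr_loss = self._loss(ptr, onehot_tr, params, (cache_tr[2], cache_tr[5]))
            v_loss = self._loss(pval, onehot_val, params, (cache_val[2], cache_val[5]))
            hist.train_loss.append(tr_loss)
            hist.val_loss.append(v_loss)
            hist.train_balanced_accuracy.append(
                balanced_accuracy_score(ytr, ptr.argmax(axis=1))
            )
            hist.val_balanced_accuracy.append(
                balanced_accuracy_score(yval, pval.argmax(axis=1))
            )
            hist.lr_trace.append(lr)
            if verbose:  # pragma: no cover
                print(f"epoch {epoch}: loss {tr_loss:.4f} val {v_loss:.4f} lr {lr:g}")

            if v_loss < best_loss:
                best_loss = v_loss
                best_params = [p.copy() for p in params]
                hist.best_epoch = epoch
                wait = 0
                just_reduced = False
            else:
                wait += 1
                if wait >= self.spec.patience:
                    if just_reduced:
                        hist.stopped_epoch = epoch
                        break
                    lr *= self.spec.lr_factor
                    wait = 0
                    just_reduced = True

        self._params = best_params
        if hist.stopped_epoch < 0:
            hist.stopped_epoch = len(hist.train_loss) - 1
        return hist

    # ----------------------------------------------------------------- infer
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if not self._params:
            raise ValueError("model is not fitted")
        probs, _ = self._forward(np.asarray(x, dtype=float), self._params)
        return probs

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(x).argmax(axis=1)]


def train_mlp(
    spec: MLPSpec,
    table: FeatureTable | np.ndarray,
    labels: np.ndarray | None = None,
    validation_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[MLPClassifier, TrainingHistory]:
    """Train an MLP with the given architecture on a table (or raw
    matrix) and labels."""
    if isinstance(table, FeatureTable):
        x = table.matrix
        y = np.asarray(labels) if labels is not None else table.labels()
    else:
        x, y = np.asarray(table, dtype=float), np.asarray(labels)
    clf = MLPClassifier(spec, seed=seed)
    hist = clf.fit(x, y, validation_fraction=validation_fraction)
    return clf, hist


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    classes: list
    precision: dict
    recall: dict
    fscore: dict
    balanced_accuracy: float
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "precision": {str(k): v for k, v in self.precision.items()},
            "recall": {str(k): v for k, v in self.recall.items()},
            "fscore": {str(k): v for k, v in self.fscore.items()},
            "balanced_accuracy": self.balanced_accuracy,
            "confusion": self.confusion.tolist(),
        }


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ClassificationReport:
    """Per-class precision/recall/F (harmonic mean), balanced accuracy
    (mean per-class recall) and the confusion matrix."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    classes = np.unique(np.concatenate([y_true, y_pred]))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    return ClassificationReport(
        classes=list(classes),
        precision=dict(zip(classes, prec)),
        recall=dict(zip(classes, rec)),
        fscore=dict(zip(classes, f1)),
        balanced_accuracy=float(balanced_accuracy_score(y_true, y_pred)),
        confusion=confusion_matrix(y_true, y_pred, labels=classes),
    )


def evaluate(
    model, table: FeatureTable | np.ndarray, labels: np.ndarray | None = None
) -> ClassificationReport:
    """Evaluate a fitted classifier (argmax of predict_proba)."""
    if isinstance(table, FeatureTable):
        x = table.matrix
        y = np.asarray(labels) if labels is not None else table.labels()
    else:
        x, y = np.asarray(table, dtype=float), np.asarray(labels)
    data_classes = set(map(str, np.unique(y)))
    model_classes = set(map(str, getattr(model, "classes_", [])))
    if model_classes and not data_classes <= model_classes:
        raise ValueError(
            f"label set {sorted(data_classes)} not covered by model classes "
            f"{sorted(model_classes)}"
        )
    return report_from_predictions(y, model.predict(x))
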