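"""Deep multilayer perceptron (DMLP) family for affect classification.

The model family: fully connected networks with N input features, two or
three hidden layers of 8-256 units, ReLU activations each followed by
dropout at rate 0.25, and a sigmoid (binary) or softmax (multiclass) head,
trained with Adam on (binary) cross-entropy.  :class:`DMLPClassifier` is a
compact NumPy implementation wrapped as a scikit-learn estimator, so it
composes with pipelines, stratified cross-validation and model selection.

Evaluation protocol: an 80/20 stratified split drives architecture search
(smallest test error, ties broken by fewest hidden neurons); the reported
metrics (mean AUC, f1, accuracy) come from 10-fold stratified
cross-validation with per-feature standardization and median imputation
fit on training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.impute import SimpleImputer
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted, check_random_state

from .reference import NETWORK_PRESETS

HIDDEN_WIDTH_BOUNDS = (8, 256)
HIDDEN_DEPTH_CHOICES = (2, 3)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of one DMLP: input width, hidden widths, output head."""

    input_size: int
    hidden_sizes: tuple[int, ...]
    n_classes: int = 2
    dropout_rate: float = 0.25

    def __post_init__(self):
        if self.input_size < 1:
            raise ValueError("input_size must be >= 1")
        if len(self.hidden_sizes) not in HIDDEN_DEPTH_CHOICES:
            raise ValueError(f"number of hidden layers must be in {HIDDEN_DEPTH_CHOICES}")
        lo, hi = HIDDEN_WIDTH_BOUNDS
        if any(not (lo <= w <= hi) for w in self.hidden_sizes):
            raise ValueError(f"hidden widths must lie in [{lo}, {hi}]")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @property
    def output_units(self) -> int:
        return 1 if self.n_classes == 2 else self.n_classes

    def layer_sizes(self) -> tuple[int, ...]:
        return (self.input_size, *self.hidden_sizes, self.output_units)

    @property
    def n_parameters(self) -> int:
        sizes = self.layer_sizes()
        return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))

    @property
    def n_hidden_neurons(self) -> int:
        return sum(self.hidden_sizes)


def build_network(spec: NetworkSpec, random_state=None) -> "DMLPClassifier":
    """Instantiate a trainable classifier for an architecture spec."""
    return DMLPClassifier(hidden_sizes=spec.hidden_sizes, dropout=spec.dropout_rate,
                          random_state=random_state)


class DMLPClassifier(ClassifierMixin, BaseEstimator):
    """Fully connected NumPy network with ReLU + dropout hidden layers.

    Binary problems use a single sigmoid output with binary cross-entropy;
    multiclass problems use a softmax head with categorical cross-entropy
    (the categorical generalization of the stated binary loss).  Training
    uses minibatch Adam with optional early stopping on the training loss.
    Fully deterministic for a fixed ``random_state``.
    """

    def __init__(self, hidden_sizes=(64, 16), dropout=0.25, lr=1e-3,
                 epochs=200, batch_size=32, patience=20, tol=1e-4,
                 early_stopping=False, random_state=None):
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.tol = tol
        self.early_stopping = early_stopping
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _forward(self, X, rng=None):
        """Forward pass; returns activations per layer.  ``rng`` enables
        inverted dropout (training mode)."""
        acts = [X]
        h = X
        n_hidden = len(self.coefs_) - 1
        for i, (W, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            z = h @ W + b
            if i < n_hidden:
                h = np.maximum(z, 0.0)
                if rng is not None and self.dropout > 0:
                    keep = 1.0 - self.dropout
                    mask = (rng.random_sample(h.shape) < keep) / keep
                    h = h * mask
            else:
                h = z
            acts.append(h)
        return acts

    @staticmethod
    def _sigmoid(z):
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out

    @staticmethod
    def _softmax(z):
        z = z - z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def _loss_grad_output(self, z_out, y_target):
        """Cross-entropy loss and dLoss/dz at the output layer."""
        n = len(z_out)
        if self.n_outputs_ == 1:
            p = self._sigmoid(z_out[:, 0])
            eps = 1e-12
            loss = -np.mean(y_target * np.log(p + eps) + (1 - y_target) * np.log(1 - p + eps))
            grad = ((p - y_target) / n)[:, None]
        else:
            p = self._softmax(z_out)
            eps = 1e-12
            loss = -np.mean(np.log(p[np.arange(n), y_target] + eps))
            grad = p.copy()
            grad[np.arange(n), y_target] -= 1.0
            grad /= n
        return loss, grad

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values; impute before fitting")
        rng = check_random_state(self.random_state)

        self.classes_ = unique_labels(y)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        spec = NetworkSpec(input_size=X.shape[1], hidden_sizes=tuple(self.hidden_sizes),
                           n_classes=n_classes, dropout_rate=self.dropout)
        self.spec_ = spec
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = spec.output_units
        y_idx = np.searchsorted(self.classes_, y)
        y_target = y_idx.astype(float) if self.n_outputs_ == 1 else y_idx

        sizes = spec.layer_sizes()
        self.coefs_ = [rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b))
                       for a, b in zip(sizes[:-1], sizes[1:])]
        self.intercepts_ = [np.zeros(b) for b in sizes[1:]]

        mW = [np.zeros_like(W) for W in self.coefs_]
        vW = [np.zeros_like(W) for W in self.coefs_]
        mb = [np.zeros_like(b) for b in self.intercepts_]
        vb = [np.zeros_like(b) for b in self.intercepts_]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0

        n = len(X)
        batch = min(self.batch_size, n)
        best_loss, since_best = np.inf, 0
        self.loss_curve_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                acts = self._forward(X[idx], rng=rng)
                loss, grad = self._loss_grad_output(acts[-1], y_target[idx])
                epoch_loss += loss * len(idx)
                # backprop
                grads_W, grads_b = [], []
                delta = grad
                for li in range(len(self.coefs_) - 1, -1, -1):
                    grads_W.append(acts[li].T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if li > 0:
                        delta = (delta @ self.coefs_[li].T) * (acts[li] > 0)
                grads_W.reverse()
                grads_b.reverse()
                step += 1
                for li in range(len(self.coefs_)):
                    for g, m, v, p in ((grads_W[li], mW[li], vW[li], self.coefs_[li]),
                                       (grads_b[li], mb[li], vb[li], self.intercepts_[li])):
                        m *= b1
                        m += (1 - b1) * g
                        v *= b2
                        v += (1 - b2) * g * g
                        mhat = m / (1 - b1 ** step)
                        vhat = v / (1 - b2 ** step)
                        p -= self.lr * mhat / (np.sqrt(vhat) + eps)
            epoch_loss /= n
            self.loss_curve_.append(epoch_loss)
            if self.early_stopping:
                if epoch_loss < best_loss - self.tol:
                    best_loss, since_best = epoch_loss, 0
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        self.n_iter_ = len(self.loss_curve_)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, dtype=float)
        z = self._forward(X, rng=None)[-1]
        if self.n_outputs_ == 1:
            p1 = self._sigmoid(z[:, 0])
            return np.column_stack([1 - p1, p1])
        return self._softmax(z)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# Tasks
# ---------------------------------------------------------------------------

_LEVEL_COLUMN = {
    frozenset({"LA", "MA", "HA"}): "arousal",
    frozenset({"NV", "MV", "PV"}): "valence",
    frozenset({"HANV", "LANV", "LAPV", "MAMV"}): "quadrant",
}


@dataclass(frozen=True)
class TaskSpec:
    """A classification task over affect labels.

    ``name`` uses '/' between classes and '+' for merged levels, e.g.
    "LA+MA/HA" (binary: low-or-medium arousal vs high) or "HA/MA/LA"
    (3-class).  Levels absent from the name are excluded from the task.
    """

    name: str
    groups: tuple[tuple[str, ...], ...] = ()
    hidden_sizes: tuple[int, ...] = ()

    def __post_init__(self):
        groups = self.groups or tuple(
            tuple(part.split("+")) for part in self.name.split("/"))
        object.__setattr__(self, "groups", groups)
        levels = [lv for g in groups for lv in g]
        if len(levels) != len(set(levels)):
            raise ValueError(f"task {self.name}: classes must partition the levels")
        if not self.hidden_sizes and self.name in NETWORK_PRESETS:
            object.__setattr__(self, "hidden_sizes", NETWORK_PRESETS[self.name])

    @property
    def levels(self) -> frozenset[str]:
        return frozenset(lv for g in self.groups for lv in g)

    @property
    def label_column(self) -> str:
        for levels, col in _LEVEL_COLUMN.items():
            if self.levels <= levels:
                return col
        raise ValueError(f"task {self.name}: levels {sorted(self.levels)} match no label space")

    @property
    def n_classes(self) -> int:
        return len(self.groups)

    def class_of(self, level: str) -> str | None:
        """Task class name ('LA+MA', 'HA', ...) for a level; None if excluded."""
        for group in self.groups:
            if level in group:
                return "+".join(group)
        return None

    def encode(self, levels) -> pd.Series:
        """Map a level series to task classes; excluded levels become NaN."""
        return pd.Series([self.class_of(lv) for lv in levels], index=getattr(levels, "index", None))


def preset_tasks() -> dict[str, TaskSpec]:
    """All published task presets with their architecture choices."""
    return {name: TaskSpec(name=name) for name in NETWORK_PRESETS}


# ---------------------------------------------------------------------------
# Training / evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Cross-validated performance of one task."""

    task: str
    hidden_sizes: tuple[int, ...]
    seed: int
    auc: list[float] = field(default_factory=list)
    f1: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    fold_assignments: np.ndarray | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))

    def to_dict(self) -> dict:
        return {"task": self.task, "hidden_sizes": list(self.hidden_sizes),
                "seed": self.seed, "auc": self.mean_auc, "f1": self.mean_f1,
                "accuracy": self.mean_accuracy,
                "per_fold": {"auc": self.auc, "f1": self.f1, "accuracy": self.accuracy}}


def _make_pipeline(hidden_sizes, seed, dropout=0.25, epochs=200, lr=1e-3,
                   batch_size=32, patience=20, early_stopping=False) -> Pipeline:
    """Median imputation + per-feature z-scoring + DMLP, all fold-local."""
    return Pipeline([
        ("impute", SimpleImputer(strategy="median", add_indicator=False)),
        ("scale", StandardScaler()),
        ("net", DMLPClassifier(hidden_sizes=hidden_sizes, dropout=dropout,
                               epochs=epochs, lr=lr, batch_size=batch_size,
                               patience=patience, early_stopping=early_stopping,
                               random_state=seed)),
    ])


def _task_arrays(features: pd.DataFrame, labels, task: TaskSpec):
    y = task.encode(pd.Series(list(labels), index=features.index))
    keep = y.notna().to_numpy()
    return features.to_numpy(float)[keep], y.to_numpy(object)[keep]


def train_eval(features: pd.DataFrame, labels, task: TaskSpec, seed: int = 0,
               hidden_sizes=None, n_folds: int = 10, epochs: int = 200,
               lr: float = 1e-3, dropout: float = 0.25) -> EvalReport:
    """10-fold stratified cross-validation of a task.

    ``features`` must already be restricted to the task's predictor set;
    ``labels`` are levels in the task's label space (e.g. 'HA').  Rows
    whose level the task excludes are dropped.  Imputation and scaling are
    fit inside each training fold.  AUC is macro one-vs-rest for
    multiclass; f1 is macro-averaged.
    """
    hidden = tuple(hidden_sizes or task.hidden_sizes)
    if not hidden:
        raise ValueError(f"no architecture given or preset for task {task.name}")
    X, y = _task_arrays(features, labels, task)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    report = EvalReport(task=task.name, hidden_sizes=hidden, seed=seed,
                        fold_assignments=np.full(len(y), -1))
    classes = np.unique(y)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        pipe = _make_pipeline(hidden, seed + fold, dropout=dropout, epochs=epochs, lr=lr)
        pipe.fit(X[tr], y[tr])
        proba = pipe.predict_proba(X[te])
        pred = classes[np.argmax(proba, axis=1)]
        report.accuracy.append(float(accuracy_score(y[te], pred)))
        report.f1.append(float(f1_score(y[te], pred, average="macro", zero_division=0)))
        if len(classes) == 2:
            auc = roc_auc_score((y[te] == classes[1]).astype(int), proba[:, 1])
        else:
            auc = roc_auc_score(y[te], proba, multi_class="ovr", average="macro",
                                labels=classes)
        report.auc.append(float(auc))
        report.fold_assignments[te] = fold
    return report


def architecture_search(features: pd.DataFrame, labels, task: TaskSpec,
                        grid, seed: int = 0, epochs: int = 200,
                        test_size: float = 0.2) -> NetworkSpec:
    """Pick the architecture with the smallest held-out error.

    Candidates in ``grid`` (hidden-size tuples) are trained on a stratified
    80% split and scored on the remaining 20%; the spec minimizing test
    error wins, ties broken by the fewest hidden neurons.
    """
    grid = [tuple(h) for h in grid]
    if not grid:
        raise ValueError("architecture grid must be nonempty")
    X, y = _task_arrays(features, labels, task)
    Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=test_size,
                                          stratify=y, random_state=seed)
    n_classes = len(np.unique(y))
    best = None
    for hidden in grid:
        spec = NetworkSpec(input_size=X.shape[1], hidden_sizes=hidden,
                           n_classes=n_classes)
        pipe = _make_pipeline(hidden, seed, epochs=epochs)
        pipe.fit(Xtr, ytr)
        err = 1.0 - accuracy_score(yte, pipe.predict(Xte))
        key = (err, spec.n_hidden_neurons)
        if best is None or key < best[0]:
            best = (key, spec)
    return best[1]
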