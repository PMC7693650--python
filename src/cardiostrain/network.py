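"""Feed-forward neural-network classifier and the cross-validation protocol.

The architecture is two fully-connected hidden layers of 30 and 5 neurons
with hyperbolic-tangent sigmoid activations, a single read-out perceptron
with a log-sigmoid output in (0, 1), binary cross-entropy loss, and exactly
100 training epochs. A subject is called positive (HCM) when the output
strictly exceeds 0.5. Training is full-batch Adam with features z-scored on
the training split only; everything is seeded and deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .evaluate import auc as rank_auc
from .evaluate import confusion_metrics, roc_points

__all__ = [
    "NetworkConfig",
    "MLPBinaryClassifier",
    "init_network",
    "forward",
    "cross_entropy",
    "train",
    "classify",
    "stratified_kfold",
    "cross_validate",
    "CVResult",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the diagnosis network."""

    hidden: tuple[int, int] = (30, 5)
    epochs: int = 100
    learning_rate: float = 0.01
    seed: int = 0
    threshold: float = 0.5
    n_folds: int = 5

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def init_network(d_in: int, hidden: tuple[int, ...], rng: np.random.Generator) -> list:
    """Uniform(-1/sqrt(fan_in), +1/sqrt(fan_in)) weights, zero biases."""
    sizes = [d_in, *hidden, 1]
    params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        w = rng.uniform(-bound, bound, size=(fan_out, fan_in))
        params.append((w, np.zeros(fan_out)))
    return params


def forward(params: list, x: np.ndarray) -> np.ndarray:
    """Network output probability/ies in (0, 1): tanh hidden layers, then a
    log-sigmoid read-out."""
    a = np.atleast_2d(np.asarray(x, dtype=float))
    for w, b in params[:-1]:
        a = np.tanh(a @ w.T + b)
    w, b = params[-1]
    z = (a @ w.T + b)[:, 0]
    p = 1.0 / (1.0 + np.exp(-z))
    # keep strictly inside (0, 1) for the cross-entropy
    return np.clip(p, 1e-12, 1.0 - 1e-12)


def cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, -[y ln p + (1-y) ln(1-p)]."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class MLPBinaryClassifier:
    """sklearn-style estimator for the HCM-vs-mimic diagnosis network.

    Parameters mirror :class:`NetworkConfig`; fitted attributes follow the
    sklearn trailing-underscore convention (``weights_``, ``loss_curve_``,
    ``mean_``, ``scale_``).
    """

    def __init__(
        self,
        hidden: tuple[int, int] = (30, 5),
        epochs: int = 100,
        learning_rate: float = 0.01,
        seed: int = 0,
        threshold: float = 0.5,
        standardize: bool = True,
    ):
        self.hidden = hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed
        self.threshold = threshold
        self.standardize = standardize

    # -- sklearn protocol -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "hidden": self.hidden,
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
            "threshold": self.threshold,
            "standardize": self.standardize,
        }

    def set_params(self, **params) -> "MLPBinaryClassifier":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPBinaryClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2D with one row per label")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training set contains a single class")
        if not set(classes) <= {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        self.classes_ = np.array([0, 1])

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            self.scale_ = np.where(scale > 0, scale, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_

        rng = np.random.default_rng(self.seed)
        params = init_network(X.shape[1], tuple(self.hidden), rng)
        m = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params]
        v = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        losses = np.empty(self.epochs)
        n = X.shape[0]
        for epoch in range(self.epochs):
            # forward with cached activations
            acts = [Xs]
            a = Xs
            for w, b in params[:-1]:
                a = np.tanh(a @ w.T + b)
                acts.append(a)
            w_out, b_out = params[-1]
            z = (a @ w_out.T + b_out)[:, 0]
            p = 1.0 / (1.0 + np.exp(-z))
            p = np.clip(p, 1e-12, 1.0 - 1e-12)
            loss = cross_entropy(p, y)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            losses[epoch] = loss

            # backward pass (mean cross-entropy + logistic output)
            delta = (p - y)[:, None] / n  # (n, 1)
            grads: list = [None] * len(params)
            grads[-1] = (delta.T @ acts[-1], delta.sum(axis=0))
            back = delta @ w_out  # (n, fan_in of output)
            for li in range(len(params) - 2, -1, -1):
                w_li, _ = params[li]
                back = back * (1.0 - acts[li + 1] ** 2)
                grads[li] = (back.T @ acts[li], back.sum(axis=0))
                if li > 0:
                    back = back @ w_li

            t = epoch + 1
            new_params = []
            for li, ((w, b), (gw, gb)) in enumerate(zip(params, grads)):
                mw, mb = m[li]
                vw, vb = v[li]
                mw = beta1 * mw + (1 - beta1) * gw
                mb = beta1 * mb + (1 - beta1) * gb
                vw = beta2 * vw + (1 - beta2) * gw**2
                vb = beta2 * vb + (1 - beta2) * gb**2
                m[li], v[li] = (mw, mb), (vw, vb)
                mhw, mhb = mw / (1 - beta1**t), mb / (1 - beta1**t)
                vhw, vhb = vw / (1 - beta2**t), vb / (1 - beta2**t)
                new_params.append(
                    (
                        w - self.learning_rate * mhw / (np.sqrt(vhw) + eps),
                        b - self.learning_rate * mhb / (np.sqrt(vhb) + eps),
                    )
                )
            params = new_params
        self.weights_ = params
        self.loss_curve_ = losses
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        p = forward(self.weights_, Xs)
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        # strict inequality: an output of exactly 0.5 is called non-HCM
        return (self.decision_function(X) > self.threshold).astype(int)

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise RuntimeError("classifier is not fitted")


def train(X: np.ndarray, y: np.ndarray, config: NetworkConfig | None = None) -> MLPBinaryClassifier:
    """Functional wrapper: fit a fresh classifier under ``config``."""
    config = config or NetworkConfig()
    clf = MLPBinaryClassifier(
        hidden=config.hidden,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        seed=config.seed,
        threshold=config.threshold,
    )
    return clf.fit(X, y)


def classify(clf: MLPBinaryClassifier, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label samples: positive (HCM) iff the network output is > threshold."""
    return (clf.decision_function(np.atleast_2d(x)) > threshold).astype(int)


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Per-class shuffled round-robin fold assignment.

    Returns an integer fold id (0..k-1) per subject; per-class fold sizes
    differ by at most one, and every subject lands in exactly one test fold.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2 (no held-out data otherwise)")
    rng = np.random.default_rng(seed)
    folds = np.empty(labels.shape[0], dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls!r} has {idx.size} subjects, fewer than k={k}")
        perm = rng.permutation(idx)
        folds[perm] = np.arange(perm.size) % k
    return folds


@dataclass
class CVResult:
    """Per-fold metrics and ROC curves with mean/SD summaries."""

    fold_metrics: list[dict]  # per fold: auc, sensitivity, ... + indices
    fold_rocs: list[dict]  # per fold: {"fpr": [...], "tpr": [...]}
    summary: dict  # metric -> {"mean": ..., "sd": ...}
    median_roc: dict  # {"fpr": grid, "tpr": pointwise median}
    config: dict = dc_field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        def conv(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps(
            {
                "fold_metrics": self.fold_metrics,
                "fold_rocs": self.fold_rocs,
                "summary": self.summary,
                "median_roc": self.median_roc,
                "config": self.config,
            },
            indent=indent,
            default=conv,
            sort_keys=True,
        )


_CV_METRICS = ("auc", "sensitivity", "specificity", "ppv", "npv", "accuracy")


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    config: NetworkConfig | None = None,
    fpr_grid: np.ndarray | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the diagnosis network.

    Per fold: standardize on the training split, train for the configured
    epochs, score the held-out fifth; report AUC plus threshold-0.5
    confusion metrics. Summaries are the mean and sample SD (ddof=1) over
    folds; the median ROC is the pointwise median of fold ROC curves
    interpolated on a common FPR grid.
    """
    config = config or NetworkConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    folds = stratified_kfold(y, config.n_folds, config.seed)
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)

    fold_metrics, fold_rocs, tprs = [], [], []
    for f in range(config.n_folds):
        test = folds == f
        train_idx = np.flatnonzero(~test)
        test_idx = np.flatnonzero(test)
        clf = MLPBinaryClassifier(
            hidden=config.hidden,
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            seed=config.seed + f,
            threshold=config.threshold,
        ).fit(X[train_idx], y[train_idx])
        scores = clf.decision_function(X[test_idx])
        y_test = y[test_idx]
        row: dict = {"fold": f, "train_idx": train_idx.tolist(), "test_idx": test_idx.tolist()}
        if np.unique(y_test).size < 2:
            warnings.warn(f"fold {f} has a single-class test set; AUC undefined")
            row.update({m: float("nan") for m in _CV_METRICS})
        else:
            pred = (scores > config.threshold).astype(int)
            cm = confusion_metrics(pred, y_test)
            fpr, tpr = roc_points(scores, y_test)
            row["auc"] = rank_auc(scores, y_test)
            row.update(
                {
                    "sensitivity": cm["sensitivity"],
                    "specificity": cm["specificity"],
                    "ppv": cm["ppv"],
                    "npv": cm["npv"],
                    "accuracy": cm["accuracy"],
                }
            )
            fold_rocs.append({"fold": f, "fpr": fpr.tolist(), "tpr": tpr.tolist()})
            tprs.append(np.interp(fpr_grid, fpr, tpr))
        fold_metrics.append(row)

    summary = {}
    for mname in _CV_METRICS:
        vals = np.array([fm[mname] for fm in fold_metrics], dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() < len(vals):
            warnings.warn(f"metric {mname}: {len(vals) - ok.sum()} undefined fold(s) excluded")
        vals = vals[ok]
        summary[mname] = {
            "mean": float(vals.mean()) if vals.size else float("nan"),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
        }
    median_roc = {
        "fpr": fpr_grid.tolist(),
        "tpr": np.median(np.vstack(tprs), axis=0).tolist() if tprs else [],
    }
    return CVResult(
        fold_metrics=fold_metrics,
        fold_rocs=fold_rocs,
        summary=summary,
        median_roc=median_roc,
        config={
            "hidden": list(config.hidden),
            "epochs": config.epochs,
            "learning_rate": config.learning_rate,
            "seed": config.seed,
            "threshold": config.threshold,
            "n_folds": config.n_folds,
        },
    )
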