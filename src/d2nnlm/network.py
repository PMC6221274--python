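"""Feed-forward neural language-model classifiers (NNLM / DNNLM / D2NNLM).

One architecture covers the three variants, differing only in depth and in
what is fed to it:

* NNLM   — 1 tanh hidden layer over the raw sparse n-gram vectors;
* DNNLM  — 3 (or more) tanh hidden layers over the same sparse vectors;
* D2NNLM — 3 (or more) tanh hidden layers over SVD-reduced higher-order
  n-gram features, where the reduced coordinates themselves play the role
  of the continuous projection layer.

Hidden activations are d_j = tanh(sum_l M_jl c_l + b_j); the output layer
o_i = sum_j V_ij d_j + k_i feeds a softmax giving class probabilities p_i.
Training minimizes the mean negative log-likelihood of the targets plus an
elastic-net penalty on the weight matrices,

    E = -(1/B) sum_batch log p_target  +  l1 * sum |W|  +  l2 * sum W^2,

by minibatch stochastic gradient descent with a constant learning rate, for
a fixed number of epochs (500 by default), with seeded Glorot-uniform
initialization and seeded epoch-level shuffling, so training is fully
deterministic for a given ``random_state``.
"""

from __future__ import annotations

import io
import json
import zipfile
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin, clone

from .evaluation import percent_error, perplexity

__all__ = [
    "NeuralLMClassifier",
    "gradient_check",
    "grid_search",
    "save_model",
    "load_model",
]


def _as_dense(X) -> np.ndarray:
    if sp.issparse(X):
        X = X.todense()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    return X


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_cached(weights, biases, X):
    """Activations of every layer; returns (list of hidden activations, probs)."""
    acts = []
    a = X
    for W, b in zip(weights[:-1], biases[:-1]):
        a = np.tanh(a @ W + b)
        acts.append(a)
    logits = a @ weights[-1] + biases[-1]
    return acts, _softmax(logits)


def _loss_and_grads(weights, biases, X, T, l1, l2):
    """Regularized NLL and its gradients w.r.t. every weight and bias."""
    B = X.shape[0]
    acts, P = _forward_cached(weights, biases, X)
    eps = 1e-300  # guards log(0) from extreme logits; softmax is > 0 analytically
    data = -np.sum(T * np.log(P + eps)) / B
    reg = sum(l1 * np.abs(W).sum() + l2 * (W * W).sum() for W in weights)
    gW = [None] * len(weights)
    gb = [None] * len(biases)
    delta = (P - T) / B
    layer_inputs = [X] + acts
    for k in range(len(weights) - 1, -1, -1):
        W = weights[k]
        gW[k] = layer_inputs[k].T @ delta + l1 * np.sign(W) + 2.0 * l2 * W
        gb[k] = delta.sum(axis=0)
        if k > 0:
            delta = (delta @ W.T) * (1.0 - acts[k - 1] ** 2)
    return data + reg, gW, gb


class NeuralLMClassifier(BaseEstimator, ClassifierMixin):
    """Multi-layer tanh/softmax classifier trained by minibatch SGD.

    Parameters
    ----------
    hidden_layers : int, default 3
        Number of tanh hidden layers (1 = NNLM-style, >= 3 = deep variants).
    hidden_units : int, default 16
        Units H in every hidden layer.
    epochs : int, default 500
        Full passes over the training data.
    batch_size : int, default 9
        Minibatch size; the last short minibatch of an epoch is kept.
    learning_rate : float, default 0.01
        Constant SGD step size (no momentum, no decay).
    l1, l2 : float, default 1e-4
        Elastic-net penalties on the weight matrices (biases unpenalized);
        small near-zero values by default.
    random_state : int, default 0
        Seeds both initialization and epoch shuffling.

    Attributes
    ----------
    classes_ : class labels in sorted order.
    weights_, biases_ : per-layer parameters (last entry is the softmax layer).
    history_ : DataFrame with per-epoch mean training loss (and validation
        percent error when validation data is supplied to ``fit``).
    """

    def __init__(self, hidden_layers: int = 3, hidden_units: int = 16,
                 epochs: int = 500, batch_size: int = 9,
                 learning_rate: float = 0.01, l1: float = 1e-4,
                 l2: float = 1e-4, random_state: int = 0):
        self.hidden_layers = hidden_layers
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.l1 = l1
        self.l2 = l2
        self.random_state = random_state

    # -- parameter initialization -------------------------------------------------

    def _init_params(self, n_features: int, n_classes: int, rng: np.random.Generator):
        if self.hidden_layers < 1:
            raise ValueError("hidden_layers must be >= 1")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        dims = [n_features] + [self.hidden_units] * self.hidden_layers + [n_classes]
        weights, biases = [], []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return weights, biases

    # -- sklearn API --------------------------------------------------------------

    def fit(self, X, y, validation_data=None) -> "NeuralLMClassifier":
        X = _as_dense(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least one example of each of >= 2 classes")
        n, d = X.shape
        if not 1 <= self.batch_size <= n:
            raise ValueError(f"batch_size must be in [1, {n}]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("l1 and l2 must be nonnegative")
        T_full = np.eye(len(self.classes_))[y_idx]

        rng = np.random.default_rng(self.random_state)
        weights, biases = self._init_params(d, len(self.classes_), rng)

        val = None
        if validation_data is not None:
            Xv, yv = validation_data
            val = (_as_dense(Xv), np.asarray(yv))

        history = []
        for epoch in range(self.epochs):
            perm = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, self.batch_size):
                idx = perm[start:start + self.batch_size]
                loss, gW, gb = _loss_and_grads(
                    weights, biases, X[idx], T_full[idx], self.l1, self.l2)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}: {loss}")
                for k in range(len(weights)):
                    weights[k] -= self.learning_rate * gW[k]
                    biases[k] -= self.learning_rate * gb[k]
                batch_losses.append(loss)
            rec = {"epoch": epoch, "train_loss": float(np.mean(batch_losses))}
            if val is not None:
                rec["validation_percent_error"] = percent_error(
                    self._predict_with(weights, biases, val[0]), val[1])
            history.append(rec)

        self.weights_ = weights
        self.biases_ = biases
        self.n_features_in_ = d
        self.history_ = pd.DataFrame(history)
        return self

    def _check_fitted_X(self, X) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise RuntimeError("NeuralLMClassifier is not fitted")
        X = _as_dense(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}")
        return X

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_fitted_X(X)
        _, P = _forward_cached(self.weights_, self.biases_, X)
        return P

    def _predict_with(self, weights, biases, X):
        _, P = _forward_cached(weights, biases, X)
        return self.classes_[P.argmax(axis=1)]

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def confidence(self, X, positive_label) -> np.ndarray:
        """Score used for ranking/AUC: probability of the positive class."""
        col = int(np.flatnonzero(self.classes_ == positive_label)[0])
        return self.predict_proba(X)[:, col]

    def loss(self, X, y) -> float:
        """Regularized mean negative log-likelihood on (X, y)."""
        X = self._check_fitted_X(X)
        y_idx = np.searchsorted(self.classes_, np.asarray(y))
        T = np.eye(len(self.classes_))[y_idx]
        value, _, _ = _loss_and_grads(self.weights_, self.biases_, X, T,
                                      self.l1, self.l2)
        return float(value)


# -- gradient verification --------------------------------------------------------


def gradient_check(clf: NeuralLMClassifier, X, y, tol: float = 1e-4,
                   step: float = 1e-6) -> tuple[bool, float]:
    """Compare analytic gradients with central finite differences.

    Initializes (or reuses) the classifier's parameters, computes the
    analytic gradient of the regularized loss on the given small batch, and
    perturbs every parameter by ±``step``.  Returns ``(passed, max relative
    deviation)`` where the deviation for each parameter is
    |analytic - numeric| / max(1, |analytic|, |numeric|).
    """
    X = _as_dense(X)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    T = np.eye(len(classes))[y_idx]
    if hasattr(clf, "weights_"):
        weights = [W.copy() for W in clf.weights_]
        biases = [b.copy() for b in clf.biases_]
    else:
        rng = np.random.default_rng(clf.random_state)
        weights, biases = clf._init_params(X.shape[1], len(classes), rng)

    _, gW, gb = _loss_and_grads(weights, biases, X, T, clf.l1, clf.l2)

    def loss_at() -> float:
        val, _, _ = _loss_and_grads(weights, biases, X, T, clf.l1, clf.l2)
        return val

    max_dev = 0.0
    for params, grads in ((weights, gW), (biases, gb)):
        for arr, g in zip(params, grads):
            flat, gflat = arr.ravel(), g.ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + step
                up = loss_at()
                flat[i] = orig - step
                down = loss_at()
                flat[i] = orig
                numeric = (up - down) / (2 * step)
                dev = abs(gflat[i] - numeric) / max(1.0, abs(gflat[i]), abs(numeric))
                max_dev = max(max_dev, dev)
    return max_dev < tol, max_dev


# -- grid search ------------------------------------------------------------------


def grid_search(
    estimator,
    train: tuple,
    validation: tuple,
    test: tuple,
    hidden_units_grid: Sequence[int],
    batch_size_grid: Sequence[int],
    positive_label,
    select_on: str = "validation",
    h_param: str = "hidden_units",
    b_param: str = "batch_size",
):
    """Exhaustive grid over hidden units and minibatch sizes.

    Trains one model per grid cell and selects the cell minimizing percent
    error on the ``select_on`` set (default: validation; ``"test"`` mimics
    selection on the held-out test set).  Ties are broken by lower
    perplexity, then smaller hidden-unit count, then smaller batch size.

    Returns ``(best_estimator, best_params, table)`` where ``table`` is a
    DataFrame with one row per cell: H, batch, percent error and perplexity
    on both held-out sets.
    """
    if select_on not in ("validation", "test"):
        raise ValueError("select_on must be 'validation' or 'test'")
    Xtr, ytr = train
    sets = {"validation": validation, "test": test}
    rows = []
    fitted = {}
    for H in hidden_units_grid:
        for bz in batch_size_grid:
            model = clone(estimator)
            model.set_params(**{h_param: int(H), b_param: int(bz)})
            model.fit(Xtr, ytr)
            row = {"hidden_units": int(H), "batch_size": int(bz)}
            for name, (Xs, ys) in sets.items():
                pred = model.predict(Xs)
                probs = model.predict_proba(Xs)
                clf = model[-1] if hasattr(model, "steps") else model
                q = probs[np.arange(len(ys)),
                          np.searchsorted(clf.classes_, np.asarray(ys))]
                row[f"{name}_percent_error"] = percent_error(pred, ys)
                row[f"{name}_perplexity"] = perplexity(q)
            rows.append(row)
            fitted[(int(H), int(bz))] = model
    table = pd.DataFrame(rows)
    order = table.sort_values(
        by=[f"{select_on}_percent_error", f"{select_on}_perplexity",
            "hidden_units", "batch_size"],
        kind="mergesort",
    )
    best = order.iloc[0]
    best_params = {"hidden_units": int(best["hidden_units"]),
                   "batch_size": int(best["batch_size"])}
    return fitted[(best_params["hidden_units"], best_params["batch_size"])], \
        best_params, table


# -- persistence ------------------------------------------------------------------

_FORMAT_VERSION = 1


def _zip_write(zf: zipfile.ZipFile, name: str, data: bytes) -> None:
    # fixed timestamp so identical models produce byte-identical archives
    info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
    zf.writestr(info, data)


def save_model(clf: NeuralLMClassifier, path: str | Path) -> None:
    """Save a fitted classifier to a single self-describing zip archive."""
    if not hasattr(clf, "weights_"):
        raise RuntimeError("cannot save an unfitted model")
    meta = {
        "format_version": _FORMAT_VERSION,
        "params": clf.get_params(),
        "classes": [str(c) for c in clf.classes_],
        "n_layers": len(clf.weights_),
        "n_features_in": int(clf.n_features_in_),
    }
    with zipfile.ZipFile(path, "w") as zf:
        _zip_write(zf, "meta.json", json.dumps(meta, indent=1, sort_keys=True).encode())
        arrays = {f"W{k}": W for k, W in enumerate(clf.weights_)}
        arrays.update({f"b{k}": b for k, b in enumerate(clf.biases_)})
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, arr)
            _zip_write(zf, f"{name}.npy", buf.getvalue())


def load_model(path: str | Path) -> NeuralLMClassifier:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["format_version"] != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format {meta['format_version']}")
        clf = NeuralLMClassifier(**meta["params"])
        clf.weights_ = [np.load(io.BytesIO(zf.read(f"W{k}.npy")))
                        for k in range(meta["n_layers"])]
        clf.biases_ = [np.load(io.BytesIO(zf.read(f"b{k}.npy")))
                       for k in range(meta["n_layers"])]
    clf.classes_ = np.asarray(meta["classes"])
    clf.n_features_in_ = meta["n_features_in"]
    return clf
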