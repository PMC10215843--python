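"""Pathway expression classifiers: a Chebyshev-filter graph convolutional
network (ChebNet) over the pathway PPI graph, and a plain multilayer
perceptron on the same 111-gene feature vector.

Both are sklearn-style estimators (``fit`` / ``predict`` /
``predict_proba``) trained with Adam on softmax cross-entropy, implemented
in NumPy. Architectures follow the study design they reproduce:

* GCNN — two graph-convolution layers of 32 Chebyshev filters of
  polynomial order 20, each followed by ReLU and size-2 max pooling on the
  coarsening binary tree, then fully connected layers of 512 and 128 units
  and a 2-class softmax head;
* MLP — 111 inputs, hidden ReLU layers of 42, 21 and 10 units, 2-class
  softmax head (5,849 trainable parameters at the default width).

Training protocol choices the study leaves open (optimizer, learning rate,
epoch budget, batch size, initialization, splits) are exposed as estimator
parameters with conventional defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from ._nn import (
    Adam,
    cheb_basis,
    cheb_layer_backward,
    cheb_layer_forward,
    chebyshev_filter,
    glorot_uniform,
    softmax,
    softmax_cross_entropy,
)
from .graph import CoarseningHierarchy, coarsen, permute_signal

__all__ = [
    "chebyshev_filter",
    "mlp_forward",
    "gcnn_forward",
    "PathwayMLPClassifier",
    "ChebNetClassifier",
    "Metrics",
    "TrainResult",
    "train",
    "evaluate",
]


# ---------------------------------------------------------------------------
# functional forward passes
# ---------------------------------------------------------------------------

def mlp_forward(X: np.ndarray, weights: list, biases: list) -> np.ndarray:
    """Forward pass of the MLP; returns per-sample class probabilities.

    ``weights``/``biases`` hold every layer including the softmax head; all
    hidden layers use ReLU. All-zero parameters therefore give exactly
    uniform probabilities.
    """
    H = np.asarray(X, dtype=float)
    if H.shape[1] != weights[0].shape[0]:
        raise ValueError(
            f"input has {H.shape[1]} features, first layer expects {weights[0].shape[0]}"
        )
    for W, b in zip(weights[:-1], biases[:-1]):
        H = np.maximum(H @ W + b, 0.0)
    logits = H @ weights[-1] + biases[-1]
    return softmax(logits)


def _maxpool(H: np.ndarray, size: int):
    """Size-``size`` stride-``size`` max pool along the node axis (axis 1)."""
    b, n, f = H.shape
    if n % size:
        raise ValueError(f"{n} nodes not divisible by pool size {size}")
    R = H.reshape(b, n // size, size, f)
    arg = R.argmax(axis=2)
    return R.max(axis=2), arg


def gcnn_forward(
    X: np.ndarray,
    hierarchy: CoarseningHierarchy,
    bases: list,
    params: dict,
    pool_size: int = 2,
) -> np.ndarray:
    """Forward pass of the graph network; returns class probabilities.

    ``X`` is samples x real-nodes (one scalar expression channel per gene);
    ``bases[l]`` is the Chebyshev basis stack of the level-``l`` padded
    graph. Parameters: ``theta{l}``/``bconv{l}`` per conv layer, ``W{i}``/
    ``b{i}`` for the dense head.
    """
    Xp = np.stack([permute_signal(x, hierarchy) for x in np.asarray(X, dtype=float)])
    H = Xp[:, :, None]
    n_conv = sum(1 for k in params if k.startswith("theta"))
    for layer in range(n_conv):
        H, _ = cheb_layer_forward(
            bases[layer], H, params[f"theta{layer}"], params[f"bconv{layer}"]
        )
        H = np.maximum(H, 0.0)
        H, _ = _maxpool(H, pool_size)
    F = H.reshape(H.shape[0], -1)
    n_dense = sum(1 for k in params if k.startswith("W"))
    for i in range(n_dense - 1):
        F = np.maximum(F @ params[f"W{i}"] + params[f"b{i}"], 0.0)
    logits = F @ params[f"W{n_dense - 1}"] + params[f"b{n_dense - 1}"]
    return softmax(logits)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class _BaseNet(BaseEstimator, ClassifierMixin):
    """Shared Adam/minibatch training loop with plateau early stopping."""

    def _encode_y(self, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        y_idx = np.searchsorted(self.classes_, y)
        onehot = np.eye(len(self.classes_))[y_idx]
        return y_idx, onehot

    def _sample_weights(self, y_idx):
        if getattr(self, "class_weight", None) == "balanced":
            counts = np.bincount(y_idx, minlength=len(self.classes_))
            w = len(y_idx) / (len(self.classes_) * counts.astype(float))
            return w[y_idx]
        return None

    def _standardize_fit(self, X):
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
            return (X - self.mean_) / self.scale_
        self.mean_ = np.zeros(X.shape[1])
        self.scale_ = np.ones(X.shape[1])
        return X

    def _standardize(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def _train_loop(self, X, onehot, sample_weight, rng):
        n = X.shape[0]
        opt = Adam(self.params_, lr=self.learning_rate)
        self.loss_curve_ = []
        best = np.inf
        stall = 0
        for _epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                sw = None if sample_weight is None else sample_weight[idx]
                loss, grads = self._loss_and_grads(X[idx], onehot[idx], sw)
                opt.step(grads)
                epoch_loss += loss * len(idx)
            epoch_loss /= n
            self.loss_curve_.append(epoch_loss)
            if epoch_loss < best - self.tol:
                best = epoch_loss
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        self.n_iter_ = len(self.loss_curve_)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


class PathwayMLPClassifier(_BaseNet):
    """Multilayer perceptron on pathway gene expression.

    Parameters
    ----------
    hidden_units : tuple of int
        ReLU hidden layer widths (default (42, 21, 10)); the input width is
        the number of pathway genes, the head is an ``n_classes`` softmax.
    class_weight : None or "balanced"
        Optional inverse-frequency loss weighting for the imbalanced design.
    standardize : bool
        Standardize features on the training set (recommended for raw log2
        intensities).
    """

    def __init__(
        self,
        hidden_units=(42, 21, 10),
        learning_rate=1e-3,
        max_epochs=200,
        batch_size=32,
        tol=1e-4,
        patience=10,
        class_weight=None,
        standardize=True,
        random_state=0,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.tol = tol
        self.patience = patience
        self.class_weight = class_weight
        self.standardize = standardize
        self.random_state = random_state

    def _init_params(self, n_features, n_classes, rng):
        dims = [n_features, *self.hidden_units, n_classes]
        params = {}
        for i, (fin, fout) in enumerate(zip(dims[:-1], dims[1:])):
            params[f"W{i}"] = glorot_uniform(rng, (fin, fout), fin, fout)
            params[f"b{i}"] = np.zeros(fout)
        return params

    @property
    def n_parameters_(self):
        check_is_fitted(self, "params_")
        return int(sum(v.size for v in self.params_.values()))

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be samples x genes")
        y_idx, onehot = self._encode_y(y)
        for c in range(len(self.classes_)):
            if (y_idx == c).sum() < 2:
                raise ValueError(
                    f"class {self.classes_[c]!r} has <2 training samples"
                )
        self.n_features_in_ = X.shape[1]
        Xs = self._standardize_fit(X)
        rng = np.random.default_rng(self.random_state)
        self.params_ = self._init_params(X.shape[1], len(self.classes_), rng)
        sw = self._sample_weights(y_idx)
        self._train_loop(Xs, onehot, sw, rng)
        return self

    def _loss_and_grads(self, Xb, Yb, sw):
        p = self.params_
        n_layers = len(self.hidden_units) + 1
        acts = [Xb]
        H = Xb
        for i in range(n_layers - 1):
            H = np.maximum(H @ p[f"W{i}"] + p[f"b{i}"], 0.0)
            acts.append(H)
        logits = H @ p[f"W{n_layers - 1}"] + p[f"b{n_layers - 1}"]
        loss, dlogits = softmax_cross_entropy(logits, Yb, sw)
        grads = {}
        d = dlogits
        for i in range(n_layers - 1, -1, -1):
            grads[f"W{i}"] = acts[i].T @ d
            grads[f"b{i}"] = d.sum(axis=0)
            if i > 0:
                d = (d @ p[f"W{i}"].T) * (acts[i] > 0)
        return loss, grads

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        Xs = self._standardize(X)
        n_layers = len(self.hidden_units) + 1
        weights = [self.params_[f"W{i}"] for i in range(n_layers)]
        biases = [self.params_[f"b{i}"] for i in range(n_layers)]
        return mlp_forward(Xs, weights, biases)


class ChebNetClassifier(_BaseNet):
    """Spectral graph convolutional network on the pathway PPI graph.

    The graph is coarsened ``n_conv_layers`` times (Graclus-style matching,
    binary-tree padding); each convolution applies ``n_filters`` Chebyshev
    filters of order ``poly_order`` on the rescaled normalized Laplacian of
    its level, followed by ReLU and size-``pool_size`` max pooling; a dense
    ReLU head of ``fc_units`` feeds the softmax output.

    Parameters
    ----------
    graph : PPIGraph
        Pathway graph; node order must match the columns of X. Alternatively
        pass a prebuilt ``hierarchy``.
    lambda_max : float or None
        None (default) computes the exact largest Laplacian eigenvalue per
        level; 2.0 opts into the spectral upper bound.
    """

    def __init__(
        self,
        graph=None,
        hierarchy=None,
        n_conv_layers=2,
        n_filters=32,
        poly_order=20,
        pool_size=2,
        fc_units=(512, 128),
        learning_rate=1e-3,
        max_epochs=200,
        batch_size=32,
        tol=1e-4,
        patience=10,
        class_weight=None,
        standardize=True,
        lambda_max=None,
        coarsen_seed=0,
        random_state=0,
    ):
        self.graph = graph
        self.hierarchy = hierarchy
        self.n_conv_layers = n_conv_layers
        self.n_filters = n_filters
        self.poly_order = poly_order
        self.pool_size = pool_size
        self.fc_units = fc_units
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.tol = tol
        self.patience = patience
        self.class_weight = class_weight
        self.standardize = standardize
        self.lambda_max = lambda_max
        self.coarsen_seed = coarsen_seed
        self.random_state = random_state

    # -- setup ------------------------------------------------------------
    def _build_structure(self):
        if self.hierarchy is not None:
            h = self.hierarchy
        elif self.graph is not None:
            h = coarsen(self.graph, n_levels=self.n_conv_layers, seed=self.coarsen_seed)
        else:
            raise ValueError("ChebNetClassifier needs a graph or a hierarchy")
        if h.n_levels < self.n_conv_layers:
            raise ValueError(
                f"hierarchy has {h.n_levels} levels but {self.n_conv_layers} conv "
                "layers each need one pooling level"
            )
        self.hierarchy_ = h
        laps = h.scaled_laplacians(lambda_max=self.lambda_max)
        self.bases_ = [
            cheb_basis(laps[l].matrix, self.poly_order)
            for l in range(self.n_conv_layers)
        ]

    def _init_params(self, n_classes, rng):
        K, F = self.poly_order, self.n_filters
        params = {}
        f_in = 1
        for layer in range(self.n_conv_layers):
            params[f"theta{layer}"] = glorot_uniform(
                rng, (K, f_in, F), K * f_in, F
            )
            params[f"bconv{layer}"] = np.zeros(F)
            f_in = F
        n_out_nodes = self.hierarchy_.level_sizes()[self.n_conv_layers]
        dims = [n_out_nodes * F, *self.fc_units, n_classes]
        for i, (fin, fout) in enumerate(zip(dims[:-1], dims[1:])):
            params[f"W{i}"] = glorot_uniform(rng, (fin, fout), fin, fout)
            params[f"b{i}"] = np.zeros(fout)
        return params

    # -- training ---------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self._build_structure()
        if X.shape[1] != self.hierarchy_.n_real:
            raise ValueError(
                f"X has {X.shape[1]} genes but the graph has "
                f"{self.hierarchy_.n_real} nodes"
            )
        y_idx, onehot = self._encode_y(y)
        for c in range(len(self.classes_)):
            if (y_idx == c).sum() < 2:
                raise ValueError(f"class {self.classes_[c]!r} has <2 training samples")
        self.n_features_in_ = X.shape[1]
        Xs = self._standardize_fit(X)
        Xp = np.stack([permute_signal(x, self.hierarchy_) for x in Xs])
        rng = np.random.default_rng(self.random_state)
        self.params_ = self._init_params(len(self.classes_), rng)
        sw = self._sample_weights(y_idx)
        self._train_loop(Xp, onehot, sw, rng)
        return self

    def _loss_and_grads(self, Xb, Yb, sw):
        p = self.params_
        H = Xb[:, :, None]
        caches = []
        for layer in range(self.n_conv_layers):
            pre, Z = cheb_layer_forward(
                self.bases_[layer], H, p[f"theta{layer}"], p[f"bconv{layer}"]
            )
            act = np.maximum(pre, 0.0)
            pooled, arg = _maxpool(act, self.pool_size)
            caches.append((Z, pre, act.shape, arg))
            H = pooled
        flat = H.reshape(H.shape[0], -1)
        conv_out_shape = H.shape
        n_dense = len(self.fc_units) + 1
        acts = [flat]
        F = flat
        for i in range(n_dense - 1):
            F = np.maximum(F @ p[f"W{i}"] + p[f"b{i}"], 0.0)
            acts.append(F)
        logits = F @ p[f"W{n_dense - 1}"] + p[f"b{n_dense - 1}"]
        loss, dlogits = softmax_cross_entropy(logits, Yb, sw)

        grads = {}
        d = dlogits
        for i in range(n_dense - 1, 0, -1):
            grads[f"W{i}"] = acts[i].T @ d
            grads[f"b{i}"] = d.sum(axis=0)
            d = (d @ p[f"W{i}"].T) * (acts[i] > 0)
        grads["W0"] = acts[0].T @ d
        grads["b0"] = d.sum(axis=0)
        # flatten is linear; the ReLU mask for the conv stack lives in dpre below
        dH = (d @ p["W0"].T).reshape(conv_out_shape)
        for layer in range(self.n_conv_layers - 1, -1, -1):
            Z, pre, act_shape, arg = caches[layer]
            dact = np.zeros(act_shape)
            b, npool, f = dH.shape
            bi = np.arange(b)[:, None, None]
            ni = np.arange(npool)[None, :, None]
            fi = np.arange(f)[None, None, :]
            dact_r = dact.reshape(b, npool, self.pool_size, f)
            dact_r[bi, ni, arg, fi] = dH
            dact = dact_r.reshape(act_shape)
            dpre = dact * (pre > 0)
            dtheta, dbias, dH = cheb_layer_backward(
                self.bases_[layer], Z, p[f"theta{layer}"], dpre,
                need_dinput=layer > 0,
            )
            grads[f"theta{layer}"] = dtheta
            grads[f"bconv{layer}"] = dbias
        return loss, grads

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        Xs = self._standardize(X)
        return gcnn_forward(
            Xs, self.hierarchy_, self.bases_, self.params_, self.pool_size
        )


# ---------------------------------------------------------------------------
# evaluation and the train wrapper
# ---------------------------------------------------------------------------


@dataclass
class Metrics:
    """Classification metrics: accuracy, weighted F1, per-class detail."""

    accuracy: float
    f1_weighted: float
    per_class: dict
    confusion: np.ndarray
    labels: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1_weighted": self.f1_weighted,
            "per_class": self.per_class,
            "confusion": self.confusion.tolist(),
            "labels": list(self.labels),
        }


def evaluate(y_true, y_pred, labels=None) -> Metrics:
    """Accuracy, weighted F1 and per-class precision/recall/F1.

    Weighted F1 is the support-weighted mean of per-class F1 scores; classes
    with no true and no predicted members contribute F1 = 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("prediction and truth lengths differ")
    if len(y_true) == 0:
        raise ValueError("cannot evaluate zero samples")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    else:
        unknown = (set(y_true) | set(y_pred)) - set(labels)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in the declared vocabulary")
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    weighted_f1 = float(np.average(f1, weights=support)) if support.sum() else 0.0
    return Metrics(
        accuracy=float(accuracy_score(y_true, y_pred)),
        f1_weighted=weighted_f1,
        per_class={
            str(lab): {
                "precision": float(p),
                "recall": float(r),
                "f1": float(f),
                "support": int(s),
            }
            for lab, p, r, f, s in zip(labels, prec, rec, f1, support)
        },
        confusion=confusion_matrix(y_true, y_pred, labels=labels),
        labels=list(labels),
    )


@dataclass
class TrainResult:
    """A fitted model plus the split and loss trace that produced it."""

    model: object
    train_ids: list
    test_ids: list
    loss_curve: list
    seed: int
    train_metrics: Metrics = None
    test_metrics: Metrics = None


def train(
    model,
    X,
    y,
    sample_ids=None,
    test_size: float = 0.2,
    seed: int = 0,
) -> TrainResult:
    """Stratified split, fit, and evaluate a classifier.

    The estimator's own ``random_state`` governs initialization and batch
    shuffling; ``seed`` governs the split. Requires >=2 samples per class in
    the training portion.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if sample_ids is None:
        sample_ids = list(range(len(y)))
    idx = np.arange(len(y))
    tr, te = train_test_split(
        idx, test_size=test_size, stratify=y, random_state=seed
    )
    model.fit(X[tr], y[tr])
    train_m = evaluate(y[tr], model.predict(X[tr]), labels=list(model.classes_))
    test_m = evaluate(y[te], model.predict(X[te]), labels=list(model.classes_))
    return TrainResult(
        model=model,
        train_ids=[sample_ids[i] for i in tr],
        test_ids=[sample_ids[i] for i in te],
        loss_curve=list(model.loss_curve_),
        seed=seed,
        train_metrics=train_m,
        test_metrics=test_m,
    )
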