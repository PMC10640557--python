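"""Imbalance-aware segment classifiers over comodulogram features.

Five models label 20-s segments as SOZ (positive) or NSOZ from their 16 x 16
z-scored comodulogram: class-weighted SVMs (linear and RBF kernel), a
class-weighted LightGBM, and a small 2-D CNN trained with either the focal
loss or the class-balanced ("class-weighted") focal loss.  The SVM/LightGBM
input is the comodulogram flattened to a 256-vector; the CNN consumes the
16 x 16 matrix directly.

Class imbalance machinery
-------------------------
* Class-wise re-weighting: class i receives weight
  ``omega_i = N_samples / (N_classes * N_samples_i)``, so the effective SVM
  penalty is ``C_i = C * omega_i`` and ``sum_i n_i * omega_i = N_samples``.
* Focal loss: ``FL(p_t) = -alpha_t * (1 - p_t)^gamma * log(p_t)`` with
  ``p_t = p`` for positives and ``1 - p`` for negatives; ``gamma`` shifts
  training effort onto hard samples, ``alpha_t`` balances the classes.
* Class-balanced focal loss: the per-sample weight is the inverse *effective
  number* of its class, ``E_n = (1 - beta^n) / (1 - beta)``, which saturates
  as the class count n grows and hence down-weights the majority class.

The CNN (input 16 x 16 x 1) is implemented directly on numpy: two convolution
blocks (conv 32 -> BN -> ReLU, conv 64 -> BN -> ReLU, maxpool; conv 128 -> BN
-> ReLU, maxpool), a 128-unit ReLU dense layer with dropout 0.5, and a sigmoid
output unit; He-uniform initialisation in the convolution layers, Adam, batch
size 128, up to 100 epochs with early stopping on validation loss.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .pac import ComodulogramTensor

__all__ = [
    "FOCAL_ALPHA_GRID",
    "FOCAL_GAMMA_GRID",
    "CB_BETA_GRID",
    "LIGHTGBM_GRID",
    "MODEL_KINDS",
    "FeatureMatrix",
    "ClassWeightSpec",
    "flatten_comodulogram",
    "unflatten_comodulogram",
    "build_feature_matrix",
    "class_weights",
    "effective_number",
    "cb_weight",
    "focal_loss",
    "cb_focal_loss",
    "SvmModel",
    "GbmModel",
    "Cnn2d",
    "CnnModel",
    "make_model",
    "default_grid",
    "train_svm",
    "train_gbm",
    "build_cnn",
]

P_CLIP = 1e-7  # probability clamp used inside every loss

# Tuning grids.
FOCAL_ALPHA_GRID = (0.75, 0.9, 0.99, 0.999, 0.9999)
FOCAL_GAMMA_GRID = (0.5, 1.0, 2.0, 5.0)
CB_BETA_GRID = (0.75, 0.9, 0.99, 0.999, 0.9999)
SVM_C_GRID = (0.1, 1.0, 10.0, 100.0)
SVM_GAMMA_GRID = (1e-3, 1e-2, 1e-1, 1.0, "scale")
LIGHTGBM_GRID = {
    "num_leaves": (35, 40, 45, 50, 55, 60, 65),
    "max_depth": (4, 6, 8, 10),
    "learning_rate": (0.01, 0.05, 0.1, 0.15),
    "min_data_in_leaf": (20, 40, 60, 100),
}
MODEL_KINDS = ("svm_linear", "svm_rbf", "lightgbm", "cnn_focal", "cnn_cb_focal")


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def flatten_comodulogram(com: np.ndarray) -> np.ndarray:
    """Flatten a 16 x 16 comodulogram to a 256-vector.

    Raster order is row-major over (amplitude band, phase band); the
    round trip through :func:`unflatten_comodulogram` is exact.
    """
    com = np.asarray(com)
    if com.shape != (16, 16):
        raise ValueError(f"expected a 16x16 matrix, got {com.shape}")
    return com.reshape(256)


def unflatten_comodulogram(vec: np.ndarray) -> np.ndarray:
    vec = np.asarray(vec)
    if vec.shape != (256,):
        raise ValueError(f"expected a 256-vector, got {vec.shape}")
    return vec.reshape(16, 16)


@dataclass
class FeatureMatrix:
    """Flattened comodulogram features with per-row segment metadata.

    ``X`` is (n_rows, 256); ``meta`` has columns channel, channel_index,
    segment and y (SOZ = 1, NSOZ = 0), aligned with the rows of ``X``.
    """

    X: np.ndarray
    meta: pd.DataFrame

    @property
    def y(self) -> np.ndarray:
        return self.meta["y"].to_numpy()

    @property
    def segments(self) -> np.ndarray:
        return self.meta["segment"].to_numpy()


def build_feature_matrix(tensor: ComodulogramTensor) -> FeatureMatrix:
    """One row per (channel, segment), channel-major, chronological within channel."""
    n_ch, n_seg = tensor.n_channels, tensor.n_segments
    X = tensor.values.reshape(n_ch * n_seg, 256)
    meta = pd.DataFrame(
        {
            "channel": np.repeat(tensor.channel_names, n_seg),
            "channel_index": np.repeat(np.arange(n_ch), n_seg),
            "segment": np.tile(tensor.segment_index, n_ch),
            "y": np.repeat(tensor.soz_mask.astype(int), n_seg),
        }
    )
    return FeatureMatrix(X=X, meta=meta)


# ---------------------------------------------------------------------------
# class weights and losses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassWeightSpec:
    """Per-class weights omega_i with the balance identity sum_i n_i*omega_i = N."""

    omega: tuple[float, ...]
    counts: tuple[int, ...]

    def penalties(self, C: float) -> tuple[float, ...]:
        """Effective per-class penalties C_i = C * omega_i."""
        return tuple(C * w for w in self.omega)

    def as_dict(self) -> dict[int, float]:
        return dict(enumerate(self.omega))


def class_weights(n_per_class) -> ClassWeightSpec:
    """omega_i = N_samples / (N_classes * N_samples_i)."""
    counts = tuple(int(n) for n in n_per_class)
    if any(n < 1 for n in counts):
        raise ValueError(f"all class counts must be >= 1, got {counts}")
    total = sum(counts)
    k = len(counts)
    return ClassWeightSpec(
        omega=tuple(total / (k * n) for n in counts), counts=counts
    )


def effective_number(beta: float, n) -> np.ndarray | float:
    """Effective number of samples E_n = (1 - beta^n) / (1 - beta)."""
    if not 0.0 <= beta < 1.0:
        raise ValueError(f"beta must lie in [0, 1), got {beta}")
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("class counts must be >= 1")
    if beta == 0.0:
        out = np.ones_like(n)
    else:
        out = (1.0 - beta ** n) / (1.0 - beta)
    return out if out.ndim else float(out)


def cb_weight(beta: float, n) -> np.ndarray | float:
    """Inverse effective number (1 - beta) / (1 - beta^n); decreasing in n."""
    return 1.0 / effective_number(beta, n)


def _pt(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clamp p and fold in the label: p_t = p if y==1 else 1-p."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    pos = (y == 1)
    p = np.clip(p, P_CLIP, 1.0 - P_CLIP)
    return np.where(pos, p, 1.0 - p), pos


def focal_loss(p, y, alpha: float, gamma: float, reduce: str = "mean"):
    """alpha-balanced focal loss -alpha_t * (1 - p_t)^gamma * log(p_t).

    ``y`` is 1 for the positive (SOZ) class, anything else counts as negative.
    ``gamma = 0`` recovers the alpha-balanced cross-entropy.  ``reduce`` is
    ``"mean"`` (batch loss) or ``"none"`` (per-sample values).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if gamma < 0.0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    pt, pos = _pt(p, y)
    at = np.where(pos, alpha, 1.0 - alpha)
    loss = -at * (1.0 - pt) ** gamma * np.log(pt)
    return float(loss.mean()) if reduce == "mean" else loss


def cb_focal_loss(p, y, n_class_of_y, beta: float, gamma: float, reduce: str = "mean"):
    """Class-balanced focal loss -(1/E_n) * (1 - p_t)^gamma * log(p_t).

    ``n_class_of_y`` is the training-set count of each sample's own class
    (scalar or per-sample array).  The weight 1/E_n saturates with the class
    count, down-weighting the majority class.
    """
    if gamma < 0.0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    pt, _ = _pt(p, y)
    w = cb_weight(beta, np.broadcast_to(n_class_of_y, pt.shape))
    loss = -w * (1.0 - pt) ** gamma * np.log(pt)
    return float(loss.mean()) if reduce == "mean" else loss


def _loss_and_grad_p(p, y, *, kind, alpha=None, beta=None, gamma=0.0, n_per_class=None):
    """Per-sample loss and dL/dp for the CNN training loop."""
    pt, pos = _pt(p, y)
    if kind == "focal":
        w = np.where(pos, alpha, 1.0 - alpha)
    else:  # cb_focal: weight by the sample's own class count
        n_y = np.where(pos, n_per_class[1], n_per_class[0])
        w = cb_weight(beta, n_y)
    one_m = 1.0 - pt
    loss = -w * one_m ** gamma * np.log(pt)
    # d/dpt [-(1-pt)^g log pt] = g (1-pt)^(g-1) log pt - (1-pt)^g / pt
    if gamma == 0.0:
        dpt = -1.0 / pt
    else:
        dpt = gamma * one_m ** (gamma - 1.0) * np.log(pt) - one_m ** gamma / pt
    dpt = w * dpt
    dp = np.where(pos, dpt, -dpt)  # pt = p or 1-p
    return loss, dp


# ---------------------------------------------------------------------------
# SVM and LightGBM wrappers (uniform fit / predict_score / predict_proba)
# ---------------------------------------------------------------------------

class SvmModel:
    """Class-weighted SVC with per-column standardisation (training stats only).

    ``predict_score`` is the decision function (a monotone SOZ score, used for
    AUC).  ``predict_proba`` maps the score through a Platt-style logistic
    sigmoid fitted on the training decision scores.  The sigmoid is fitted
    without an inner cross-validation: with only a handful of positive
    segments per training fold, cross-validated Platt scaling (as in
    ``SVC(probability=True)``) becomes unstable and can even anti-correlate
    with the decision function, whereas the direct fit is always monotone in
    the score.
    """

    def __init__(self, kernel: str, C: float = 1.0, gamma="scale",
                 probability: bool = True, seed: int = 0):
        if kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be 'linear' or 'rbf', got {kernel!r}")
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.probability = probability  # kept for interface symmetry; always available
        self.seed = seed
        self._svc = None

    def fit(self, X, y, X_val=None, y_val=None):
        from sklearn.linear_model import LogisticRegression
        from sklearn.svm import SVC

        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("training set contains a single class")
        cw = class_weights(counts)
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd[self._sd == 0.0] = 1.0
        self._svc = SVC(
            kernel=self.kernel,
            C=self.C,
            gamma=self.gamma if self.kernel == "rbf" else "scale",
            class_weight={int(c): w for c, w in zip(classes, cw.omega)},
            random_state=self.seed,
        )
        self._svc.fit((X - self._mu) / self._sd, y)
        scores = self._svc.decision_function((X - self._mu) / self._sd)
        self._platt = LogisticRegression(C=1.0).fit(scores[:, None], y)
        return self

    def _z(self, X):
        return (np.asarray(X, dtype=float) - self._mu) / self._sd

    def predict_score(self, X) -> np.ndarray:
        return self._svc.decision_function(self._z(X))

    def predict_proba(self, X) -> np.ndarray:
        scores = self.predict_score(X)
        return self._platt.predict_proba(scores[:, None])[:, 1]


class GbmModel:
    """LightGBM classifier with balanced class weights (Eq.-style omega_i)."""

    def __init__(self, num_leaves: int = 35, max_depth: int = 4,
                 learning_rate: float = 0.1, min_data_in_leaf: int = 20,
                 n_estimators: int = 100, seed: int = 0, **_ignored):
        self.params = dict(
            num_leaves=num_leaves, max_depth=max_depth,
            learning_rate=learning_rate, min_data_in_leaf=min_data_in_leaf,
        )
        self.n_estimators = n_estimators
        self.seed = seed
        self._gbm = None

    def fit(self, X, y, X_val=None, y_val=None):
        import lightgbm as lgb

        y = np.asarray(y, dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("training set contains a single class")
        cw = class_weights(counts)
        self._gbm = lgb.LGBMClassifier(
            num_leaves=self.params["num_leaves"],
            max_depth=self.params["max_depth"],
            learning_rate=self.params["learning_rate"],
            min_child_samples=self.params["min_data_in_leaf"],
            n_estimators=self.n_estimators,
            class_weight={int(c): w for c, w in zip(classes, cw.omega)},
            random_state=self.seed,
            n_jobs=1,
            verbosity=-1,
        )
        self._gbm.fit(np.asarray(X, dtype=float), y)
        return self

    def predict_score(self, X) -> np.ndarray:
        return self._gbm.predict_proba(np.asarray(X, dtype=float))[:, 1]

    predict_proba = predict_score


# ---------------------------------------------------------------------------
# 2-D CNN on numpy
# ---------------------------------------------------------------------------

def _he_uniform(rng, shape, fan_in):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def _conv_forward(x, W, b):
    """3x3 same-padding convolution, stride 1.  x: (N,H,Wd,C), W: (3,3,C,F)."""
    n, h, wd, c = x.shape
    f = W.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    cols = np.ascontiguousarray(np.moveaxis(win, 3, 5)).reshape(n * h * wd, 9 * c)
    out = (cols @ W.reshape(9 * c, f) + b).reshape(n, h, wd, f)
    return out, (cols, x.shape, W)


def _conv_backward(dout, cache):
    cols, x_shape, W = cache
    n, h, wd, c = x_shape
    f = W.shape[-1]
    dflat = dout.reshape(n * h * wd, f)
    dW = (cols.T @ dflat).reshape(W.shape)
    db = dflat.sum(axis=0)
    dcols = (dflat @ W.reshape(9 * c, f).T).reshape(n, h, wd, 3, 3, c)
    dxp = np.zeros((n, h + 2, wd + 2, c))
    for i in range(3):
        for j in range(3):
            dxp[:, i : i + h, j : j + wd, :] += dcols[:, :, :, i, j, :]
    return dxp[:, 1 : 1 + h, 1 : 1 + wd, :], dW, db


def _bn_forward(x, gamma, beta, state, training, momentum=0.9, eps=1e-3):
    axes = tuple(range(x.ndim - 1))
    if training:
        mu = x.mean(axis=axes)
        var = x.var(axis=axes)
        state["mean"] = momentum * state["mean"] + (1.0 - momentum) * mu
        state["var"] = momentum * state["var"] + (1.0 - momentum) * var
    else:
        mu, var = state["mean"], state["var"]
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * ivar
    out = gamma * xhat + beta
    m = int(np.prod([x.shape[a] for a in axes]))
    return out, (xhat, ivar, gamma, m, axes)


def _bn_backward(dout, cache):
    xhat, ivar, gamma, m, axes = cache
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    dx = (gamma * ivar / m) * (m * dout - dbeta - xhat * dgamma)
    return dx, dgamma, dbeta


def _maxpool_forward(x):
    n, h, wd, c = x.shape
    xr = x.reshape(n, h // 2, 2, wd // 2, 2, c)
    out = xr.max(axis=(2, 4))
    mask = xr == out[:, :, None, :, None, :]
    return out, (mask, x.shape)


def _maxpool_backward(dout, cache):
    mask, x_shape = cache
    counts = mask.sum(axis=(2, 4), keepdims=True)
    dxr = mask * (dout[:, :, None, :, None, :] / counts)
    return dxr.reshape(x_shape)


class Cnn2d:
    """2-D CNN for 16 x 16 comodulograms, trained with a focal-type loss.

    Architecture: conv(32, 3x3) -> BN -> ReLU -> conv(64, 3x3) -> BN -> ReLU
    -> maxpool 2x2 -> conv(128, 3x3) -> BN -> ReLU -> maxpool 2x2 -> flatten
    (2048) -> dense(128, ReLU) -> dropout(0.5) -> dense(1, sigmoid).  All
    convolutions use same padding, stride 1, He-uniform initialisation.
    Optimised with Adam; batch size 128; up to 100 epochs with early stopping
    (patience on validation loss, best weights restored).

    ``loss`` is ``"focal"`` (params ``alpha``, ``gamma``) or ``"cb_focal"``
    (params ``beta``, ``gamma``; the per-class counts are taken from the
    training subset passed to :meth:`fit`).
    """

    HIDDEN_SHAPES = {"block1": (8, 8, 64), "block2": (4, 4, 128), "flatten": 2048}

    def __init__(self, loss: str = "focal", alpha: float = 0.75,
                 beta: float = 0.9, gamma: float = 2.0, dense_units: int = 128,
                 dropout: float = 0.5, lr: float = 1e-3, epochs: int = 100,
                 batch_size: int = 128, patience: int = 10, seed: int = 0):
        if loss not in ("focal", "cb_focal"):
            raise ValueError(f"loss must be 'focal' or 'cb_focal', got {loss!r}")
        self.loss = loss
        self.alpha, self.beta, self.gamma = alpha, beta, gamma
        self.dense_units = dense_units
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self._init_params()

    def _init_params(self):
        rng = self._rng
        d = self.dense_units
        self.params = {
            "W1": _he_uniform(rng, (3, 3, 1, 32), 9 * 1), "b1": np.zeros(32),
            "W2": _he_uniform(rng, (3, 3, 32, 64), 9 * 32), "b2": np.zeros(64),
            "W3": _he_uniform(rng, (3, 3, 64, 128), 9 * 64), "b3": np.zeros(128),
            "Wf1": _he_uniform(rng, (2048, d), 2048), "bf1": np.zeros(d),
            # Glorot-uniform for the sigmoid output
            "Wf2": rng.uniform(-np.sqrt(6.0 / (d + 1)), np.sqrt(6.0 / (d + 1)), (d, 1)),
            "bf2": np.zeros(1),
        }
        for name, ch in (("bn1", 32), ("bn2", 64), ("bn3", 128)):
            self.params[f"{name}_g"] = np.ones(ch)
            self.params[f"{name}_b"] = np.zeros(ch)
        self.bn_state = {
            name: {"mean": np.zeros(ch), "var": np.ones(ch)}
            for name, ch in (("bn1", 32), ("bn2", 64), ("bn3", 128))
        }

    # -- forward / backward ------------------------------------------------

    @staticmethod
    def _as_images(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 256:
            X = X.reshape(-1, 16, 16)
        if X.ndim == 3:
            X = X[..., None]
        if X.shape[1:] != (16, 16, 1):
            raise ValueError(f"expected (n, 16, 16[, 1]) or (n, 256) input, got {X.shape}")
        return X

    def _forward(self, X, training: bool, drop_rng=None):
        p = self.params
        cache = {}
        a, cache["c1"] = _conv_forward(X, p["W1"], p["b1"])
        a, cache["n1"] = _bn_forward(a, p["bn1_g"], p["bn1_b"], self.bn_state["bn1"], training)
        cache["r1"] = a > 0
        a = a * cache["r1"]
        a, cache["c2"] = _conv_forward(a, p["W2"], p["b2"])
        a, cache["n2"] = _bn_forward(a, p["bn2_g"], p["bn2_b"], self.bn_state["bn2"], training)
        cache["r2"] = a > 0
        a = a * cache["r2"]
        a, cache["p1"] = _maxpool_forward(a)
        a, cache["c3"] = _conv_forward(a, p["W3"], p["b3"])
        a, cache["n3"] = _bn_forward(a, p["bn3_g"], p["bn3_b"], self.bn_state["bn3"], training)
        cache["r3"] = a > 0
        a = a * cache["r3"]
        a, cache["p2"] = _maxpool_forward(a)
        flat = a.reshape(a.shape[0], -1)
        cache["flat_in"] = flat
        h = flat @ p["Wf1"] + p["bf1"]
        cache["rf"] = h > 0
        h = h * cache["rf"]
        if training and self.dropout > 0.0 and drop_rng is not None:
            keep = 1.0 - self.dropout
            cache["drop"] = (drop_rng.uniform(size=h.shape) < keep) / keep
            h = h * cache["drop"]
        else:
            cache["drop"] = None
        cache["h"] = h
        z = (h @ p["Wf2"] + p["bf2"]).ravel()
        prob = expit(z)
        return prob, cache

    def _backward(self, dprob, prob, cache):
        p = self.params
        g = {}
        dz = dprob * prob * (1.0 - prob)
        g["Wf2"] = cache["h"].T @ dz[:, None]
        g["bf2"] = np.array([dz.sum()])
        dh = dz[:, None] @ p["Wf2"].T
        if cache["drop"] is not None:
            dh = dh * cache["drop"]
        dh = dh * cache["rf"]
        g["Wf1"] = cache["flat_in"].T @ dh
        g["bf1"] = dh.sum(axis=0)
        da = (dh @ p["Wf1"].T).reshape(-1, 4, 4, 128)
        da = _maxpool_backward(da, cache["p2"])
        da = da * cache["r3"]
        da, g["bn3_g"], g["bn3_b"] = _bn_backward(da, cache["n3"])
        da, g["W3"], g["b3"] = _conv_backward(da, cache["c3"])
        da = _maxpool_backward(da, cache["p1"])
        da = da * cache["r2"]
        da, g["bn2_g"], g["bn2_b"] = _bn_backward(da, cache["n2"])
        da, g["W2"], g["b2"] = _conv_backward(da, cache["c2"])
        da = da * cache["r1"]
        da, g["bn1_g"], g["bn1_b"] = _bn_backward(da, cache["n1"])
        _, g["W1"], g["b1"] = _conv_backward(da, cache["c1"])
        return g

    def _loss_grad(self, prob, y):
        kw = dict(gamma=self.gamma)
        if self.loss == "focal":
            kw.update(kind="focal", alpha=self.alpha)
        else:
            kw.update(kind="cb_focal", beta=self.beta, n_per_class=self._n_per_class)
        loss, dp = _loss_and_grad_p(prob, y, **kw)
        return float(loss.mean()), dp / prob.size

    # -- training ----------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None, verbose: bool = False):
        X = self._as_images(X)
        y = np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("training set contains a single class")
        self._n_per_class = {0: int((y == 0).sum()), 1: int((y == 1).sum())}
        has_val = X_val is not None and y_val is not None
        if has_val:
            X_val = self._as_images(X_val)
            y_val = np.asarray(y_val, dtype=int)
        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-7
        step = 0
        best_loss, best_params, best_state, wait = np.inf, None, None, 0
        for epoch in range(self.epochs):
            order = self._rng.permutation(len(X))
            ep_loss = 0.0
            for start in range(0, len(X), self.batch_size):
                idx = order[start : start + self.batch_size]
                prob, cache = self._forward(X[idx], training=True, drop_rng=self._rng)
                loss, dp = self._loss_grad(prob, y[idx])
                grads = self._backward(dp, prob, cache)
                step += 1
                for k, gk in grads.items():
                    adam_m[k] = b1 * adam_m[k] + (1 - b1) * gk
                    adam_v[k] = b2 * adam_v[k] + (1 - b2) * gk * gk
                    mh = adam_m[k] / (1 - b1 ** step)
                    vh = adam_v[k] / (1 - b2 ** step)
                    self.params[k] = self.params[k] - self.lr * mh / (np.sqrt(vh) + eps)
                ep_loss += loss * len(idx)
            if has_val:
                vp = self._predict(X_val)
                vloss, _ = self._loss_grad(vp, y_val)
                if verbose:
                    print(f"epoch {epoch}: train {ep_loss / len(X):.4f} val {vloss:.4f}")
                if vloss < best_loss - 1e-6:
                    best_loss, wait = vloss, 0
                    best_params = copy.deepcopy(self.params)
                    best_state = copy.deepcopy(self.bn_state)
                else:
                    wait += 1
                    if wait >= self.patience:
                        break
        if best_params is not None:
            self.params, self.bn_state = best_params, best_state
        return self

    def _predict(self, X_img) -> np.ndarray:
        out = np.empty(len(X_img))
        for start in range(0, len(X_img), 512):
            prob, _ = self._forward(X_img[start : start + 512], training=False)
            out[start : start + len(prob)] = prob
        return out

    def predict_proba(self, X) -> np.ndarray:
        return self._predict(self._as_images(X))

    predict_score = predict_proba

    def activation_shapes(self, X) -> dict[str, tuple]:
        """Shapes of the two block outputs and the flattened layer (sanity check)."""
        X = self._as_images(X)[:1]
        p = self.params
        a, _ = _conv_forward(X, p["W1"], p["b1"])
        a, _ = _bn_forward(a, p["bn1_g"], p["bn1_b"], self.bn_state["bn1"], False)
        a = np.maximum(a, 0.0)
        a, _ = _conv_forward(a, p["W2"], p["b2"])
        a, _ = _bn_forward(a, p["bn2_g"], p["bn2_b"], self.bn_state["bn2"], False)
        a, _ = _maxpool_forward(np.maximum(a, 0.0))
        block1 = a.shape[1:]
        a, _ = _conv_forward(a, p["W3"], p["b3"])
        a, _ = _bn_forward(a, p["bn3_g"], p["bn3_b"], self.bn_state["bn3"], False)
        a, _ = _maxpool_forward(np.maximum(a, 0.0))
        return {"block1": block1, "block2": a.shape[1:],
                "flatten": int(np.prod(a.shape[1:]))}


class CnnModel(Cnn2d):
    """Alias used by the model factory; identical to :class:`Cnn2d`."""


def build_cnn(loss: str = "focal", seed: int = 0, **params) -> Cnn2d:
    """Construct the 2-D CNN with the given loss ('focal' or 'cb_focal')."""
    return Cnn2d(loss=loss, seed=seed, **params)


# ---------------------------------------------------------------------------
# model factory / grids / convenience trainers
# ---------------------------------------------------------------------------

def make_model(kind: str, params: dict | None = None, seed: int = 0,
               probability: bool = False):
    """Instantiate one of the five segment classifiers by name."""
    params = dict(params or {})
    if kind == "svm_linear":
        return SvmModel("linear", probability=probability, seed=seed, **params)
    if kind == "svm_rbf":
        return SvmModel("rbf", probability=probability, seed=seed, **params)
    if kind == "lightgbm":
        return GbmModel(seed=seed, **params)
    if kind == "cnn_focal":
        return Cnn2d(loss="focal", seed=seed, **params)
    if kind == "cnn_cb_focal":
        return Cnn2d(loss="cb_focal", seed=seed, **params)
    raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")


def default_grid(kind: str) -> list[dict]:
    """The hyperparameter grid searched in the inner CV loop, in declared order."""
    if kind == "svm_linear":
        return [{"C": c} for c in SVM_C_GRID]
    if kind == "svm_rbf":
        return [{"C": c, "gamma": g} for c in SVM_C_GRID for g in SVM_GAMMA_GRID]
    if kind == "lightgbm":
        g = LIGHTGBM_GRID
        return [
            {"num_leaves": nl, "max_depth": md, "learning_rate": lr,
             "min_data_in_leaf": mdl}
            for nl in g["num_leaves"]
            for md in g["max_depth"]
            for lr in g["learning_rate"]
            for mdl in g["min_data_in_leaf"]
        ]
    if kind == "cnn_focal":
        return [{"alpha": a, "gamma": g} for a in FOCAL_ALPHA_GRID for g in FOCAL_GAMMA_GRID]
    if kind == "cnn_cb_focal":
        return [{"beta": b, "gamma": g} for b in CB_BETA_GRID for g in FOCAL_GAMMA_GRID]
    raise ValueError(f"unknown model kind {kind!r}")


def _chrono_grid_search(kind, X, y, grid, seed, val_fraction=0.2):
    """Pick grid params by AUC on a chronological tail validation split."""
    from .tsncv import auc

    n = len(X)
    cut = int(round(n * (1.0 - val_fraction)))
    if np.unique(y[:cut]).size < 2 or np.unique(y[cut:]).size < 2:
        raise ValueError("train subset or validation set is single-class")
    best = None
    for params in grid:
        m = make_model(kind, params, seed=seed)
        m.fit(X[:cut], y[:cut], X[cut:], y[cut:])
        a = auc(m.predict_score(X[cut:]), y[cut:])
        if best is None or a > best[0]:
            best = (a, params)
    return best[1]


def train_svm(X, y, kernel: str = "rbf", C_grid=SVM_C_GRID,
              gamma_grid=SVM_GAMMA_GRID, seed: int = 0) -> SvmModel:
    """Grid-search an SVM on a chronological 80/20 split, refit on all rows."""
    kind = "svm_rbf" if kernel == "rbf" else "svm_linear"
    if kind == "svm_rbf":
        grid = [{"C": c, "gamma": g} for c in C_grid for g in gamma_grid]
    else:
        grid = [{"C": c} for c in C_grid]
    params = _chrono_grid_search(kind, np.asarray(X, float), np.asarray(y, int),
                                 grid, seed)
    return make_model(kind, params, seed=seed, probability=True).fit(X, y)


def train_gbm(X, y, grid: dict = LIGHTGBM_GRID, seed: int = 0) -> GbmModel:
    """Grid-search a LightGBM on a chronological 80/20 split, refit on all rows."""
    combos = [
        {"num_leaves": nl, "max_depth": md, "learning_rate": lr,
         "min_data_in_leaf": mdl}
        for nl in grid["num_leaves"]
        for md in grid["max_depth"]
        for lr in grid["learning_rate"]
        for mdl in grid["min_data_in_leaf"]
    ]
    params = _chrono_grid_search("lightgbm", np.asarray(X, float),
                                 np.asarray(y, int), combos, seed)
    return make_model("lightgbm", params, seed=seed).fit(X, y)
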