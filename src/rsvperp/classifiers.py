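"""Classification back ends: RBF-kernel SVM and a compact CNN.

Two detectors for single-trial evoked responses, each trainable in binary
(target / nontarget) or ternary (target / near / far) mode:

* :func:`train_svm` — an RBF support-vector machine on flattened spatially
  filtered features, with the "scale" gamma rule, "balanced" class weights
  (weights inversely proportional to class frequency) and one-against-one
  pairwise voting for the ternary case.  The quadratic-program solver is
  scikit-learn's.

* :class:`CompactCNN` — a small convolutional network of the
  DeepConvNet/EEGNet family operating on raw channels x timepoints epochs:
  a temporal convolution, a spatial convolution collapsing the channel
  axis, one or more conv-pool blocks, and a dense softmax head.  Forward
  pass, backpropagation and the Adam optimiser are implemented here in
  numpy.  Training follows the published schedule: Adam at an initial
  learning rate of 1e-3 decayed by 0.8 every 50 epochs, each epoch drawing
  a class-balanced sample of the training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from ._seeding import derive_seed
from .labeling import balanced_sample

logger = logging.getLogger(__name__)

__all__ = [
    "SvmSpec",
    "CnnSpec",
    "SvmClassifier",
    "CompactCNN",
    "train_svm",
    "build_cnn",
    "train_cnn",
    "predict_target_probability",
    "learning_rate_at",
]


# --------------------------------------------------------------------------
# SVM
# --------------------------------------------------------------------------

@dataclass
class SvmSpec:
    """RBF-SVM configuration; defaults follow the standard RSVP setup."""

    C: float = 1.0
    kernel: str = "rbf"
    gamma: str | float = "scale"        # 1 / (n_features * feature variance)
    class_weight: str | dict | None = "balanced"


class SvmClassifier:
    """Thin wrapper holding the fitted SVC plus label bookkeeping."""

    def __init__(self, svc: SVC):
        self._svc = svc
        self.classes_ = svc.classes_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svc.predict(np.asarray(X, dtype=float))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(np.asarray(X, dtype=float))

    def target_score(self, X: np.ndarray, target_class) -> np.ndarray:
        """Score in [0, 1] for the target class.

        Pairwise surrogate: for every one-against-one machine involving the
        target class, squash the signed margin through a logistic and
        average.  Not a calibrated probability; documented as a surrogate
        (ROC analysis uses the CNN softmax by default).
        """
        classes = list(self.classes_)
        k = len(classes)
        dec = self.decision_function(np.asarray(X, dtype=float))
        if k == 2:
            margins = dec if classes[1] == target_class else -dec
            return 1.0 / (1.0 + np.exp(-margins))
        # column order of ovo decision_function: (0,1), (0,2), ..., (1,2), ...
        ti = classes.index(target_class)
        scores = []
        col = 0
        for i in range(k):
            for j in range(i + 1, k):
                if i == ti:
                    scores.append(1.0 / (1.0 + np.exp(-dec[:, col])))
                elif j == ti:
                    scores.append(1.0 / (1.0 + np.exp(dec[:, col])))
                col += 1
        return np.mean(scores, axis=0)


def train_svm(features: np.ndarray, labels, spec: SvmSpec | None = None,
              seed: int = 0) -> SvmClassifier:
    """Fit the pairwise-voting RBF machine on flattened feature vectors."""
    spec = spec or SvmSpec()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2:
        raise ValueError("features must be 2-D (samples x features)")
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain non-finite values")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes to train")
    svc = SVC(C=spec.C, kernel=spec.kernel, gamma=spec.gamma,
              class_weight=spec.class_weight, decision_function_shape="ovo",
              random_state=seed)
    svc.fit(features, labels)
    return SvmClassifier(svc)


# --------------------------------------------------------------------------
# Compact CNN
# --------------------------------------------------------------------------

@dataclass
class CnnSpec:
    """Architecture and training schedule of the compact CNN.

    The desk-scale defaults (16 channels, small filter banks, 100 training
    epochs on balanced batches of 90) keep a full cross-session run on a
    single CPU fast; :meth:`full_scale` matches the published deployment:
    272-channel input, 25 temporal/spatial filters, 500 epochs, balanced
    batches of 300, Adam at lr 0.001 decayed x0.8 every 50 epochs.
    """

    n_channels: int = 16
    n_times: int = 140
    n_classes: int = 3
    temporal_filters: int = 8
    temporal_kernel: int = 11
    spatial_filters: int = 16
    block_filters: tuple = (32,)
    block_kernel: int = 5
    pool_size: int = 3
    learning_rate: float = 1e-3
    lr_decay: float = 0.8
    lr_step: int = 50
    n_epochs: int = 100
    batch_size: int = 90
    minibatch_size: int = 30

    @classmethod
    def full_scale(cls, n_classes: int = 3) -> "CnnSpec":
        return cls(n_channels=272, n_times=140, n_classes=n_classes,
                   temporal_filters=25, temporal_kernel=10, spatial_filters=25,
                   block_filters=(50, 100), block_kernel=5, pool_size=3,
                   n_epochs=500, batch_size=300, minibatch_size=100)


def learning_rate_at(epoch: int, spec: CnnSpec) -> float:
    """Step-decay schedule: ``lr * decay ** floor(epoch / step)``."""
    return spec.learning_rate * spec.lr_decay ** (epoch // spec.lr_step)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray, fx: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, fx + 1.0)


def _maxpool(x: np.ndarray, p: int):
    """Non-overlapping max pool over the last axis; remainder truncated."""
    t = (x.shape[-1] // p) * p
    xr = x[..., :t].reshape(*x.shape[:-1], t // p, p)
    idx = xr.argmax(axis=-1)
    return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0], idx, t


def _maxpool_grad(dout: np.ndarray, idx: np.ndarray, p: int, t_in: int) -> np.ndarray:
    dxr = np.zeros((*dout.shape, p))
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = np.zeros((*dout.shape[:-1], t_in))
    t = dout.shape[-1] * p
    dx[..., :t] = dxr.reshape(*dout.shape[:-1], t)
    return dx


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding windows of length k over the last axis (valid convolution)."""
    return np.lib.stride_tricks.sliding_window_view(x, k, axis=-1)


def _scatter_windows(dwin: np.ndarray, t_in: int) -> np.ndarray:
    """Adjoint of :func:`_windows`: accumulate window grads back to the signal."""
    k = dwin.shape[-1]
    dx = np.zeros((*dwin.shape[:-2], t_in))
    for j in range(k):
        dx[..., j:j + dwin.shape[-2]] += dwin[..., j]
    return dx


class CompactCNN:
    """Temporal conv -> spatial conv -> conv-pool blocks -> softmax, in numpy."""

    def __init__(self, spec: CnnSpec, seed: int = 0):
        self.spec = spec
        self.trained = False
        self.training_log: list[dict] = []
        self.input_mean = np.zeros((spec.n_channels, 1))
        self.input_std = np.ones((spec.n_channels, 1))
        self.classes_: np.ndarray | None = None
        self._init_params(seed)

    # -- construction ------------------------------------------------------

    def _init_params(self, seed: int) -> None:
        s = self.spec
        if s.n_times < s.temporal_kernel:
            raise ValueError("epoch shorter than the temporal kernel")
        rng = np.random.default_rng(seed)

        def uni(shape, fan_in):
            lim = np.sqrt(1.0 / fan_in)
            return rng.uniform(-lim, lim, size=shape)

        p: dict[str, np.ndarray] = {}
        p["W1"] = uni((s.temporal_filters, s.temporal_kernel), s.temporal_kernel)
        p["b1"] = np.zeros(s.temporal_filters)
        p["W2"] = uni((s.spatial_filters, s.temporal_filters, s.n_channels),
                      s.temporal_filters * s.n_channels)
        p["b2"] = np.zeros(s.spatial_filters)
        t = s.n_times - s.temporal_kernel + 1
        t = t // s.pool_size
        f_in = s.spatial_filters
        for i, f_out in enumerate(s.block_filters):
            if t < s.block_kernel:
                raise ValueError(f"conv block {i}: {t} timepoints < kernel {s.block_kernel}")
            p[f"Wb{i}"] = uni((f_out, f_in, s.block_kernel), f_in * s.block_kernel)
            p[f"bb{i}"] = np.zeros(f_out)
            t = (t - s.block_kernel + 1) // s.pool_size
            if t < 1:
                raise ValueError(f"conv block {i} pools the signal away")
            f_in = f_out
        self._flat_dim = f_in * t
        p["Wd"] = uni((self._flat_dim, s.n_classes), self._flat_dim)
        p["bd"] = np.zeros(s.n_classes)
        self.params = p

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward -----------------------------------------------------------

    def _forward(self, x: np.ndarray, cache: bool = False):
        """x: (batch, channels, times) -> softmax probabilities (batch, k)."""
        s, p = self.spec, self.params
        c: dict = {}
        x = (x - self.input_mean) / self.input_std
        # temporal convolution: (B, C, T) -> (B, F1, C, T1)
        xw = _windows(x, s.temporal_kernel)                       # (B, C, T1, k1)
        h1 = np.einsum("bctk,fk->bfct", xw, p["W1"], optimize=True) + p["b1"][None, :, None, None]
        # spatial convolution collapses the channel axis: -> (B, F2, T1)
        h2 = np.einsum("bfct,gfc->bgt", h1, p["W2"], optimize=True) + p["b2"][None, :, None]
        a2 = _elu(h2)
        pooled, idx2, tcut2 = _maxpool(a2, s.pool_size)
        if cache:
            c.update(x=x, xw=xw, h1=h1, h2=h2, a2=a2, idx2=idx2, tcut2=tcut2)
        h = pooled
        for i in range(len(s.block_filters)):
            win = _windows(h, s.block_kernel)                     # (B, F, T', k)
            hb = np.einsum("bftk,gfk->bgt", win, p[f"Wb{i}"], optimize=True) + p[f"bb{i}"][None, :, None]
            ab = _elu(hb)
            hp, idxb, tcutb = _maxpool(ab, s.pool_size)
            if cache:
                c[f"win{i}"], c[f"hb{i}"], c[f"ab{i}"] = win, hb, ab
                c[f"idx{i}"], c[f"tcut{i}"], c[f"tin{i}"] = idxb, tcutb, h.shape[-1]
            h = hp
        flat = h.reshape(h.shape[0], -1)
        logits = flat @ p["Wd"] + p["bd"]
        logits -= logits.max(axis=1, keepdims=True)
        ex = np.exp(logits)
        probs = ex / ex.sum(axis=1, keepdims=True)
        if cache:
            c["flat"], c["hshape"] = flat, h.shape
            return probs, c
        return probs

    def first_layer_features(self, x: np.ndarray) -> np.ndarray:
        """Spatial-convolution feature maps (batch, spatial_filters, T1).

        The network's first learned feature bank; used for visualisation
        (2-D embedding of per-trial features).
        """
        s, p = self.spec, self.params
        x = (np.asarray(x, dtype=float) - self.input_mean) / self.input_std
        xw = _windows(x, s.temporal_kernel)
        h1 = np.einsum("bctk,fk->bfct", xw, p["W1"], optimize=True) + p["b1"][None, :, None, None]
        return np.einsum("bfct,gfc->bgt", h1, p["W2"], optimize=True) + p["b2"][None, :, None]

    # -- backward ----------------------------------------------------------

    def _backward(self, c: dict, dlogits: np.ndarray) -> dict:
        s, p = self.spec, self.params
        g: dict[str, np.ndarray] = {}
        g["Wd"] = c["flat"].T @ dlogits
        g["bd"] = dlogits.sum(axis=0)
        dh = (dlogits @ p["Wd"].T).reshape(c["hshape"])
        for i in reversed(range(len(s.block_filters))):
            da = _maxpool_grad(dh, c[f"idx{i}"], s.pool_size, c[f"ab{i}"].shape[-1])
            dhb = da * _elu_grad(c[f"hb{i}"], c[f"ab{i}"])
            g[f"Wb{i}"] = np.einsum("bgt,bftk->gfk", dhb, c[f"win{i}"], optimize=True)
            g[f"bb{i}"] = dhb.sum(axis=(0, 2))
            dwin = np.einsum("bgt,gfk->bftk", dhb, p[f"Wb{i}"], optimize=True)
            dh = _scatter_windows(dwin, c[f"tin{i}"])
        da2 = _maxpool_grad(dh, c["idx2"], s.pool_size, c["a2"].shape[-1])
        dh2 = da2 * _elu_grad(c["h2"], c["a2"])
        g["W2"] = np.einsum("bgt,bfct->gfc", dh2, c["h1"], optimize=True)
        g["b2"] = dh2.sum(axis=(0, 2))
        dh1 = np.einsum("bgt,gfc->bfct", dh2, p["W2"], optimize=True)
        g["W1"] = np.einsum("bfct,bctk->fk", dh1, c["xw"], optimize=True)
        g["b1"] = dh1.sum(axis=(0, 2, 3))
        return g

    # -- public API --------------------------------------------------------

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        return self._forward(x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.classes_ is None:
            raise RuntimeError("model is untrained: no class set defined")
        probs = self.predict_proba(x)
        return self.classes_[probs.argmax(axis=1)]


def build_cnn(spec: CnnSpec | None = None, seed: int = 0) -> CompactCNN:
    """Instantiate an untrained compact CNN with seeded initial weights."""
    return CompactCNN(spec or CnnSpec(), seed=seed)


def train_cnn(model: CompactCNN, epochs_data: np.ndarray, labels,
              spec: CnnSpec | None = None, seed: int = 0) -> CompactCNN:
    """Train with Adam under the step-decay schedule on balanced samples.

    Each training epoch draws a class-balanced sample of ``batch_size``
    trials (with replacement only when a class is too small), splits it
    into minibatches and takes one Adam step per minibatch on the
    cross-entropy between the softmax output and one-hot labels.  The
    learning rate at epoch ``e`` is ``lr * decay ** floor(e / step)``.
    Deterministic for a fixed seed on a single thread.
    """
    spec = spec or model.spec
    X = np.asarray(epochs_data, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != spec.n_classes:
        raise ValueError(f"labels have {len(classes)} classes, spec expects {spec.n_classes}")
    model.classes_ = classes
    y_index = np.searchsorted(classes, labels)

    model.input_mean = X.mean(axis=(0, 2), keepdims=True)[0]
    sd = X.std(axis=(0, 2), keepdims=True)[0]
    sd[sd == 0] = 1.0
    model.input_std = sd

    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    model.training_log = []
    for e in range(spec.n_epochs):
        lr = learning_rate_at(e, spec)
        idx = balanced_sample(labels, n_total=spec.batch_size,
                              seed=derive_seed(seed, "batch", e))
        losses = []
        for start in range(0, len(idx), spec.minibatch_size):
            mb = idx[start:start + spec.minibatch_size]
            xb, yb = X[mb], y_index[mb]
            probs, cache = model._forward(xb, cache=True)
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            losses.append(-np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)).mean())
            grads = model._backward(cache, (probs - onehot) / len(yb))
            step += 1
            for k, gk in grads.items():
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * gk
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * gk * gk
                mhat = adam_m[k] / (1 - beta1 ** step)
                vhat = adam_v[k] / (1 - beta2 ** step)
                model.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        model.training_log.append({"epoch": e, "loss": float(np.mean(losses)), "lr": lr})
    model.trained = True
    return model


def predict_target_probability(model, epochs, target_class=None) -> np.ndarray:
    """Per-epoch probability (or surrogate score) of the target class.

    CNN: the softmax entry of the target class.  SVM: the documented
    pairwise-margin surrogate in [0, 1].  ``target_class`` defaults to code
    1 for ternary labels or the string "target" for merged binary labels.
    """
    classes = getattr(model, "classes_", None)
    if classes is None:
        raise RuntimeError("model is untrained")
    classes = list(classes)
    if target_class is None:
        target_class = 1 if 1 in classes else "target"
    if target_class not in classes:
        raise ValueError(f"target class {target_class!r} not among {classes}")
    if isinstance(model, SvmClassifier):
        return model.target_score(epochs, target_class)
    probs = model.predict_proba(epochs)
    return probs[:, classes.index(target_class)]
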