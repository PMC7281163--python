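"""Shallow CNN binary classifier for paired-trapping change images.

The network is deliberately small — three 3x3 convolutional layers each
followed by 2x2 max-pooling, a flatten, one hidden fully connected layer
with dropout 0.5, and a single sigmoid output — because the deformation
signal in the change encoding is strong and a deep backbone would only
invite overfitting on cohorts of a few dozen cells.  All hidden layers use
the rectified linear unit.

Layers, backpropagation, binary cross-entropy and the five first-order
optimizers (SGD, RMSprop, Adagrad, Adadelta, Adam) are implemented directly
on NumPy: convolutions run as im2col patch extraction followed by a BLAS
matrix product, in float32.  Gradient correctness is established against
numerical differentiation in the test suite.

The public surface is :class:`ShallowCNNClassifier`, a scikit-learn
estimator (``fit`` / ``predict`` / ``predict_proba`` / ``get_params``) that
composes with sklearn model selection.  The decision rule is the study's:
predict invasive (1) iff the sigmoid output strictly exceeds 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "weighted_summation",
    "bce_loss",
    "ModelConfig",
    "TrainConfig",
    "ShallowCNNClassifier",
    "build_model",
    "train",
    "classify",
]

_EPS = 1e-7  # probability clip for the loss


# ---------------------------------------------------------------------------
# primitives


def weighted_summation(patch: np.ndarray, filt: np.ndarray) -> float:
    """Element-wise weighted sum of an image patch with a filter.

    This is the primitive a convolutional filter evaluates at every stride
    position; e.g. a horizontal-edge filter contrasts the top row against
    the bottom row of its receptive field.
    """
    patch = np.asarray(patch, dtype=np.float64)
    filt = np.asarray(filt, dtype=np.float64)
    if patch.shape != filt.shape:
        raise ValueError(f"shape mismatch: patch {patch.shape} vs filter {filt.shape}")
    return float(np.sum(patch * filt))


def bce_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Binary cross-entropy, mean over samples.

    Predictions are clipped away from {0, 1}; the loss is 0 exactly when
    every (clipped) prediction equals its label.
    """
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal lengths")
    p = np.clip(y_pred, _EPS, 1.0 - _EPS)
    return float(-np.mean(y_true * np.log(p) + (1.0 - y_true) * np.log(1.0 - p)))


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# layers (NHWC, float32)


def _conv_forward(x, w, b, stride=1):
    """Same-padded conv. x: (N,H,W,Cin); w: (k,k,Cin,Cout); returns y, cache."""
    n, h, wd, cin = x.shape
    k = w.shape[0]
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    windows = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H',W',Cin,k,k)
    windows = windows[:, ::stride, ::stride]
    oh, ow = windows.shape[1], windows.shape[2]
    cols = windows.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, k * k * cin)
    wmat = w.reshape(k * k * cin, -1)
    y = cols @ wmat + b
    y = y.reshape(n, oh, ow, -1)
    return y, (cols, x.shape, pad, stride)


def _conv_backward(dy, w, cache):
    cols, xshape, pad, stride = cache
    n, h, wd, cin = xshape
    k = w.shape[0]
    cout = w.shape[3]
    oh, ow = dy.shape[1], dy.shape[2]
    dymat = dy.reshape(n * oh * ow, cout)
    dwmat = cols.T @ dymat
    dw = dwmat.reshape(k, k, cin, cout)
    db = dymat.sum(axis=0)
    # scatter gradients back through the patch extraction
    dxp = np.zeros((n, h + 2 * pad, wd + 2 * pad, cin), dtype=dy.dtype)
    dcols = (dymat @ w.reshape(-1, cout).T).reshape(n, oh, ow, k, k, cin)
    for ki in range(k):
        for kj in range(k):
            dxp[:, ki : ki + oh * stride : stride, kj : kj + ow * stride : stride] += (
                dcols[:, :, :, ki, kj, :]
            )
    dx = dxp[:, pad : pad + h, pad : pad + wd]
    return dx, dw, db


def _pool_forward(x, size=2):
    n, h, w, c = x.shape
    oh, ow = h // size, w // size
    xr = x[:, : oh * size, : ow * size].reshape(n, oh, size, ow, size, c)
    y = xr.max(axis=(2, 4))
    return y, (x.shape, size, xr, y)


def _pool_backward(dy, cache):
    xshape, size, xr, y = cache
    n, h, w, c = xshape
    oh, ow = y.shape[1], y.shape[2]
    # route the gradient to every element attaining the max (ties split)
    mask = xr == y[:, :, None, :, None, :]
    counts = mask.sum(axis=(2, 4), keepdims=True)
    dxr = mask * (dy[:, :, None, :, None, :] / counts)
    dx = np.zeros(xshape, dtype=dy.dtype)
    dx[:, : oh * size, : ow * size] = dxr.reshape(n, oh * size, ow * size, c)
    return dx


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    Exactly three conv layers (the first 32 filters wide), each followed by
    2x2 max-pooling, then two fully connected layers with dropout 0.5 after
    the first; the output is one sigmoid unit.
    """

    input_size: tuple[int, int, int] = (128, 128, 3)
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    kernel_size: tuple[int, int] = (3, 3)
    stride: int = 1
    pool_size: tuple[int, int] = (2, 2)
    fc_width: int = 128
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3:
            raise ValueError("exactly 3 convolutional layers")
        h, w, c = self.input_size
        p = self.pool_size[0]
        if h // p**3 < 1 or w // p**3 < 1:
            raise ValueError("input too small for three pooling halvings")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


_OPTIMIZERS = ("sgd", "rmsprop", "adagrad", "adadelta", "adam")


@dataclass(frozen=True)
class TrainConfig:
    """Training-loop hyper-parameters (optimizer, rho, beta, epsilon-epochs).

    Adadelta rescales its own step from accumulated statistics and is run
    with the recommended initial learning rate of 1.00; any other value is
    coerced with a warning.
    """

    optimizer: str = "adadelta"
    learning_rate: float = 1.0
    batch_size: int = 16
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer.lower() not in _OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {_OPTIMIZERS}")
        object.__setattr__(self, "optimizer", self.optimizer.lower())
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.optimizer == "adadelta" and self.learning_rate != 1.0:
            warnings.warn("Adadelta runs with learning rate 1.00; coercing")
            object.__setattr__(self, "learning_rate", 1.0)


# ---------------------------------------------------------------------------
# optimizers (canonical defaults from the original papers)


class _Optimizer:
    def __init__(self, lr: float):
        self.lr = lr
        self.state: dict = {}

    def update(self, params: dict, grads: dict) -> None:
        raise NotImplementedError


class _SGD(_Optimizer):
    def update(self, params, grads):
        for k in params:
            params[k] -= self.lr * grads[k]


class _RMSprop(_Optimizer):
    rho, eps = 0.9, 1e-8

    def update(self, params, grads):
        for k in params:
            acc = self.state.setdefault(k, np.zeros_like(params[k]))
            acc *= self.rho
            acc += (1 - self.rho) * grads[k] ** 2
            params[k] -= self.lr * grads[k] / (np.sqrt(acc) + self.eps)


class _Adagrad(_Optimizer):
    eps = 1e-8

    def update(self, params, grads):
        for k in params:
            acc = self.state.setdefault(k, np.zeros_like(params[k]))
            acc += grads[k] ** 2
            params[k] -= self.lr * grads[k] / (np.sqrt(acc) + self.eps)


class _Adadelta(_Optimizer):
    rho, eps = 0.95, 1e-6

    def update(self, params, grads):
        for k in params:
            st = self.state.setdefault(
                k, (np.zeros_like(params[k]), np.zeros_like(params[k]))
            )
            eg, ex = st
            eg *= self.rho
            eg += (1 - self.rho) * grads[k] ** 2
            step = -np.sqrt(ex + self.eps) / np.sqrt(eg + self.eps) * grads[k]
            ex *= self.rho
            ex += (1 - self.rho) * step**2
            params[k] += self.lr * step


class _Adam(_Optimizer):
    b1, b2, eps = 0.9, 0.999, 1e-8

    def __init__(self, lr):
        super().__init__(lr)
        self.t = 0

    def update(self, params, grads):
        self.t += 1
        for k in params:
            st = self.state.setdefault(
                k, (np.zeros_like(params[k]), np.zeros_like(params[k]))
            )
            m, v = st
            m *= self.b1
            m += (1 - self.b1) * grads[k]
            v *= self.b2
            v += (1 - self.b2) * grads[k] ** 2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _make_optimizer(name: str, lr: float) -> _Optimizer:
    return {
        "sgd": _SGD,
        "rmsprop": _RMSprop,
        "adagrad": _Adagrad,
        "adadelta": _Adadelta,
        "adam": _Adam,
    }[name](lr)


# ---------------------------------------------------------------------------
# estimator


class ShallowCNNClassifier(BaseEstimator, ClassifierMixin):
    """Three-conv-layer binary classifier with a sigmoid output.

    Parameters
    ----------
    conv_filters : tuple of 3 ints
        Filter counts of the convolutional layers (first fixed at 32 in the
        study's architecture; configurable here).
    fc_width : int
        Width of the hidden fully connected layer.
    dropout_rate : float
        Dropout probability after the hidden FC layer (training only).
    optimizer : {'sgd', 'rmsprop', 'adagrad', 'adadelta', 'adam'}
    learning_rate : float
        Initial learning rate rho; forced to 1.0 for Adadelta.
    batch_size : int
        Weights are updated once per ``batch_size`` samples.
    epochs : int
        Number of passes over the training set.
    early_stop_train_loss : float or None
        If set, training stops after the first epoch whose mean training
        loss falls at or below this value (a convergence criterion; the
        epoch cap still applies).
    seed : int
        Seeds weight initialisation, shuffling and dropout; runs are
        bit-reproducible under single-threaded execution.

    Attributes
    ----------
    params_ : dict of arrays
        Fitted weights and biases.
    history_ : dict of lists
        Per-epoch ``train_loss``, ``train_acc`` and, when validation data
        is passed to ``fit``, ``val_loss`` and ``val_acc``.
    classes_ : ndarray
        Always ``[0, 1]`` (0 = non-invasive, 1 = invasive).
    """

    def __init__(
        self,
        conv_filters=(32, 64, 128),
        kernel_size=3,
        stride=1,
        pool_size=2,
        fc_width=128,
        dropout_rate=0.5,
        optimizer="adadelta",
        learning_rate=1.0,
        batch_size=16,
        epochs=30,
        early_stop_train_loss=None,
        seed=0,
    ):
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.stride = stride
        self.pool_size = pool_size
        self.fc_width = fc_width
        self.dropout_rate = dropout_rate
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.early_stop_train_loss = early_stop_train_loss
        self.seed = seed

    # -- construction ------------------------------------------------------

    def _validate_arch(self, input_hw):
        ModelConfig(
            input_size=(*input_hw, 3),
            conv_filters=tuple(self.conv_filters),
            kernel_size=(self.kernel_size, self.kernel_size),
            stride=self.stride,
            pool_size=(self.pool_size, self.pool_size),
            fc_width=self.fc_width,
            dropout_rate=self.dropout_rate,
        )
        if self.stride != 1:
            raise NotImplementedError("only stride 1 convolutions are supported")

    def _init_params(self, input_hw, rng) -> dict:
        h, w = input_hw
        k = self.kernel_size
        params = {}
        cin = 3
        for i, cout in enumerate(self.conv_filters):
            fan_in = k * k * cin
            params[f"w{i}"] = (
                rng.standard_normal((k, k, cin, cout)) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            params[f"b{i}"] = np.zeros(cout, dtype=np.float32)
            cin = cout
            h //= self.pool_size
            w //= self.pool_size
        flat = h * w * cin
        params["wf1"] = (
            rng.standard_normal((flat, self.fc_width)) * np.sqrt(2.0 / flat)
        ).astype(np.float32)
        params["bf1"] = np.zeros(self.fc_width, dtype=np.float32)
        params["wf2"] = (
            rng.standard_normal((self.fc_width, 1)) * np.sqrt(1.0 / self.fc_width)
        ).astype(np.float32)
        params["bf2"] = np.zeros(1, dtype=np.float32)
        return params

    def n_parameters(self) -> int:
        check_is_fitted(self, "params_")
        return int(sum(p.size for p in self.params_.values()))

    # -- forward / backward ------------------------------------------------

    def _forward(self, x, params, train_mode=False, rng=None):
        caches = []
        a = x
        for i in range(3):
            z, cc = _conv_forward(a, params[f"w{i}"], params[f"b{i}"])
            r = _relu(z)
            p, pc = _pool_forward(r, self.pool_size)
            caches.append((cc, z, pc))
            a = p
        flat_shape = a.shape
        a = a.reshape(a.shape[0], -1)
        z1 = a @ params["wf1"] + params["bf1"]
        h1 = _relu(z1)
        if train_mode and self.dropout_rate > 0:
            mask = (
                rng.random(h1.shape) >= self.dropout_rate
            ).astype(np.float32) / (1.0 - self.dropout_rate)
            h1d = h1 * mask
        else:
            mask = None
            h1d = h1
        z2 = h1d @ params["wf2"] + params["bf2"]
        prob = _sigmoid(z2).ravel()
        cache = (caches, flat_shape, a, z1, h1, mask, h1d)
        return prob, cache

    def _backward(self, prob, y, params, cache):
        caches, flat_shape, a, z1, h1, mask, h1d = cache
        n = len(y)
        grads = {}
        # d BCE / d z2 for sigmoid output
        dz2 = ((prob - y) / n).astype(h1d.dtype)[:, None]
        grads["wf2"] = h1d.T @ dz2
        grads["bf2"] = dz2.sum(axis=0)
        dh1d = dz2 @ params["wf2"].T
        if mask is not None:
            dh1d = dh1d * mask
        dz1 = dh1d * (z1 > 0)
        grads["wf1"] = a.T @ dz1
        grads["bf1"] = dz1.sum(axis=0)
        da = (dz1 @ params["wf1"].T).reshape(flat_shape)
        for i in reversed(range(3)):
            cc, z, pc = caches[i]
            dr = _pool_backward(da, pc)
            dz = dr * (z > 0)
            da, dw, db = _conv_backward(dz, params[f"w{i}"], cc)
            grads[f"w{i}"] = dw
            grads[f"b{i}"] = db
        return grads

    # -- sklearn API -------------------------------------------------------

    @staticmethod
    def _as_float(X):
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must have shape (n, H, W, 3)")
        return X.astype(np.float32) / 255.0 if X.dtype == np.uint8 else X.astype(
            np.float32
        )

    def fit(self, X, y, validation_data=None):
        """Train on images ``X`` (n, H, W, 3) with binary labels ``y``.

        ``validation_data=(X_val, y_val)`` adds per-epoch validation loss
        and accuracy to ``history_`` without influencing training.
        """
        X = self._as_float(X)
        y = np.asarray(y, dtype=np.float32).ravel()
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if not np.isin(y, [0.0, 1.0]).all():
            raise ValueError("labels must be coded 0/1")
        TrainConfig(
            optimizer=self.optimizer,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=self.seed,
        )
        self._validate_arch(X.shape[1:3])
        rng = np.random.default_rng(self.seed)
        self.input_hw_ = X.shape[1:3]
        self.params_ = self._init_params(self.input_hw_, rng)
        self.classes_ = np.array([0, 1])
        lr = 1.0 if self.optimizer == "adadelta" else self.learning_rate
        opt = _make_optimizer(self.optimizer, lr)
        hist: dict[str, list] = {"epoch": [], "train_loss": [], "train_acc": []}
        if validation_data is not None:
            hist["val_loss"] = []
            hist["val_acc"] = []
        n = len(X)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses, hits = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y[idx]
                prob, cache = self._forward(
                    xb, self.params_, train_mode=True, rng=rng
                )
                losses += bce_loss(yb, prob) * len(idx)
                hits += int(((prob > 0.5) == (yb == 1)).sum())
                grads = self._backward(prob, yb, self.params_, cache)
                opt.update(self.params_, grads)
            hist["epoch"].append(epoch)
            hist["train_loss"].append(losses / n)
            hist["train_acc"].append(hits / n)
            if validation_data is not None:
                pv = self._predict_proba_fitted(self._as_float(validation_data[0]))
                yv = np.asarray(validation_data[1], dtype=np.float32).ravel()
                hist["val_loss"].append(bce_loss(yv, pv))
                hist["val_acc"].append(float(np.mean((pv > 0.5) == (yv == 1))))
            if (
                self.early_stop_train_loss is not None
                and hist["train_loss"][-1] <= self.early_stop_train_loss
            ):
                break
        self.history_ = hist
        self.n_epochs_run_ = len(hist["epoch"])
        return self

    def _predict_proba_fitted(self, X, batch=64):
        out = np.empty(len(X), dtype=np.float64)
        for start in range(0, len(X), batch):
            prob, _ = self._forward(X[start : start + batch], self.params_)
            out[start : start + batch] = prob
        return out

    def predict_proba(self, X):
        """Per-image probability of each class, columns [P(0), P(1)]."""
        check_is_fitted(self, "params_")
        p1 = self._predict_proba_fitted(self._as_float(X))
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        """Invasive (1) iff the sigmoid score strictly exceeds 0.5."""
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y).ravel()))

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Write weights (.npz) plus a sidecar JSON of the configuration."""
        import json
        from pathlib import Path

        check_is_fitted(self, "params_")
        path = Path(path)
        np.savez(path, **self.params_)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"params": self.get_params(), "input_hw": list(self.input_hw_)},
                indent=2,
                default=list,
            )
        )

    @classmethod
    def load(cls, path) -> "ShallowCNNClassifier":
        import json
        from pathlib import Path

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        init = meta["params"]
        for key in ("conv_filters",):
            if isinstance(init.get(key), list):
                init[key] = tuple(init[key])
        clf = cls(**init)
        with np.load(path.with_suffix(".npz")) as data:
            clf.params_ = {k: data[k] for k in data.files}
        clf.input_hw_ = tuple(meta["input_hw"])
        clf.classes_ = np.array([0, 1])
        return clf


# ---------------------------------------------------------------------------
# thin functional wrappers


def build_model(
    model_config: ModelConfig, train_config: TrainConfig | None = None, seed: int = 0
) -> ShallowCNNClassifier:
    """Instantiate an (unfitted) classifier from explicit configs."""
    tc = train_config or TrainConfig(seed=seed)
    return ShallowCNNClassifier(
        conv_filters=tuple(model_config.conv_filters),
        kernel_size=model_config.kernel_size[0],
        stride=model_config.stride,
        pool_size=model_config.pool_size[0],
        fc_width=model_config.fc_width,
        dropout_rate=model_config.dropout_rate,
        optimizer=tc.optimizer,
        learning_rate=tc.learning_rate,
        batch_size=tc.batch_size,
        epochs=tc.epochs,
        seed=tc.seed,
    )


def train(model: ShallowCNNClassifier, X, y, validation_data=None):
    """Fit ``model`` in place and return (model, history dict)."""
    model.fit(X, y, validation_data=validation_data)
    return model, model.history_


def classify(model: ShallowCNNClassifier, image: np.ndarray) -> tuple[int, float]:
    """Classify one combined image; returns (class, sigmoid score)."""
    score = float(model.predict_proba(image[None])[:, 1][0])
    return (1 if score > 0.5 else 0), score
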