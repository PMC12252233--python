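"""A small convolutional classifier for two-class radiograph phantoms.

Self-contained numpy implementation (forward and backward passes, Adam,
batch normalization, dropout, early stopping) of a three-block CNN:

    conv 3x3/32 -> ReLU -> maxpool 2x2
    conv 3x3/64 -> BN -> ReLU -> maxpool 2x2
    conv 3x3/128 -> BN -> ReLU -> maxpool 2x2
    flatten -> dense 128 -> ReLU -> dropout -> dense K -> softmax

All convolutions use stride 1 with same padding; inputs are single-channel
images normalized to [0, 1]. Training minimizes categorical cross-entropy
with Adam (default learning rate 1e-3, batch size 32, at most 50 epochs)
and stops early when the validation loss has not improved for ``patience``
consecutive epochs, restoring the best-validation weights. Gradients are
clipped to a global norm (default 1.0) and the classifier head starts with
near-zero weights; both guard the small-batch float32 training against the
transient logit blow-ups that otherwise kill the ReLU trunk.

The input side length is configurable so smoke-scale experiments can run at
64 x 64 instead of the full 224 x 224; the architecture is otherwise fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .image import GrayImage

__all__ = [
    "CnnConfig",
    "TrainConfig",
    "TrainHistory",
    "SmallCNN",
    "EarlyStopping",
    "build_model",
    "train",
    "predict",
    "images_to_arrays",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CnnConfig:
    """Architecture hyperparameters (kernel 3x3, stride 1, pool 2x2 fixed)."""

    input_size: tuple[int, int] = (224, 224)
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    dense_units: int = 128
    dropout_rate: float = 0.5
    n_classes: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must lie in [0, 1), got {self.dropout_rate}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        h, w = self.input_size
        if h % 8 != 0 or w % 8 != 0 or h < 8 or w < 8:
            raise ValueError(
                f"input_size {self.input_size} must be a multiple of 8 in each "
                "dimension to survive three 2x2 poolings"
            )

    @property
    def flatten_length(self) -> int:
        h, w = self.input_size
        return self.conv_filters[2] * (h // 8) * (w // 8)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 10
    clip_grad_norm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("learning_rate, batch_size, max_epochs, patience must be > 0")


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0.0, scale, size=(c_in * 9, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        view = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # (b, c, h, w, 3, 3) -> (b*h*w, c*9)
        return view.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * 9)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, h, w = x.shape
        cols = np.ascontiguousarray(self._im2col(x))
        out = cols @ self.w + self.b
        if training:
            self._cache = (cols, x.shape)
        out = out.reshape(b, h, w, -1).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray):
        cols, (b, c, h, w) = self._cache
        dflat = dout.transpose(0, 2, 3, 1).reshape(b * h * w, -1)
        dw = cols.T @ dflat
        db = dflat.sum(axis=0)
        dcols = dflat @ self.w.T  # (b*h*w, c*9)
        dview = dcols.reshape(b, h, w, c, 3, 3)
        dxp = np.zeros((b, c, h + 2, w + 2), dtype=np.float32)
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di : di + h, dj : dj + w] += dview[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        dx = dxp[:, :, 1 : 1 + h, 1 : 1 + w]
        return dx, [dw.astype(np.float32), db.astype(np.float32)]


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray):
        return dout * self._mask, []


class _MaxPool2:
    params: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if training:
            self._cache = (xr, out)
        return out

    def backward(self, dout: np.ndarray):
        xr, out = self._cache
        mask = xr == out[:, :, :, None, :, None]
        dx = mask * dout[:, :, :, None, :, None]
        b, c, h2, _, w2, _ = xr.shape
        return dx.reshape(b, c, h2 * 2, w2 * 2), []


class _BatchNorm2d:
    """Per-channel batch normalization over (batch, height, width)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        mean_b = mean[None, :, None, None]
        std_b = np.sqrt(var + self.eps)[None, :, None, None]
        xhat = (x - mean_b) / std_b
        if training:
            self._cache = (xhat, std_b)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray):
        xhat, std_b = self._cache
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / std_b
        return dx, [dgamma.astype(np.float32), dbeta.astype(np.float32)]


class _Flatten:
    params: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray):
        return dout.reshape(self._shape), []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 w_scale: float | None = None):
        scale = np.sqrt(2.0 / n_in) if w_scale is None else w_scale
        self.w = rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray):
        dw = self._x.T @ dout
        db = dout.sum(axis=0)
        return dout @ self.w.T, [dw.astype(np.float32), db.astype(np.float32)]


class _Dropout:
    """Inverted dropout; identity in eval mode (deterministic inference)."""

    params: list = []

    def __init__(self, rate: float):
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.uniform(size=x.shape) < keep) / keep
        return x * self._mask.astype(np.float32)

    def backward(self, dout: np.ndarray):
        if self.rate == 0.0:
            return dout, []
        return dout * self._mask.astype(np.float32), []


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

class SmallCNN:
    """Three-conv-block classifier; see module docstring for the layout."""

    def __init__(self, cfg: CnnConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f1, f2, f3 = cfg.conv_filters
        self.conv1 = _Conv3x3(1, f1, rng)
        self.conv2 = _Conv3x3(f1, f2, rng)
        self.bn2 = _BatchNorm2d(f2)
        self.conv3 = _Conv3x3(f2, f3, rng)
        self.bn3 = _BatchNorm2d(f3)
        self.dense1 = _Dense(cfg.flatten_length, cfg.dense_units, rng)
        self.dropout = _Dropout(cfg.dropout_rate)
        # small classifier-head init keeps initial logits near zero so the
        # first optimizer steps cannot blow up the softmax
        self.dense2 = _Dense(cfg.dense_units, cfg.n_classes, rng, w_scale=0.01)
        self.layers = [
            self.conv1, _ReLU(), _MaxPool2(),
            self.conv2, self.bn2, _ReLU(), _MaxPool2(),
            self.conv3, self.bn3, _ReLU(), _MaxPool2(),
            _Flatten(), self.dense1, _ReLU(), self.dropout, self.dense2,
        ]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch of shape (n, 1, rows, cols) in [0, 1]."""
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2:] != self.cfg.input_size:
            raise ValueError(
                f"expected input of shape (n, 1, {self.cfg.input_size[0]}, "
                f"{self.cfg.input_size[1]}), got {x.shape}"
            )
        out = x.astype(np.float32)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self.forward(x, training=False))

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        grads: list[np.ndarray] = []
        dout = dlogits
        for layer in reversed(self.layers):
            dout, g = layer.backward(dout)
            grads = g + grads
        return grads

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def set_params(self, values: Sequence[np.ndarray]) -> None:
        for p, v in zip(self.params, values, strict=True):
            p[...] = v

    def snapshot(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params] + [
            self.bn2.running_mean.copy(), self.bn2.running_var.copy(),
            self.bn3.running_mean.copy(), self.bn3.running_var.copy(),
        ]

    def restore(self, snap: Sequence[np.ndarray]) -> None:
        n = len(self.params)
        self.set_params(snap[:n])
        self.bn2.running_mean, self.bn2.running_var = snap[n].copy(), snap[n + 1].copy()
        self.bn3.running_mean, self.bn3.running_var = snap[n + 2].copy(), snap[n + 3].copy()


def build_model(cfg: CnnConfig, seed: int = 0) -> SmallCNN:
    """Construct the classifier with seeded He-initialized weights."""
    return SmallCNN(cfg, seed=seed)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

class EarlyStopping:
    """Stop when the monitored loss has not improved for ``patience`` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.wait = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record this epoch's loss; return True when training should stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v, strict=True):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p[...] = p - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def cross_entropy(probs: np.ndarray, y_onehot: np.ndarray) -> float:
    """Mean categorical cross-entropy -1/N sum_i sum_j y_ij log p_ij."""
    p = np.clip(probs, 1e-12, 1.0)
    return float(-(y_onehot * np.log(p)).sum() / probs.shape[0])


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((labels.size, k), dtype=np.float32)
    out[np.arange(labels.size), labels.astype(int)] = 1.0
    return out


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def train(
    model: SmallCNN,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray] | None,
    cfg: TrainConfig,
    val_loss_fn: Callable[[int], float] | None = None,
) -> TrainHistory:
    """Fit with Adam + early stopping; returns per-epoch loss history.

    ``val_loss_fn(epoch) -> loss`` overrides the validation-loss computation
    (used for custom validation schemes and for testing the stopping rule);
    by default the loss is evaluated on ``val_set`` in inference mode.
    The best-validation weights are restored before returning.
    """
    x_train, y_train = train_set
    if x_train.shape[0] == 0:
        raise ValueError("training set is empty")
    if val_set is None and val_loss_fn is None:
        raise ValueError("either a validation set or val_loss_fn is required")
    if val_set is not None and val_set[0].shape[0] == 0:
        raise ValueError("validation set is empty")
    k = model.cfg.n_classes
    y_onehot = _one_hot(np.asarray(y_train), k)
    rng = np.random.default_rng(cfg.seed)
    model.dropout.rng = np.random.default_rng(cfg.seed + 1)
    optimizer = _Adam(model.params, cfg.learning_rate)
    stopper = EarlyStopping(cfg.patience)
    history = TrainHistory()
    best_snap = model.snapshot()
    n = x_train.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_onehot[idx]
            logits = model.forward(xb, training=True)
            probs = _softmax(logits)
            epoch_loss += cross_entropy(probs, yb) * idx.size
            dlogits = (probs - yb) / idx.size
            grads = model.backward(dlogits)
            if cfg.clip_grad_norm > 0:
                gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads))
                if gnorm > cfg.clip_grad_norm:
                    grads = [g * (cfg.clip_grad_norm / gnorm) for g in grads]
            optimizer.step(model.params, grads)
        history.train_loss.append(epoch_loss / n)
        if val_loss_fn is not None:
            vloss = float(val_loss_fn(epoch))
        else:
            x_val, y_val = val_set
            vprobs = model.predict_proba(x_val)
            vloss = cross_entropy(vprobs, _one_hot(np.asarray(y_val), k))
        history.val_loss.append(vloss)
        improved = vloss < stopper.best
        stop = stopper.update(vloss, epoch)
        if improved:
            best_snap = model.snapshot()
        if stop:
            break
    history.stopped_epoch = len(history.val_loss)
    history.best_epoch = stopper.best_epoch
    model.restore(best_snap)
    return history


def predict(model: SmallCNN, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (ties resolve to class 0)."""
    probs = model.predict_proba(x)
    return probs, probs.argmax(axis=1)


def images_to_arrays(
    dataset: Sequence[tuple], size: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack (GrayImage, label) pairs into (n, 1, rows, cols) in [0, 1]."""
    from .image import resize_image

    xs, ys = [], []
    for item in dataset:
        img: GrayImage = item[0]
        if size is not None and img.shape != tuple(size):
            img = resize_image(img, size)
        xs.append(img.astype_float() / (img.levels - 1))
        ys.append(int(item[1]))
    return np.asarray(xs, dtype=np.float32)[:, None, :, :], np.asarray(ys, dtype=np.int64)


def save_model(model: SmallCNN, path: str | Path) -> None:
    """Persist weights + config as a compressed npz."""
    cfg = model.cfg
    arrays = {f"p{i}": p for i, p in enumerate(model.snapshot())}
    np.savez_compressed(
        path,
        input_rows=cfg.input_size[0], input_cols=cfg.input_size[1],
        f1=cfg.conv_filters[0], f2=cfg.conv_filters[1], f3=cfg.conv_filters[2],
        dense_units=cfg.dense_units, dropout_rate=cfg.dropout_rate,
        n_classes=cfg.n_classes, **arrays,
    )


def load_model(path: str | Path) -> SmallCNN:
    data = np.load(path)
    cfg = CnnConfig(
        input_size=(int(data["input_rows"]), int(data["input_cols"])),
        conv_filters=(int(data["f1"]), int(data["f2"]), int(data["f3"])),
        dense_units=int(data["dense_units"]),
        dropout_rate=float(data["dropout_rate"]),
        n_classes=int(data["n_classes"]),
    )
    model = SmallCNN(cfg)
    snap = [data[f"p{i}"] for i in range(len(model.snapshot()))]
    model.restore(snap)
    return model
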