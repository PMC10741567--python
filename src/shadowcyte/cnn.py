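"""A compact AlexNet-style CNN with SELU activations, in pure NumPy.

The classifier takes 50x50 single-channel shadow crops through eight 3x3
convolutions (padding 1) with max pooling after convs 1, 2, 4, 6 and 8
(spatial trace 50 -> 25 -> 12 -> 6 -> 3 -> 1) and three fully connected
layers ending in 2 class logits. Every hidden layer uses the scaled
exponential linear unit

    selu(x) = lambda * x                      for x >= 0
    selu(x) = lambda * alpha * (exp(x) - 1)   for x <  0

with lambda = 1.0507 and alpha = 1.6732, the self-normalizing constants.
Training is minibatch Adam on softmax cross-entropy with best-epoch
checkpointing by validation accuracy. Gradients are computed by manual
backpropagation (im2col convolutions), which also powers Grad-CAM.

Class index convention: 0 = RESIDUAL, 1 = CD34_POS (the positive class).
"""

from __future__ import annotations

import copy
import logging
import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

SELU_LAMBDA = 1.0507
SELU_ALPHA = 1.6732

__all__ = [
    "SELU_LAMBDA",
    "SELU_ALPHA",
    "selu",
    "ArchitectureSpec",
    "TrainConfig",
    "EvalReport",
    "Model",
    "build_model",
    "pooling_trace",
    "train",
    "evaluate",
    "gradcam",
    "save_model",
    "load_model",
]


def selu(x):
    """Scaled exponential linear unit, elementwise."""
    x = np.asarray(x, dtype=np.float64)
    out = np.where(
        x >= 0, SELU_LAMBDA * x, SELU_LAMBDA * SELU_ALPHA * (np.expm1(np.minimum(x, 0)))
    )
    return out if out.ndim else float(out)


def _selu_f32(x: np.ndarray) -> np.ndarray:
    return np.where(
        x >= 0, np.float32(SELU_LAMBDA) * x,
        np.float32(SELU_LAMBDA * SELU_ALPHA) * np.expm1(np.minimum(x, 0)),
    ).astype(np.float32)


def _selu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(
        x >= 0, np.float32(SELU_LAMBDA),
        np.float32(SELU_LAMBDA * SELU_ALPHA) * np.exp(np.minimum(x, 0)),
    ).astype(np.float32)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer plan: 8 convs, pools after {1,2,4,6,8}, 3 FC layers, 2 classes."""

    n_conv: int = 8
    pool_after: tuple[int, ...] = (1, 2, 4, 6, 8)
    conv_channels: tuple[int, ...] = (32, 32, 64, 64, 128, 128, 256, 256)
    fc_widths: tuple[int, ...] = (512, 128, 2)
    input_size: int = 50
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.n_conv != len(self.conv_channels):
            raise ValueError("conv_channels length must equal n_conv")
        if self.n_conv != 8:
            raise ValueError(f"architecture requires exactly 8 conv layers, got {self.n_conv}")
        if tuple(sorted(self.pool_after)) != (1, 2, 4, 6, 8):
            raise ValueError(f"pooling must follow convs 1,2,4,6,8, got {self.pool_after}")
        if len(self.fc_widths) != 3:
            raise ValueError(f"exactly 3 fully connected layers required, got {len(self.fc_widths)}")
        if self.fc_widths[-1] != 2:
            raise ValueError(f"final layer width must be 2 classes, got {self.fc_widths[-1]}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the published training recipe."""

    batch_size: int = 16
    learning_rate: float = 5e-4
    epochs: int = 500
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass(frozen=True)
class EvalReport:
    """Binary confusion counts and derived metrics; CD34_POS is positive."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def pooling_trace(input_size: int = 50, n_pools: int = 5) -> list[int]:
    """Spatial sizes after each 2x2/stride-2 pool (floor division)."""
    sizes, n = [], input_size
    for _ in range(n_pools):
        n //= 2
        sizes.append(n)
    return sizes


# ---------------------------------------------------------------- layers

def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patch matrix for 3x3/pad-1/stride-1 conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, h, w, 3, 3), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)


def _col2im(dcol: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    n, c, h, w = shape
    dcol = dcol.reshape(n, h, w, c, 3, 3).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcol.dtype)
    for ki in range(3):
        for kj in range(3):
            dxp[:, :, ki : ki + h, kj : kj + w] += dcol[:, :, :, :, ki, kj]
    return dxp[:, :, 1:-1, 1:-1]


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        # LeCun-normal initialization keeps SELU self-normalizing
        self.w = rng.normal(0.0, 1.0 / np.sqrt(fan_in), (c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        col = _im2col(x)
        out = (col @ self.w.T + self.b).reshape(n, h, w, -1).transpose(0, 3, 1, 2)
        if train:
            self._cache = (col, x.shape)
        return out

    def backward(self, dout: np.ndarray):
        col, xshape = self._cache
        n, _, h, w = xshape
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, -1)
        dw = dflat.T @ col
        db = dflat.sum(axis=0)
        dx = _col2im(dflat @ self.w, xshape)
        return dx, [dw, db]


class _Selu:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return _selu_f32(x)

    def backward(self, dout: np.ndarray):
        return dout * _selu_grad(self._x), []


class _MaxPool2:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        out = xt.max(axis=(3, 5))
        if train:
            self._mask = xt == out[:, :, :, None, :, None]
            self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray):
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        spread = self._mask * dout[:, :, :, None, :, None]
        dx[:, :, : 2 * h2, : 2 * w2] = spread.reshape(n, c, 2 * h2, 2 * w2)
        return dx, []


class _Flatten:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray):
        return dout.reshape(self._shape), []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_out, n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dout: np.ndarray):
        dw = dout.T @ self._x
        db = dout.sum(axis=0)
        return dout @ self.w, [dw, db]


class Model:
    """The assembled network: an ordered layer list plus training history."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list = []
        c_in = spec.in_channels
        self._last_conv_index = None
        for i, c_out in enumerate(spec.conv_channels, start=1):
            layers.append(_Conv3x3(c_in, c_out, rng))
            layers.append(_Selu())
            self._last_conv_index = len(layers) - 1  # post-activation feature map
            if i in spec.pool_after:
                layers.append(_MaxPool2())
            c_in = c_out
        side = pooling_trace(spec.input_size, len(spec.pool_after))[-1]
        layers.append(_Flatten())
        n_in = c_in * side * side
        for j, width in enumerate(spec.fc_widths):
            layers.append(_Dense(n_in, width, rng))
            if j < len(spec.fc_widths) - 1:
                layers.append(_Selu())
            n_in = width
        self.layers = layers
        self.history: list[dict] = []

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray, upto: int = 0):
        """Backpropagate; returns (d_input_at_layer_`upto`, grads per layer)."""
        grads = [None] * len(self.layers)
        d = dlogits
        for i in range(len(self.layers) - 1, upto - 1, -1):
            d, g = self.layers[i].backward(d)
            grads[i] = g
        return d, grads

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Argmax class per item (0 = RESIDUAL, 1 = CD34_POS)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        out = [self.forward(x[i : i + batch_size]).argmax(axis=1)
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out) if out else np.empty(0, dtype=int)

    def get_params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def set_params(self, values: list[np.ndarray]) -> None:
        flat = self.get_params()
        if len(flat) != len(values):
            raise ValueError("parameter count mismatch")
        for dst, src in zip(flat, values):
            dst[...] = src


def build_model(spec: ArchitectureSpec = ArchitectureSpec(), seed: int = 0) -> Model:
    """Instantiate an untrained network with LeCun-normal weights."""
    return Model(spec, seed=seed)


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = len(y)
    logp = _log_softmax(logits.astype(np.float64))
    loss = -logp[np.arange(n), y].mean()
    dlogits = np.exp(logp)
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _accuracy(model: Model, x: np.ndarray, y: np.ndarray) -> float:
    return float((model.predict(x) == y).mean())


def _epoch_loss(model: Model, x: np.ndarray, y: np.ndarray, batch_size: int = 256) -> float:
    tot = 0.0
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i : i + batch_size])
        loss, _ = cross_entropy(logits, y[i : i + batch_size])
        tot += loss * len(y[i : i + batch_size])
    return tot / len(y)


def train(
    model: Model,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainConfig = TrainConfig(),
) -> Model:
    """Minibatch Adam on cross-entropy; keeps the best-validation weights.

    ``train_set``/``val_set`` are (inputs, labels) with inputs shaped
    (N, 50, 50) or (N, 1, 50, 50) in [0, 1] and integer labels
    (1 = CD34_POS). History records per-epoch train/val loss and accuracy.
    Ties in validation accuracy keep the earlier epoch's weights.
    """
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    if len(x_tr) == 0:
        raise ValueError("empty training set")
    x_tr = np.asarray(x_tr, dtype=np.float32)
    x_va = np.asarray(x_va, dtype=np.float32)
    if x_tr.ndim == 3:
        x_tr = x_tr[:, None]
    if x_va.ndim == 3:
        x_va = x_va[:, None]
    y_tr = np.asarray(y_tr, dtype=np.int64)
    y_va = np.asarray(y_va, dtype=np.int64)
    if config.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer {config.optimizer!r}")
    if config.loss.lower() not in ("cross_entropy", "crossentropy", "ce"):
        raise ValueError(f"unsupported loss {config.loss!r}")

    params = model.get_params()
    opt = _Adam(params, config.learning_rate)
    rng = np.random.default_rng(config.seed)
    best_acc, best_weights = -1.0, None
    model.history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        run_loss, run_correct = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = cross_entropy(logits, yb)
            _, layer_grads = model.backward(dlogits)
            grads = [g for lg in layer_grads if lg for g in lg]
            opt.step(params, grads)
            run_loss += loss * len(yb)
            run_correct += int((logits.argmax(axis=1) == yb).sum())
        train_loss = run_loss / len(x_tr)
        train_acc = run_correct / len(x_tr)
        val_acc = _accuracy(model, x_va, y_va) if len(x_va) else float("nan")
        val_loss = _epoch_loss(model, x_va, y_va) if len(x_va) else float("nan")
        model.history.append(
            {"epoch": epoch, "train_loss": train_loss, "train_acc": train_acc,
             "val_loss": val_loss, "val_acc": val_acc}
        )
        if len(x_va) and val_acc > best_acc:  # strict: ties keep earlier epoch
            best_acc = val_acc
            best_weights = copy.deepcopy(params)
        logger.info("epoch %d train_acc=%.4f val_acc=%.4f", epoch, train_acc, val_acc)
    if best_weights is not None:
        model.set_params(best_weights)
    return model


def evaluate(model: Model, test_set: tuple[np.ndarray, np.ndarray]) -> EvalReport:
    """Confusion counts and accuracy/precision/recall on a labeled set."""
    x, y = test_set
    if len(x) == 0:
        raise ValueError("empty test set")
    y = np.asarray(y, dtype=np.int64)
    pred = model.predict(np.asarray(x, dtype=np.float32))
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    n = len(y)
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=(tp + tn) / n,
        precision=tp / (tp + fp) if tp + fp else 0.0,
        recall=tp / (tp + fn) if tp + fn else 0.0,
    )


def gradcam(model: Model, x: np.ndarray, target_class: int) -> np.ndarray:
    """Gradient-weighted class activation map of the last conv layer.

    Channel weights are the spatial mean of d(logit)/d(activation) at the
    final conv feature map (post-SELU); the weighted sum is rectified,
    bilinearly upsampled to the input size, and min-max normalized to
    [0, 1]. All-zero maps are returned as zeros (with a warning).
    """
    from .dataset import _bilinear_resize

    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]
    li = model._last_conv_index
    # forward with caches so the backward pass can run
    out = x
    activation = None
    for i, layer in enumerate(model.layers):
        out = layer.forward(out, train=True)
        if i == li:
            activation = out
    dlogits = np.zeros_like(out)
    dlogits[0, target_class] = 1.0
    d = dlogits
    for i in range(len(model.layers) - 1, li, -1):
        d, _ = model.layers[i].backward(d)
    grad = d[0]  # (C, h, w) gradient at the last conv activation
    weights = grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * activation[0]).sum(axis=0), 0.0)
    size = model.spec.input_size
    cam = _bilinear_resize(cam.astype(np.float64), size, size)
    lo, hi = cam.min(), cam.max()
    if hi <= lo:
        logger.warning("Grad-CAM is degenerate (all-zero gradients); returning zeros")
        return np.zeros((size, size))
    return (cam - lo) / (hi - lo)


def save_model(model: Model, path) -> None:
    """Serialize spec + weights + history (pickle checkpoint)."""
    payload = {
        "spec": model.spec,
        "params": [p.copy() for p in model.get_params()],
        "history": model.history,
    }
    Path(path).write_bytes(pickle.dumps(payload))


def load_model(path) -> Model:
    payload = pickle.loads(Path(path).read_bytes())
    model = Model(payload["spec"])
    model.set_params(payload["params"])
    model.history = payload["history"]
    return model
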