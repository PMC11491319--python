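"""A compact DenseNet-style convolutional classifier for benign/malignant
nodule images, implemented directly on numpy.

Architecture: an initial 3x3 convolution to ``initial_channels`` feature
maps, then ``num_blocks`` dense blocks. Each dense-block layer applies
batch-norm -> ReLU -> 3x3 convolution producing ``growth_rate`` maps and
concatenates them with every earlier map in the block, so layer l sees
k_in + (l-1)*g input channels. Blocks are separated by transition layers
(1x1 convolution compressing to ceil(theta * C) channels, then 2x2 average
pooling); the head is batch-norm -> ReLU -> global average pooling -> a
fully connected 2-way softmax. Training is mini-batch gradient descent on
cross-entropy with Adam updates; forward/backward passes are im2col matrix
multiplications, which keeps desk-scale CPU training in the minutes range.

Seeded runs are reproducible on a fixed compute backend (BLAS reduction
order can differ across builds; bit-equality across machines is not
promised).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .evaluate import NEGATIVE, POSITIVE

MESSAGE_BENIGN = "Tumor is BENIGN"
MESSAGE_MALIGNANT = "Tumor is MALIGNANT"

_DTYPE = np.float32


@dataclass(frozen=True)
class DenseNetConfig:
    input_size: int = 64
    initial_channels: int = 16
    num_blocks: int = 2
    layers_per_block: int = 2
    growth_rate: int = 8
    compression: float = 0.5
    num_classes: int = 2
    seed: int = 0

    def validate(self) -> None:
        if min(self.input_size, self.initial_channels, self.num_blocks,
               self.layers_per_block, self.growth_rate, self.num_classes) < 1:
            raise ValueError("all DenseNetConfig integers must be positive")
        if not 0 < self.compression <= 1:
            raise ValueError("compression must be in (0, 1]")
        # one 2x average pooling per transition (num_blocks - 1 of them)
        if self.input_size % (2 ** (self.num_blocks - 1)) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"2^{self.num_blocks - 1} transition poolings"
            )


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 16
    batch_size: int = 32
    learning_rate: float = 5e-4
    validation_fraction: float = 0.1
    restore_best: bool = True  # roll back to the best-validation epoch
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclass(frozen=True)
class Prediction:
    label: str
    probabilities: tuple[float, float]  # (benign, malignant)
    message: str


# ---------------------------------------------------------------- layers


class _Conv:
    """k x k same-padding convolution as an im2col matmul."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator):
        fan_in = in_ch * ksize * ksize
        self.W = (rng.standard_normal((fan_in, out_ch)) * np.sqrt(2.0 / fan_in)).astype(_DTYPE)
        self.b = np.zeros(out_ch, dtype=_DTYPE)
        self.ksize = ksize
        self.in_ch, self.out_ch = in_ch, out_ch
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.ksize
        if k == 1:
            B, C, H, W = x.shape
            return x.transpose(0, 2, 3, 1).reshape(B * H * W, C)
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # B,C,H,W,k,k
        B, C, H, W = x.shape
        return cols.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * k * k)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, H, W = x.shape
        cols = self._im2col(x).astype(_DTYPE, copy=False)
        y = cols @ self.W + self.b
        if train:
            self._cols, self._shape = cols, (B, C, H, W)
        return y.reshape(B, H, W, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        dy_flat = dy.transpose(0, 2, 3, 1).reshape(B * H * W, self.out_ch)
        self.dW = self._cols.T @ dy_flat
        self.db = dy_flat.sum(axis=0)
        self._cols = None
        if self.ksize == 1:
            dx = dy_flat @ self.W.T
            return dx.reshape(B, H, W, C).transpose(0, 3, 1, 2)
        # dX = same-pad convolution of dy with the flipped, transposed kernel
        k = self.ksize
        Wk = self.W.reshape(C, k, k, self.out_ch)
        W_back = Wk[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(self.out_ch * k * k, C)
        pad = k // 2
        dyp = np.pad(dy, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = sliding_window_view(dyp, (k, k), axis=(2, 3))
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, self.out_ch * k * k)
        dx = cols.astype(_DTYPE, copy=False) @ W_back
        return dx.reshape(B, H, W, C).transpose(0, 3, 1, 2)

    def params(self):
        return [("W", self), ("b", self)]


class _BatchNorm:
    """Per-channel batch normalization over (batch, height, width)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=_DTYPE)
        self.beta = np.zeros(channels, dtype=_DTYPE)
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)
        self.momentum, self.eps = momentum, eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(_DTYPE)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        if train:
            self._xhat, self._std = xhat, std
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma = (dy * self._xhat).sum(axis=axes)
        self.dbeta = dy.sum(axis=axes)
        g_std = (self.gamma / self._std)[None, :, None, None]
        dx = g_std * (
            dy
            - (self.dbeta / m)[None, :, None, None]
            - self._xhat * (self.dgamma / m)[None, :, None, None]
        )
        self._xhat = None
        return dx.astype(_DTYPE, copy=False)


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


def _avgpool2(x: np.ndarray) -> np.ndarray:
    B, C, H, W = x.shape
    return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))


def _avgpool2_back(dy: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * np.asarray(0.25, dtype=_DTYPE)


class _DenseLayer:
    """BN -> ReLU -> 3x3 conv producing ``growth_rate`` maps."""

    def __init__(self, in_ch: int, growth_rate: int, rng: np.random.Generator):
        self.bn = _BatchNorm(in_ch)
        self.relu = _ReLU()
        self.conv = _Conv(in_ch, growth_rate, 3, rng)

    def forward(self, x, train):
        return self.conv.forward(self.relu.forward(self.bn.forward(x, train), train), train)

    def backward(self, dy):
        return self.bn.backward(self.relu.backward(self.conv.backward(dy)))


class _DenseBlock:
    """Concatenative feature reuse: layer l consumes all earlier maps."""

    def __init__(self, in_ch: int, layers: int, growth_rate: int, rng: np.random.Generator):
        self.layers = [_DenseLayer(in_ch + i * growth_rate, growth_rate, rng) for i in range(layers)]
        self.g = growth_rate
        self.in_ch = in_ch
        self.out_ch = in_ch + layers * growth_rate

    def forward(self, x, train):
        feats = x
        for layer in self.layers:
            feats = np.concatenate([feats, layer.forward(feats, train)], axis=1)
        return feats

    def backward(self, dy):
        # dy covers the concatenated [input, out_1, ..., out_L] channels
        for i in reversed(range(len(self.layers))):
            lo = self.in_ch + i * self.g
            d_out = dy[:, lo : lo + self.g]
            d_in = self.layers[i].backward(d_out)
            dy = dy[:, :lo] + d_in
        return dy


class _Transition:
    """1x1 conv to ceil(theta * C) channels, then 2x2 average pooling."""

    def __init__(self, in_ch: int, compression: float, rng: np.random.Generator):
        self.out_ch = int(np.ceil(compression * in_ch))
        self.bn = _BatchNorm(in_ch)
        self.relu = _ReLU()
        self.conv = _Conv(in_ch, self.out_ch, 1, rng)

    def forward(self, x, train):
        return _avgpool2(self.conv.forward(self.relu.forward(self.bn.forward(x, train), train), train))

    def backward(self, dy):
        return self.bn.backward(self.relu.backward(self.conv.backward(_avgpool2_back(dy))))


class DenseNet:
    """The assembled network; see the module docstring for the layout."""

    def __init__(self, config: DenseNetConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.stem = _Conv(1, config.initial_channels, 3, rng)
        self.blocks: list = []
        ch = config.initial_channels
        for b in range(config.num_blocks):
            block = _DenseBlock(ch, config.layers_per_block, config.growth_rate, rng)
            self.blocks.append(block)
            ch = block.out_ch
            if b < config.num_blocks - 1:
                trans = _Transition(ch, config.compression, rng)
                self.blocks.append(trans)
                ch = trans.out_ch
        self.head_bn = _BatchNorm(ch)
        self.head_relu = _ReLU()
        fan_in = ch
        self.fc_W = (rng.standard_normal((fan_in, config.num_classes)) * np.sqrt(2.0 / fan_in)).astype(_DTYPE)
        self.fc_b = np.zeros(config.num_classes, dtype=_DTYPE)
        self.d_fc_W = np.zeros_like(self.fc_W)
        self.d_fc_b = np.zeros_like(self.fc_b)
        self.feature_channels = ch

    # -- forward / backward

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (B, H, W) batch of preprocessed images in [0, 1]."""
        h = self._stack(x)
        h = self.stem.forward(h, train)
        for layer in self.blocks:
            h = layer.forward(h, train)
        h = self.head_relu.forward(self.head_bn.forward(h, train), train)
        self._spatial = h.shape[2:]
        pooled = h.mean(axis=(2, 3))
        if train:
            self._pooled = pooled
        return pooled @ self.fc_W + self.fc_b

    def backward(self, dlogits: np.ndarray) -> None:
        self.d_fc_W = self._pooled.T @ dlogits
        self.d_fc_b = dlogits.sum(axis=0)
        d_pooled = dlogits @ self.fc_W.T
        Hs, Ws = self._spatial
        dh = np.broadcast_to(
            d_pooled[:, :, None, None] / np.asarray(Hs * Ws, dtype=_DTYPE),
            (d_pooled.shape[0], d_pooled.shape[1], Hs, Ws),
        ).astype(_DTYPE)
        dh = self.head_bn.backward(self.head_relu.backward(dh))
        for layer in reversed(self.blocks):
            dh = layer.backward(dh)
        self.stem.backward(dh)

    @staticmethod
    def _stack(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        if x.ndim == 2:
            x = x[None]
        return x[:, None, :, :]

    # -- parameter access

    def _param_tensors(self):
        out = [(self.stem, "W"), (self.stem, "b")]
        for layer in self.blocks:
            if isinstance(layer, _DenseBlock):
                for dl in layer.layers:
                    out += [(dl.bn, "gamma"), (dl.bn, "beta"), (dl.conv, "W"), (dl.conv, "b")]
            else:
                out += [(layer.bn, "gamma"), (layer.bn, "beta"), (layer.conv, "W"), (layer.conv, "b")]
        out += [(self.head_bn, "gamma"), (self.head_bn, "beta"), (self, "fc_W"), (self, "fc_b")]
        return out

    def _grad_of(self, owner, name):
        return getattr(owner, "d_" + name if owner is self else {"W": "dW", "b": "db", "gamma": "dgamma", "beta": "dbeta"}[name])

    def _bn_buffers(self):
        out = []
        for layer in self.blocks:
            sub = layer.layers if isinstance(layer, _DenseBlock) else [layer]
            for s in sub:
                out.append(s.bn)
        return [b for b in out] + [self.head_bn]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": getattr(o, n) for i, (o, n) in enumerate(self._param_tensors())}
        for i, bn in enumerate(self._bn_buffers()):
            state[f"rm{i}"] = bn.running_mean
            state[f"rv{i}"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (o, n) in enumerate(self._param_tensors()):
            setattr(o, n, state[f"p{i}"].astype(_DTYPE))
        for i, bn in enumerate(self._bn_buffers()):
            bn.running_mean = state[f"rm{i}"].astype(_DTYPE)
            bn.running_var = state[f"rv{i}"].astype(_DTYPE)


def build_densenet(config: DenseNetConfig) -> DenseNet:
    """Construct a seeded, freshly initialized network."""
    return DenseNet(config)


# ---------------------------------------------------------------- training


class _Adam:
    def __init__(self, model: DenseNet, lr: float):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(getattr(o, n)) for o, n in model._param_tensors()]
        self.v = [np.zeros_like(getattr(o, n)) for o, n in model._param_tensors()]

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.beta2**self.t) / (1 - self.beta1**self.t)
        for i, (o, n) in enumerate(self.model._param_tensors()):
            g = self.model._grad_of(o, n)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            update = lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps)
            setattr(o, n, (getattr(o, n) - update).astype(_DTYPE))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def prepare_images(images: np.ndarray, input_size: int, levels: int = 256) -> np.ndarray:
    """The documented input contract: resize to input_size, scale to [0, 1]."""
    arr = np.asarray(images, dtype=_DTYPE)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[1] != input_size or arr.shape[2] != input_size:
        from skimage.transform import resize

        arr = np.stack(
            [resize(im, (input_size, input_size), preserve_range=True, anti_aliasing=True) for im in arr]
        ).astype(_DTYPE)
    return arr / _DTYPE(levels - 1)


def fit_arrays(
    model: DenseNet,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> pd.DataFrame:
    """Train on arrays (X: (N, H, W) raw gray images; y: 0 benign / 1 malignant).

    Returns a per-epoch history frame (train_loss, val_loss, train_acc,
    val_acc) suitable for loss-curve plots. Raises on a single-class training
    set and aborts with diagnostics on non-finite loss.
    """
    cfg.validate()
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    X = prepare_images(X, model.config.input_size)
    rng = np.random.default_rng(cfg.seed)

    if X_val is None and cfg.validation_fraction > 0:
        n_val = int(round(len(X) * cfg.validation_fraction))
        order = rng.permutation(len(X))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        X_val, y_val = X[val_idx], y[val_idx]
        X, y = X[tr_idx], y[tr_idx]
    elif X_val is not None:
        X_val = prepare_images(X_val, model.config.input_size)
        y_val = np.asarray(y_val, dtype=int)

    opt = _Adam(model, cfg.learning_rate)
    history = []
    best_val = (-np.inf, np.inf)  # (val_acc, -val_loss) ordering
    best_state = None
    n = len(X)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            logits = model.forward(xb, train=True)
            probs = _softmax(logits)
            eps = 1e-12
            loss = -np.log(probs[np.arange(len(yb)), yb] + eps).mean()
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}: "
                    f"logit range [{logits.min()}, {logits.max()}]"
                )
            losses.append(float(loss))
            correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits = (dlogits / len(yb)).astype(_DTYPE)
            model.backward(dlogits)
            opt.step()
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_acc": correct / n,
            "val_loss": np.nan,
            "val_acc": np.nan,
        }
        if X_val is not None and len(X_val):
            logits = model.forward(X_val, train=False)
            probs = _softmax(logits)
            row["val_loss"] = float(-np.log(probs[np.arange(len(y_val)), y_val] + 1e-12).mean())
            row["val_acc"] = float((probs.argmax(axis=1) == y_val).mean())
            if cfg.restore_best and (row["val_acc"], -row["val_loss"]) > best_val:
                best_val = (row["val_acc"], -row["val_loss"])
                best_state = {k: v.copy() for k, v in model.state_dict().items()}
        history.append(row)
    if best_state is not None:
        model.load_state_dict(best_state)
    return pd.DataFrame(history)


def train(
    model: DenseNet,
    manifest: pd.DataFrame,
    train_cfg: TrainConfig,
    images_root: str | Path = ".",
) -> pd.DataFrame:
    """Train from a dataset manifest, honoring its train/val split tags."""
    from .preprocess import read_image

    root = Path(images_root)

    def _load(split: str):
        sub = manifest[manifest["split"] == split]
        if sub.empty:
            return None, None
        X = np.stack([read_image(root / p) for p in sub["image_path"]])
        y = (sub["label"] == POSITIVE).to_numpy().astype(int)
        return X, y

    X_tr, y_tr = _load("train")
    if X_tr is None:
        raise ValueError("manifest has no train split")
    X_val, y_val = _load("val")
    return fit_arrays(model, X_tr, y_tr, train_cfg, X_val, y_val)


# ---------------------------------------------------------------- inference


def predict_proba(model: DenseNet, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """(N, 2) class probabilities, columns (benign, malignant)."""
    X = prepare_images(images, model.config.input_size)
    out = []
    for start in range(0, len(X), batch_size):
        out.append(_softmax(model.forward(X[start : start + batch_size], train=False)))
    return np.concatenate(out)


def predict(model: DenseNet, image: np.ndarray) -> Prediction:
    """Classify one image; ties at probability 0.5 resolve to malignant."""
    probs = predict_proba(model, np.asarray(image)[None])[0]
    malignant = probs[1] >= 0.5
    return Prediction(
        label=POSITIVE if malignant else NEGATIVE,
        probabilities=(float(probs[0]), float(probs[1])),
        message=MESSAGE_MALIGNANT if malignant else MESSAGE_BENIGN,
    )


def save_model(model: DenseNet, path: str | Path) -> None:
    path = Path(path)
    np.savez(path, **model.state_dict(), _config=json.dumps(asdict(model.config)))


def load_model(path: str | Path) -> DenseNet:
    data = np.load(path, allow_pickle=False)
    config = DenseNetConfig(**json.loads(str(data["_config"])))
    model = DenseNet(config)
    model.load_state_dict({k: data[k] for k in data.files if k != "_config"})
    return model
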