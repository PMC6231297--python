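"""Small convolutional network for 2.5D hippocampus patches.

Architecture (input 32x32, 3 channels):

    conv 5x5 pad 2 (32 maps) -> ReLU -> max-pool 3x3 stride 2 -> LRN
    conv 5x5 pad 2 (32 maps) -> ReLU -> avg-pool 3x3 stride 2 -> LRN
    conv 5x5 pad 2 (64 maps) -> ReLU -> avg-pool 3x3 stride 2
    flatten (64 * 4 * 4 = 1024) -> fully-connected (2) -> softmax

Spatial trace: 32 -> 16 -> 8 -> 4 (ceil-mode pooling).  The flattened
output of the last pooling layer is the 1024-dimensional deep feature
vector per patch.

Training is plain mini-batch SGD with momentum and weight decay:

    v <- m * v - eta * (g + lambda * theta);   theta <- theta + v

implemented from scratch on numpy so the package has no deep-learning
framework dependency.  Inputs are standardized with the training set's
global mean/SD (stored on the model) purely for optimization stability.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Sequence

import numpy as np

from mcipredict.io import FeatureMatrix
from mcipredict.patches import Patch25D

# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class CnnConfig:
    conv_kernel: int = 5
    padding: int = 2
    pool_kernel: int = 3
    pool_stride: int = 2
    channels: tuple[int, int, int] = (32, 32, 64)
    pool_types: tuple[str, str, str] = ("max", "avg", "avg")
    lrn_size: int = 3
    lrn_alpha: float = 5e-5
    lrn_beta: float = 0.75
    momentum: float = 0.9
    learning_rate: float = 0.001
    weight_decay: float = 0.0001
    epochs: int = 30
    batch_size: int = 151
    init_scheme: str = "he"  # fan-in-scaled Gaussian; "gaussian" = fixed init_std
    init_std: float = 0.01
    input_size: int = 32
    in_channels: int = 3
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if len(self.channels) != len(self.pool_types):
            raise ValueError("channels and pool_types length mismatch")


def _init_std(cfg: CnnConfig, fan_in: int) -> float:
    if cfg.init_scheme == "he":
        return math.sqrt(2.0 / fan_in)
    if cfg.init_scheme == "gaussian":
        return cfg.init_std
    raise ValueError(f"unknown init_scheme '{cfg.init_scheme}'")


def _pool_out(size: int, k: int, s: int) -> int:
    # ceil mode, as in classic Caffe pooling: 32 -> 16 -> 8 -> 4
    return int(math.ceil((size - k) / s)) + 1


# ---------------------------------------------------------------------------
# layers


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B,C,H,W) -> (C*k*k, B*H*W) for stride-1 same-size convolution."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (B, C, H, W, k, k) since H + 2*pad - k + 1 == H for pad = (k-1)/2
    cols = win.transpose(1, 4, 5, 0, 2, 3).reshape(C * k * k, B * H * W)
    return np.ascontiguousarray(cols)


def _col2im(cols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add columns back to the image."""
    B, C, H, W = x_shape
    cols6 = cols.reshape(C, k, k, B, H, W)
    xp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + H, j : j + W] += cols6[:, i, j].transpose(1, 0, 2, 3)
    return xp[:, :, pad : pad + H, pad : pad + W]


class Conv2D:
    """5x5 same-padding convolution via im2col (one large GEMM per pass)."""

    def __init__(self, in_ch: int, out_ch: int, k: int, pad: int, rng, init_std: float):
        self.k, self.pad = k, pad
        self.params = {
            "W": rng.normal(0.0, init_std, size=(out_ch, in_ch * k * k)).astype(np.float32),
            "b": np.zeros(out_ch, dtype=np.float32),
        }
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k, self.pad)  # (C*k*k, B*H*W)
        B, _, H, W = x.shape
        out = self.params["W"] @ self._cols  # (F, B*H*W)
        out += self.params["b"][:, None]
        return out.reshape(-1, B, H, W).transpose(1, 0, 2, 3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, F, H, W = gy.shape
        g = np.ascontiguousarray(gy.transpose(1, 0, 2, 3)).reshape(F, B * H * W)
        self.grads["W"] = g @ self._cols.T
        self.grads["b"] = g.sum(axis=1)
        gcols = self.params["W"].T @ g
        return _col2im(gcols, self._x_shape, self.k, self.pad)


class ReLU:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class Pool2D:
    """Max or average pooling, ceil mode (windows truncated at borders)."""

    params: dict = {}
    grads: dict = {}

    def __init__(self, kind: str, k: int = 3, stride: int = 2):
        if kind not in ("max", "avg"):
            raise ValueError(f"unknown pool kind '{kind}'")
        self.kind, self.k, self.stride = kind, k, stride

    def _windows(self, size: int):
        out = _pool_out(size, self.k, self.stride)
        return [(i * self.stride, min(i * self.stride + self.k, size)) for i in range(out)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        hw, ww = self._windows(H), self._windows(W)
        out = np.empty((B, C, len(hw), len(ww)), dtype=x.dtype)
        self._x_shape = x.shape
        self._argmax = {}
        for i, (hs, he) in enumerate(hw):
            for j, (ws, we) in enumerate(ww):
                win = x[:, :, hs:he, ws:we]
                if self.kind == "max":
                    flat = win.reshape(B, C, -1)
                    am = flat.argmax(axis=2)
                    self._argmax[(i, j)] = (am, he - hs, we - ws)
                    out[:, :, i, j] = np.take_along_axis(flat, am[..., None], axis=2)[..., 0]
                else:
                    out[:, :, i, j] = win.mean(axis=(2, 3))
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._x_shape
        gx = np.zeros(self._x_shape, dtype=gy.dtype)
        hw, ww = self._windows(H), self._windows(W)
        bi = np.arange(B)[:, None]
        ci = np.arange(C)[None, :]
        for i, (hs, he) in enumerate(hw):
            for j, (ws, we) in enumerate(ww):
                if self.kind == "max":
                    am, wh, wwid = self._argmax[(i, j)]
                    gx[bi, ci, hs + am // wwid, ws + am % wwid] += gy[:, :, i, j]
                else:
                    area = (he - hs) * (we - ws)
                    gx[:, :, hs:he, ws:we] += gy[:, :, i, j][..., None, None] / area
        return gx


class LRN:
    """Local response normalization across channels (Caffe-style):

    y_c = x_c / (1 + (alpha/n) * sum_{i in window(c)} x_i^2) ** beta
    """

    params: dict = {}
    grads: dict = {}

    def __init__(self, size: int = 3, alpha: float = 5e-5, beta: float = 0.75):
        self.size, self.alpha, self.beta = size, alpha, beta

    def _window_sum(self, t: np.ndarray) -> np.ndarray:
        half = self.size // 2
        pad = np.pad(t, ((0, 0), (half, half), (0, 0), (0, 0)))
        csum = np.cumsum(pad, axis=1)
        csum = np.concatenate([np.zeros_like(csum[:, :1]), csum], axis=1)
        C = t.shape[1]
        return csum[:, self.size : self.size + C] - csum[:, :C]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._S = 1.0 + (self.alpha / self.size) * self._window_sum(x * x)
        self._Snb = self._S ** (-self.beta)
        return x * self._Snb

    def backward(self, gy: np.ndarray) -> np.ndarray:
        t = gy * self._x * self._S ** (-self.beta - 1.0)
        return gy * self._Snb - (2.0 * self.alpha * self.beta / self.size) * self._x * self._window_sum(t)


class Linear:
    def __init__(self, in_dim: int, out_dim: int, rng, init_std: float):
        self.params = {
            "W": rng.normal(0.0, init_std, size=(out_dim, in_dim)).astype(np.float32),
            "b": np.zeros(out_dim, dtype=np.float32),
        }
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads["W"] = gy.T @ self._x
        self.grads["b"] = gy.sum(axis=0)
        return gy @ self.params["W"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-300))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


# ---------------------------------------------------------------------------
# model


class CnnModel:
    """Feature extractor + softmax classification head."""

    def __init__(self, cfg: CnnConfig):
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        size = cfg.input_size
        in_ch = cfg.in_channels
        self.feature_layers: list = []
        for stage, (out_ch, pool) in enumerate(zip(cfg.channels, cfg.pool_types)):
            fan_in = in_ch * cfg.conv_kernel**2
            self.feature_layers.append(
                Conv2D(in_ch, out_ch, cfg.conv_kernel, cfg.padding, rng,
                       _init_std(cfg, fan_in))
            )
            self.feature_layers.append(ReLU())
            self.feature_layers.append(Pool2D(pool, cfg.pool_kernel, cfg.pool_stride))
            size = _pool_out(size, cfg.pool_kernel, cfg.pool_stride)
            if stage < len(cfg.channels) - 1:  # no LRN after the last stage
                self.feature_layers.append(LRN(cfg.lrn_size, cfg.lrn_alpha, cfg.lrn_beta))
            in_ch = out_ch
        self.final_size = size
        self.feature_dim = cfg.channels[-1] * size * size
        self.head = Linear(self.feature_dim, cfg.n_classes, rng,
                           _init_std(cfg, self.feature_dim))
        self.input_mean = 0.0
        self.input_std = 1.0
        self.trained = False
        self.training_log: list[dict] = []

    # -- forward passes ----------------------------------------------------

    def _prep(self, patches: Sequence[Patch25D] | np.ndarray) -> np.ndarray:
        """Stack patches into (B, C, H, W) and apply input standardization."""
        if isinstance(patches, np.ndarray):
            x = patches
        else:
            x = np.stack([p.data for p in patches]).transpose(0, 3, 1, 2)
        x = x.astype(np.float32)
        return (x - np.float32(self.input_mean)) / np.float32(self.input_std)

    def forward_features(self, x: np.ndarray) -> np.ndarray:
        for layer in self.feature_layers:
            x = layer.forward(x)
        return x.reshape(x.shape[0], -1)

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.forward_features(x))

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.head.backward(grad_logits)
        g = g.reshape(g.shape[0], self.config.channels[-1], self.final_size, self.final_size)
        for layer in reversed(self.feature_layers):
            g = layer.backward(g)

    def predict_proba(self, patches: Sequence[Patch25D]) -> np.ndarray:
        return softmax(self.forward_logits(self._prep(patches)))

    def layer_shape_trace(self) -> list[tuple]:
        """Output shape (C, H, W) after each feature layer for one input."""
        x = np.zeros(
            (1, self.config.in_channels, self.config.input_size, self.config.input_size),
            dtype=np.float32,
        )
        trace = []
        for layer in self.feature_layers:
            x = layer.forward(x)
            trace.append(x.shape[1:])
        return trace

    # -- parameters --------------------------------------------------------

    def parameters(self) -> list[tuple[object, str]]:
        out = []
        for layer in self.feature_layers + [self.head]:
            for name in layer.params:
                out.append((layer, name))
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for i, (layer, name) in enumerate(self.parameters()):
            arrays[f"p{i}_{name}"] = layer.params[name]
        arrays["input_mean"] = np.asarray(self.input_mean)
        arrays["input_std"] = np.asarray(self.input_std)
        arrays["trained"] = np.asarray(int(self.trained))
        arrays["config_json"] = np.frombuffer(
            json.dumps(dataclasses.asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "CnnModel":
        with np.load(path) as z:
            cfg_dict = json.loads(bytes(z["config_json"]).decode())
            for key in ("channels", "pool_types", "volume_shape"):
                if key in cfg_dict and isinstance(cfg_dict[key], list):
                    cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(CnnConfig(**cfg_dict))
            for i, (layer, name) in enumerate(model.parameters()):
                layer.params[name] = z[f"p{i}_{name}"]
            model.input_mean = float(z["input_mean"])
            model.input_std = float(z["input_std"])
            model.trained = bool(int(z["trained"]))
        return model


def build_cnn(cfg: CnnConfig | None = None) -> CnnModel:
    """Instantiate the network and assert its spatial trace is valid."""
    cfg = cfg or CnnConfig()
    model = CnnModel(cfg)
    if model.final_size < 1:
        raise ValueError("config collapses the spatial dimensions below 1x1")
    return model


def n_minibatches(n_samples: int, batch_size: int) -> int:
    """Mini-batches per epoch (last batch may be short)."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    return -(-n_samples // batch_size)


# ---------------------------------------------------------------------------
# training


def train_cnn(
    model: CnnModel,
    patches: Sequence[Patch25D],
    labels: Sequence[int],
    cfg: CnnConfig | None = None,
) -> CnnModel:
    """Momentum SGD with weight decay, in place.

    ``labels`` are binary per patch (positive class = 1).  Patches are
    shuffled globally each epoch with the configured seed.  Zero epochs
    leaves the weights untouched.
    """
    cfg = cfg or model.config
    y = np.asarray(labels, dtype=int)
    if len(patches) == 0:
        raise ValueError("empty training set")
    if len(patches) != len(y):
        raise ValueError("patches and labels length mismatch")
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")

    x_all = np.stack([p.data for p in patches]).transpose(0, 3, 1, 2).astype(np.float32)
    model.input_mean = float(x_all.mean(dtype=np.float64))
    model.input_std = float(x_all.std(dtype=np.float64)) or 1.0
    x_all = (x_all - np.float32(model.input_mean)) / np.float32(model.input_std)

    rng = np.random.default_rng(cfg.seed + 1)
    velocity = {(id(layer), name): np.zeros_like(layer.params[name])
                for layer, name in model.parameters()}
    n = len(y)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = x_all[idx], y[idx]
            logits = model.forward_logits(xb)
            loss, grad = softmax_cross_entropy(logits, yb)
            model.backward(grad)
            for layer, name in model.parameters():
                key = (id(layer), name)
                g = layer.grads[name]
                velocity[key] = (
                    cfg.momentum * velocity[key]
                    - cfg.learning_rate * (g + cfg.weight_decay * layer.params[name])
                )
                layer.params[name] += velocity[key]
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == yb).sum())
        model.training_log.append(
            {"epoch": epoch, "loss": float(np.sum(losses) / n), "accuracy": correct / n}
        )
    model.trained = cfg.epochs > 0 or model.trained
    return model


# ---------------------------------------------------------------------------
# feature extraction / voting


def extract_cnn_features(
    model: CnnModel, patches: Sequence[Patch25D], batch_size: int = 256
) -> FeatureMatrix:
    """Deep features from the last pooling layer, one row per patch."""
    if len(patches) == 0:
        raise ValueError("no patches given")
    rows = []
    for start in range(0, len(patches), batch_size):
        chunk = patches[start : start + batch_size]
        rows.append(model.forward_features(model._prep(chunk)))
    values = np.vstack(rows)
    ids = [f"{p.subject_id}#{i}" for i, p in enumerate(patches)]
    names = [f"cnn_{j}" for j in range(model.feature_dim)]
    return FeatureMatrix(values=values, subject_ids=ids, feature_names=names)


def majority_vote(decisions: Sequence[int]) -> int:
    """Majority over binary per-patch decisions; a tie goes to class 1."""
    votes = np.asarray(decisions, dtype=int)
    if votes.size == 0:
        raise ValueError("no decisions to vote over")
    return int(2 * votes.sum() >= votes.size)


def classify_subject_by_patch_vote(model: CnnModel, patches: Sequence[Patch25D]) -> int:
    """Subject-level diagnosis from per-patch argmax decisions."""
    if len(patches) == 0:
        raise ValueError("no patches to vote over")
    probs = model.predict_proba(patches)
    return majority_vote(probs.argmax(axis=1))
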