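"""Fully convolutional network for window classification and embeddings.

The architecture is the standard three-block FCN for time-series
classification: Conv1d(128, k=8) → BN → ReLU, Conv1d(256, k=5) → BN → ReLU,
Conv1d(128, k=3) → BN → ReLU, global average pooling over time, and a final
linear layer with softmax. The pooled 128-wide activation (pre-softmax) is
the *embedding* used as a learned feature representation elsewhere in the
pipeline. Because pooling is global, the network accepts any window length.

The implementation is pure numpy (float32) with manual backpropagation and
an Adam optimizer: convolutions are evaluated tap-by-tap as batched matrix
products, which keeps memory bounded and routes the arithmetic through
BLAS. Training is deterministic given the config seed. Raw windows are
z-normalized per channel with statistics from the training split, stored on
the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import WindowSet

_EPS = 1e-5


@dataclass(frozen=True)
class FCNConfig:
    conv_blocks: tuple = ((128, 8), (256, 5), (128, 3))
    batch_size: int = 256
    learning_rate: float = 0.0001
    epochs: int = 150
    seed: int = 0

    @property
    def embedding_width(self) -> int:
        return self.conv_blocks[-1][0]


def small_scale_config(epochs: int = 25, learning_rate: float = 0.001,
                       batch_size: int = 64, seed: int = 0) -> FCNConfig:
    """Reduced-budget training settings for unit tests and small cohorts."""
    return FCNConfig(
        batch_size=batch_size, learning_rate=learning_rate, epochs=epochs, seed=seed
    )


class _Conv1d:
    """Same-padded stride-1 1-D convolution; weights (K, C_in, C_out)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (k * c_in))
        self.W = (rng.standard_normal((k, c_in, c_out)) * std).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.pad_left = (k - 1) // 2
        self.pad_right = k - 1 - self.pad_left

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, L, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        y = np.broadcast_to(self.b, (B, L, self.W.shape[2])).copy()
        for tap in range(self.k):
            y += xp[:, tap : tap + L, :] @ self.W[tap]
        if training:
            self._xp = xp
        return y

    def backward(self, dy: np.ndarray):
        B, L, c_out = dy.shape
        xp = self._xp
        dW = np.empty_like(self.W)
        dxp = np.zeros_like(xp)
        dy_flat = dy.reshape(-1, c_out)
        for tap in range(self.k):
            seg = xp[:, tap : tap + L, :].reshape(-1, self.W.shape[1])
            dW[tap] = seg.T @ dy_flat
            dxp[:, tap : tap + L, :] += dy @ self.W[tap].T
        db = dy_flat.sum(axis=0)
        self._xp = None
        dx = dxp[:, self.pad_left : self.pad_left + L, :]
        return dx, [dW, db]


class _BatchNorm:
    """Per-channel batch normalization over the (batch, time) axes."""

    def __init__(self, c: int):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = 0.9

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mean) * inv
        if training:
            self._xhat = xhat.astype(np.float32)
            self._inv = inv.astype(np.float32)
        return xhat * self.gamma + self.beta

    def backward(self, dy: np.ndarray):
        xhat, inv = self._xhat, self._inv
        n = dy.shape[0] * dy.shape[1]
        dgamma = (dy * xhat).sum(axis=(0, 1))
        dbeta = dy.sum(axis=(0, 1))
        dx = (self.gamma * inv / n) * (
            n * dy - dbeta - xhat * dgamma
        )
        self._xhat = self._inv = None
        return dx.astype(np.float32), [dgamma, dbeta]


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray):
        dx = dy * self._mask
        self._mask = None
        return dx, []


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + eps)


@dataclass
class FCNModel:
    """Fitted FCN: conv/BN stack, linear head, class order, input scaling."""

    config: FCNConfig
    classes: list[str]
    layers: list = field(repr=False, default_factory=list)
    head_W: np.ndarray | None = field(repr=False, default=None)
    head_b: np.ndarray | None = field(repr=False, default=None)
    channel_mean: np.ndarray | None = None
    channel_std: np.ndarray | None = None
    history: list[float] = field(default_factory=list)  # mean loss per epoch

    @property
    def fitted(self) -> bool:
        return self.head_W is not None and self.channel_mean is not None

    def _require_fitted(self) -> None:
        if not self.fitted:
            raise RuntimeError("FCN model has not been trained")

    def _normalize(self, windows: np.ndarray) -> np.ndarray:
        x = np.asarray(windows, dtype=np.float32)
        return (x - self.channel_mean) / self.channel_std

    def _embed_batch(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h, training)
        if training:
            self._gap_len = h.shape[1]
        return h.mean(axis=1)  # global average pooling

    def extract_embeddings(self, ws: WindowSet | np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Pooled penultimate-layer activations, shape (W, embedding_width)."""
        self._require_fitted()
        windows = ws.windows if isinstance(ws, WindowSet) else np.asarray(ws)
        x = self._normalize(windows)
        out = [
            self._embed_batch(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out, axis=0).astype(np.float64)

    def logits_from_embeddings(self, emb: np.ndarray) -> np.ndarray:
        self._require_fitted()
        return np.asarray(emb, dtype=np.float32) @ self.head_W + self.head_b

    def predict_proba(self, ws: WindowSet | np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Softmax class probabilities, rows summing to 1; columns follow
        ``self.classes``."""
        emb = self.extract_embeddings(ws, batch_size=batch_size)
        logits = self.logits_from_embeddings(emb).astype(np.float64)
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, ws: WindowSet | np.ndarray) -> np.ndarray:
        proba = self.predict_proba(ws)
        return np.asarray(self.classes, dtype=object)[proba.argmax(axis=1)]


def train_fcn(
    windows: np.ndarray | WindowSet,
    labels: np.ndarray | None = None,
    cfg: FCNConfig | None = None,
) -> FCNModel:
    """Train the FCN on labelled windows.

    ``windows`` may be a WindowSet (labels taken from metadata) or a raw
    (W, L, 6) tensor with ``labels`` supplied separately. At least two
    classes must be present.
    """
    cfg = cfg or FCNConfig()
    if isinstance(windows, WindowSet):
        labels = windows.labels
        windows = windows.windows
    x64 = np.asarray(windows, dtype=float)
    if x64.ndim != 3:
        raise ValueError(f"expected (W, L, C) window tensor, got shape {x64.shape}")
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError(f"training requires >= 2 classes, got {classes}")
    class_index = {c: i for i, c in enumerate(classes)}
    yi = np.array([class_index[c] for c in y])

    model = FCNModel(config=cfg, classes=classes)
    model.channel_mean = x64.mean(axis=(0, 1)).astype(np.float32)
    sd = x64.std(axis=(0, 1))
    model.channel_std = np.where(sd > 0, sd, 1.0).astype(np.float32)

    rng = np.random.default_rng(cfg.seed)
    c_in = x64.shape[2]
    layers: list = []
    for c_out, k in cfg.conv_blocks:
        layers.append(_Conv1d(c_in, c_out, k, rng))
        layers.append(_BatchNorm(c_out))
        layers.append(_ReLU())
        c_in = c_out
    model.layers = layers
    n_classes = len(classes)
    limit = np.sqrt(6.0 / (c_in + n_classes))
    model.head_W = rng.uniform(-limit, limit, size=(c_in, n_classes)).astype(np.float32)
    model.head_b = np.zeros(n_classes, dtype=np.float32)

    params = [p for layer in layers for p in layer.params] + [model.head_W, model.head_b]
    opt = _Adam(params, cfg.learning_rate)

    x = model._normalize(x64)
    n = len(x)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], yi[idx]
            emb = model._embed_batch(xb, training=True)
            logits = emb @ model.head_W + model.head_b
            shifted = logits - logits.max(axis=1, keepdims=True)
            expz = np.exp(shifted)
            proba = expz / expz.sum(axis=1, keepdims=True)
            loss = -np.log(
                np.maximum(proba[np.arange(len(idx)), yb], 1e-12)
            ).mean()
            losses.append(float(loss) * len(idx))

            dlogits = proba.copy()
            dlogits[np.arange(len(idx)), yb] -= 1.0
            dlogits = (dlogits / len(idx)).astype(np.float32)
            dW_head = emb.T @ dlogits
            db_head = dlogits.sum(axis=0)
            demb = dlogits @ model.head_W.T
            # undo global average pooling
            dh = np.repeat(demb[:, None, :] / model._gap_len, model._gap_len, axis=1)
            grads_rev = []
            for layer in reversed(layers):
                dh, g = layer.backward(dh)
                grads_rev.extend(reversed(g))
            grads = list(reversed(grads_rev)) + [dW_head, db_head]
            opt.step(grads)
        model.history.append(sum(losses) / n)
    return model
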