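"""Convolutional depth regressor with self-attention and residual blocks.

The architecture follows the published layer table: three conv/max-pool
pairs (3x3 kernels, stride 1, one ring of zero padding; 2x2 pools, stride
2) taking a 1x24x24 feature image through 16, 32 and 64 maps down to
3x3x64.  The hidden layers between the last pool and the scalar output are
then: the 64 3x3 maps are treated as 64 nine-dimensional tokens passed
through one scaled dot-product self-attention block (softmax(QK^T/sqrt(d_k))V),
flattened to 576 features, passed through one residual fully connected
block H(x) = x + F(x), and regressed to a scalar squashed to [0, 100] by
sigmoid x 100.  ReLU activations, mean-squared-error loss, plain SGD at
learning rate 0.01.

Everything — forward passes, gradients, the optimizer — is implemented
directly in numpy; all randomness (initialization, batch sampling, fold
assignment) flows from a single seed, so training is bit-reproducible.
Gradient global-norm clipping (max 10) keeps early SGD steps finite on the
0-100 target scale; it is the only addition to the plain SGD update.

An "accuracy" for the regression is the fraction of predictions within
+/-10 depth units of the reference (tolerance configurable); validation
accuracy and error are checkpointed every 30 iterations during training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from anesdepth.samples import SampleImage, IMAGE_SIDE, IMAGE_SIZE

__all__ = [
    "NetworkConfig",
    "TrainResult",
    "Network",
    "conv_forward",
    "max_pool",
    "self_attention",
    "residual_block",
    "autoencoder_pretrain",
    "build_network",
    "train_model",
    "fit_network",
]

CHECKPOINT_EVERY = 30  # validation cadence, iterations


# ---------------------------------------------------------------------------
# functional operations (single-sample forms)


def _activation(name):
    if callable(name):
        return name
    if name == "relu":
        return lambda z: np.maximum(z, 0.0)
    if name == "linear":
        return lambda z: z
    raise ValueError(f"unknown activation {name!r}")


def conv_forward(x, w, d=0.0, activation="linear", stride: int = 1, pad: int = 0):
    """2-d convolution (cross-correlation) over feature maps.

    ``x``: (C, H, W) input maps; ``w``: (F, C, kh, kw) kernels; ``d``: bias
    per output map (scalar or length F).  Output spatial side must be an
    integer: (H + 2*pad - kh)/stride + 1.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.ndim == 2:
        x = x[None]
    C, H, W = x.shape
    F, Cw, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"kernel expects {Cw} input maps, got {C}")
    if (H + 2 * pad - kh) % stride or (W + 2 * pad - kw) % stride:
        raise ValueError(
            f"non-integer output size for input {H}x{W}, kernel {kh}x{kw}, "
            f"stride {stride}, padding {pad}"
        )
    out = _conv_batch(x[None], w, stride, pad)[0]
    bias = np.asarray(d, dtype=float).reshape(-1, 1, 1) if np.ndim(d) else float(d)
    return _activation(activation)(out + bias)


def max_pool(x, m: int = 2, stride: int | None = None):
    """Max pooling with an m x m window; stride defaults to m."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None]
    stride = m if stride is None else stride
    C, H, W = x.shape
    if (H - m) % stride or (W - m) % stride:
        raise ValueError(
            f"pool {m}x{m} stride {stride} does not tile input {H}x{W}"
        )
    H2, W2 = (H - m) // stride + 1, (W - m) // stride + 1
    out = np.empty((C, H2, W2))
    for i in range(H2):
        for j in range(W2):
            block = x[:, i * stride : i * stride + m, j * stride : j * stride + m]
            out[:, i, j] = block.max(axis=(1, 2))
    return out


def self_attention(X, W_q, W_k, W_v, d_k: int | None = None):
    """Scaled dot-product self-attention over token rows of ``X``.

    Q = X W_q, K = X W_k, V = X W_v; output = softmax(Q K^T / sqrt(d_k)) V.
    Attention rows are stochastic, so each output is a convex combination
    of value vectors.
    """
    X = np.asarray(X, dtype=float)
    W_q, W_k, W_v = (np.asarray(w, dtype=float) for w in (W_q, W_k, W_v))
    for name, w in (("W_q", W_q), ("W_k", W_k), ("W_v", W_v)):
        if w.shape[0] != X.shape[1]:
            raise ValueError(f"{name} expects {w.shape[0]}-d tokens, got {X.shape[1]}")
    if d_k is None:
        d_k = W_k.shape[1]
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    Q, K, V = X @ W_q, X @ W_k, X @ W_v
    S = Q @ K.T / math.sqrt(d_k)
    A = _softmax_rows(S)
    return A @ V


def residual_block(x, F):
    """Shortcut connection H(x) = F(x) + x; F must preserve shape."""
    x = np.asarray(x, dtype=float)
    fx = np.asarray(F(x), dtype=float)
    if fx.shape != x.shape:
        raise ValueError(
            f"residual transform changed shape {x.shape} -> {fx.shape}; "
            "insert a projection before the shortcut"
        )
    return x + fx


def _softmax_rows(S):
    S = S - S.max(axis=-1, keepdims=True)
    E = np.exp(S)
    return E / E.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# batched conv helpers (im2col)


def _im2col_indices(C, H, W, k, stride, pad):
    H2 = (H + 2 * pad - k) // stride + 1
    W2 = (W + 2 * pad - k) // stride + 1
    ci = np.repeat(np.arange(C), k * k)
    ki = np.tile(np.repeat(np.arange(k), k), C)
    kj = np.tile(np.tile(np.arange(k), k), C)
    oi = np.repeat(np.arange(H2) * stride, W2)
    oj = np.tile(np.arange(W2) * stride, H2)
    rows = ki[None, :] + oi[:, None]  # (H2*W2, C*k*k)
    cols = kj[None, :] + oj[:, None]
    chan = np.broadcast_to(ci, rows.shape)
    return chan, rows, cols, H2, W2


def _conv_batch(x, w, stride, pad):
    """x: (B, C, H, W), w: (F, C, k, k) -> (B, F, H2, W2)."""
    B, C, H, W = x.shape
    F, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    chan, rows, cols, H2, W2 = _im2col_indices(C, H, W, k, stride, pad)
    patches = xp[:, chan, rows, cols]  # (B, H2*W2, C*k*k)
    out = patches @ w.reshape(F, -1).T  # (B, H2*W2, F)
    return out.transpose(0, 2, 1).reshape(B, F, H2, W2)


# ---------------------------------------------------------------------------
# trainable layers


class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class _Conv(_Layer):
    def __init__(self, c_in, c_out, k, stride, pad, rng):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad
        scale = math.sqrt(2.0 / (c_in * k * k))  # He init for ReLU stacks
        self.params = {
            "w": rng.normal(0.0, scale, size=(c_out, c_in, k, k)),
            "b": np.zeros(c_out),
        }

    def forward(self, x, train=True):
        self._x = x
        out = _conv_batch(x, self.params["w"], self.stride, self.pad)
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout):
        x, w = self._x, self.params["w"]
        B, C, H, W = x.shape
        F, _, k, _ = w.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        chan, rows, cols, H2, W2 = _im2col_indices(C, H, W, k, self.stride, self.pad)
        patches = xp[:, chan, rows, cols]  # (B, H2*W2, C*k*k)
        dflat = dout.reshape(B, F, H2 * W2).transpose(0, 2, 1)  # (B, H2*W2, F)
        self.grads["w"] = (
            np.einsum("bpf,bpc->fc", dflat, patches).reshape(w.shape)
        )
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        dpatches = dflat @ w.reshape(F, -1)  # (B, H2*W2, C*k*k)
        Hp, Wp = xp.shape[2], xp.shape[3]
        dxp = np.zeros((B, C * Hp * Wp))
        flat_idx = (chan * Hp + rows) * Wp + cols
        np.add.at(
            dxp,
            (np.arange(B)[:, None, None], flat_idx[None, :, :]),
            dpatches,
        )
        dxp = dxp.reshape(B, C, Hp, Wp)
        if self.pad:
            return dxp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dxp


class _ReLU(_Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class _MaxPool2(_Layer):
    """2x2 max pool, stride 2 (the only pooling the architecture uses)."""

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        xb = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        blocks = xb.reshape(B, C, H // 2, W // 2, 4)
        self._arg = blocks.argmax(axis=-1)
        self._shape = x.shape
        return blocks.max(axis=-1)

    def backward(self, dout):
        B, C, H, W = self._shape
        dblocks = np.zeros((B, C, H // 2, W // 2, 4))
        np.put_along_axis(dblocks, self._arg[..., None], dout[..., None], axis=-1)
        dx = dblocks.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(B, C, H, W)


class _TokensFromMaps(_Layer):
    """(B, C, h, w) maps -> (B, C, h*w) tokens: one token per feature map."""

    def forward(self, x, train=True):
        self._shape = x.shape
        B, C, h, w = x.shape
        return x.reshape(B, C, h * w)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _SelfAttention(_Layer):
    def __init__(self, d_model, d_k, rng):
        super().__init__()
        self.d_k = d_k
        scale = 1.0 / math.sqrt(d_model)
        self.params = {
            "wq": rng.normal(0.0, scale, size=(d_model, d_k)),
            "wk": rng.normal(0.0, scale, size=(d_model, d_k)),
            "wv": rng.normal(0.0, scale, size=(d_model, d_model)),
        }

    def forward(self, x, train=True):
        self._x = x
        wq, wk, wv = self.params["wq"], self.params["wk"], self.params["wv"]
        self._Q, self._K, self._V = x @ wq, x @ wk, x @ wv
        S = self._Q @ self._K.transpose(0, 2, 1) / math.sqrt(self.d_k)
        self._A = _softmax_rows(S)
        return self._A @ self._V

    def backward(self, dout):
        x, A, Q, K, V = self._x, self._A, self._Q, self._K, self._V
        wq, wk, wv = self.params["wq"], self.params["wk"], self.params["wv"]
        dA = dout @ V.transpose(0, 2, 1)
        dV = A.transpose(0, 2, 1) @ dout
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dS = dS / math.sqrt(self.d_k)
        dQ = dS @ K
        dK = dS.transpose(0, 2, 1) @ Q
        self.grads["wq"] = np.einsum("btd,btk->dk", x, dQ)
        self.grads["wk"] = np.einsum("btd,btk->dk", x, dK)
        self.grads["wv"] = np.einsum("btd,btk->dk", x, dV)
        return dQ @ wq.T + dK @ wk.T + dV @ wv.T


class _Flatten(_Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _ResidualFC(_Layer):
    """H(x) = x + W2 relu(W1 x + b1) + b2 on flat features."""

    def __init__(self, dim, hidden, rng):
        super().__init__()
        self.params = {
            "w1": rng.normal(0.0, math.sqrt(2.0 / dim), size=(dim, hidden)),
            "b1": np.zeros(hidden),
            # near-zero residual start: the block begins close to identity
            "w2": rng.normal(0.0, 1e-2, size=(hidden, dim)),
            "b2": np.zeros(dim),
        }

    def forward(self, x, train=True):
        self._x = x
        self._h = np.maximum(x @ self.params["w1"] + self.params["b1"], 0.0)
        return x + self._h @ self.params["w2"] + self.params["b2"]

    def backward(self, dout):
        x, h = self._x, self._h
        self.grads["w2"] = h.T @ dout
        self.grads["b2"] = dout.sum(axis=0)
        dh = (dout @ self.params["w2"].T) * (h > 0)
        self.grads["w1"] = x.T @ dh
        self.grads["b1"] = dh.sum(axis=0)
        return dout + dh @ self.params["w1"].T


class _Dense(_Layer):
    def __init__(self, d_in, d_out, rng, scale=None):
        super().__init__()
        scale = math.sqrt(2.0 / d_in) if scale is None else scale
        self.params = {
            "w": rng.normal(0.0, scale, size=(d_in, d_out)),
            "b": np.zeros(d_out),
        }

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T


# ---------------------------------------------------------------------------
# network


@dataclass
class NetworkConfig:
    """Hyper-parameters of the depth regressor."""

    learning_rate: float = 0.01
    activation: str = "relu"
    loss: str = "mse"
    attention_dk: int = 9
    seed: int = 0
    batch_size: int = 32
    accuracy_tol: float = 10.0
    attention: bool = True
    residual: bool = True
    head: str = "linear"  # or "softmax" over discretized depth classes
    n_depth_bins: int = 51  # softmax head: bin centers 0, 2, ..., 100
    grad_clip: float = 10.0
    residual_hidden: int = 64

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.head not in ("linear", "softmax"):
            raise ValueError(f"unknown head {self.head!r}")


class Network:
    """The full regressor: Table-row conv/pool stack + attention + residual."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.layers: list[_Layer] = [
            _Conv(1, 16, 3, 1, 1, rng), _ReLU(), _MaxPool2(),
            _Conv(16, 32, 3, 1, 1, rng), _ReLU(), _MaxPool2(),
            _Conv(32, 64, 3, 1, 1, rng), _ReLU(), _MaxPool2(),
        ]
        if c.attention:
            self.layers += [_TokensFromMaps(), _SelfAttention(9, c.attention_dk, rng)]
        self.layers.append(_Flatten())
        if c.residual:
            self.layers.append(_ResidualFC(IMAGE_SIZE, c.residual_hidden, rng))
        if c.head == "linear":
            self.layers.append(_Dense(IMAGE_SIZE, 1, rng, scale=0.01))
        else:
            self.layers.append(_Dense(IMAGE_SIZE, c.n_depth_bins, rng, scale=0.01))
        self._rng = rng

    # -- forward / backward ------------------------------------------------

    def _raw_forward(self, X, train=True):
        out = X
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def predict(self, X) -> np.ndarray:
        """Depth predictions in [0, 100] for X of shape (B, 24, 24)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        z = self._raw_forward(X[:, None, :, :], train=False)
        if self.config.head == "linear":
            return 100.0 * _sigmoid(z[:, 0])
        p = _softmax_rows(z)
        centers = np.linspace(0.0, 100.0, self.config.n_depth_bins)
        return p @ centers

    def loss_and_grads(self, X, y) -> float:
        """Mean loss over the batch; gradients left in each layer."""
        B = X.shape[0]
        z = self._raw_forward(X[:, None, :, :], train=True)
        if self.config.head == "linear":
            s = _sigmoid(z[:, 0])
            pred = 100.0 * s
            loss = float(np.mean((pred - y) ** 2))
            dpred = 2.0 * (pred - y) / B
            dz = (dpred * 100.0 * s * (1 - s))[:, None]
        else:
            p = _softmax_rows(z)
            centers = np.linspace(0.0, 100.0, self.config.n_depth_bins)
            target_bin = np.clip(
                np.round(y / 100.0 * (self.config.n_depth_bins - 1)).astype(int),
                0, self.config.n_depth_bins - 1,
            )
            loss = float(-np.mean(np.log(p[np.arange(B), target_bin] + 1e-12)))
            dz = p.copy()
            dz[np.arange(B), target_bin] -= 1.0
            dz /= B
            _ = centers
        dout = dz
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return loss

    def sgd_step(self) -> None:
        gs = [g for layer in self.layers for g in layer.grads.values()]
        norm = math.sqrt(sum(float(np.sum(g * g)) for g in gs)) if gs else 0.0
        clip = self.config.grad_clip
        scale = clip / norm if (clip and norm > clip) else 1.0
        lr = self.config.learning_rate
        for layer in self.layers:
            for k in layer.params:
                layer.params[k] -= lr * scale * layer.grads[k]

    # -- introspection -----------------------------------------------------

    def trace_shapes(self) -> list[tuple[str, tuple]]:
        """Layer-by-layer output shapes for one 1x24x24 input."""
        out = np.zeros((1, 1, IMAGE_SIDE, IMAGE_SIDE))
        trace = []
        for layer in self.layers:
            out = layer.forward(out, train=False)
            trace.append((type(layer).__name__.lstrip("_"), out.shape[1:]))
        return trace

    def get_weights(self) -> list[dict]:
        return [{k: v.copy() for k, v in layer.params.items()} for layer in self.layers]

    def set_weights(self, weights: list[dict]) -> None:
        for layer, w in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k] = w[k].copy()


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build_network(config: NetworkConfig | None = None) -> Network:
    """Instantiate the depth regressor from a config (defaults if None)."""
    return Network(config or NetworkConfig())


# ---------------------------------------------------------------------------
# autoencoder pretraining


def autoencoder_pretrain(
    samples, code_dim: int, epochs: int = 50, seed: int = 0
) -> dict:
    """Linear autoencoder y = f(x) = W_e x, x' = g(y) = W_d y.

    Trained by alternating least squares on centered flattened samples
    (each step solves one factor exactly, so reconstruction error is
    non-increasing).  Returns encoder/decoder weights, the data mean and
    the per-epoch reconstruction-error curve.
    """
    X = _sample_matrix(samples)
    n, D = X.shape
    if not (0 < code_dim < D):
        raise ValueError(f"code_dim must lie in (0, {D}), got {code_dim}")
    mu = X.mean(axis=0)
    Xc = X - mu
    rng = np.random.default_rng(seed)
    W_e = rng.normal(0.0, 1.0 / math.sqrt(D), size=(D, code_dim))
    W_d = np.zeros((code_dim, D))
    losses = [float(np.mean(Xc**2))]  # reconstruction by the zero decoder
    for _ in range(epochs):
        # decoder step: best W_d for the current codes
        Y = Xc @ W_e
        W_d = np.linalg.lstsq(Y, Xc, rcond=None)[0]
        # encoder step: codes that best explain Xc under W_d, then the
        # linear map producing them
        Z = np.linalg.lstsq(W_d.T, Xc.T, rcond=None)[0].T
        W_e = np.linalg.lstsq(Xc, Z, rcond=None)[0]
        recon = (Xc @ W_e) @ W_d
        losses.append(float(np.mean((Xc - recon) ** 2)))
    return {"encoder": W_e, "decoder": W_d, "mean": mu, "loss_curve": losses}


def _sample_matrix(samples) -> np.ndarray:
    if isinstance(samples, np.ndarray):
        return samples.reshape(samples.shape[0], -1).astype(float)
    return np.stack([s.flatten() for s in samples])


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainResult:
    """Loss curve and validation checkpoints for one fold (or one fit)."""

    fold: int
    losses: list = field(default_factory=list)
    checkpoints: list = field(default_factory=list)  # (iteration, acc %, rmse)
    final_accuracy: float = float("nan")
    final_rmse: float = float("nan")
    weights: list = None  # type: ignore[assignment]

    @property
    def n_iterations(self) -> int:
        return len(self.losses)


def _samples_to_arrays(samples):
    X = np.stack([s.pixels for s in samples])
    y = np.array([s.target for s in samples])
    subjects = np.array([s.subject_id for s in samples], dtype=object)
    return X, y, subjects


def fit_network(
    model: Network,
    train_samples,
    val_samples=None,
    n_iterations: int = 171,
    rng: np.random.Generator | None = None,
    fold: int = 0,
) -> TrainResult:
    """Minibatch SGD; validation accuracy/error checkpointed every 30 steps."""
    rng = rng or np.random.default_rng(model.config.seed)
    X, y, _ = _samples_to_arrays(train_samples)
    Xv = yv = None
    if val_samples:
        Xv, yv, _ = _samples_to_arrays(val_samples)
    result = TrainResult(fold=fold)
    bs = min(model.config.batch_size, len(y))
    for it in range(1, n_iterations + 1):
        idx = rng.choice(len(y), size=bs, replace=False)
        loss = model.loss_and_grads(X[idx], y[idx])
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at iteration {it}")
        model.sgd_step()
        result.losses.append(loss)
        if Xv is not None and it % CHECKPOINT_EVERY == 0:
            pred = model.predict(Xv)
            acc = float(np.mean(np.abs(pred - yv) <= model.config.accuracy_tol) * 100)
            err = float(np.sqrt(np.mean((pred - yv) ** 2)))
            result.checkpoints.append((it, acc, err))
    if Xv is not None:
        pred = model.predict(Xv)
        result.final_accuracy = float(
            np.mean(np.abs(pred - yv) <= model.config.accuracy_tol) * 100
        )
        result.final_rmse = float(np.sqrt(np.mean((pred - yv) ** 2)))
    result.weights = model.get_weights()
    return result


def train_model(
    samples,
    config: NetworkConfig | None = None,
    folds: int = 5,
    schedule: tuple[int, int] = (3, 57),
) -> list[TrainResult]:
    """Subject-level k-fold cross-validation training.

    ``schedule`` = (periods, iterations_per_period); each fold trains for
    periods x iterations_per_period SGD iterations with validation
    checkpoints every 30.  Fold results carry final validation accuracy and
    error so best and worst folds can be compared.
    """
    config = config or NetworkConfig()
    periods, iters = schedule
    if periods < 1 or iters < 1:
        raise ValueError("schedule must be positive (periods, iterations_per_period)")
    subjects = sorted({s.subject_id for s in samples})
    if len(subjects) < folds:
        raise ValueError(f"need at least {folds} subjects for {folds}-fold CV")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(subjects))
    assignment = {subjects[i]: int(f) for f, i in zip(
        np.arange(len(subjects)) % folds, order
    )}
    results = []
    for fold in range(folds):
        train = [s for s in samples if assignment[s.subject_id] != fold]
        val = [s for s in samples if assignment[s.subject_id] == fold]
        model = Network(config)
        fold_rng = np.random.default_rng([config.seed, fold])
        results.append(
            fit_network(
                model, train, val,
                n_iterations=periods * iters, rng=fold_rng, fold=fold,
            )
        )
    return results
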