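"""1-D convolutional encoder-decoder mapping six-axis windows to coordinates.

The regressor learns the strapdown reconstruction end to end: input is a
fixed-length window of the six body-frame channels (three angular velocities,
three accelerations), output the three calibrated position coordinates on the
same time base.  The architecture is an 11-convolution encoder-decoder, all
kernels of size 41: one input convolution to 64 filters, four encoder stages
(convolution doubling the filters, max-pool halving the length) up to 1024
filters, a 1024-filter bottleneck convolution, four decoder stages
(convolution halving the filters, nearest-neighbour unpooling doubling the
length) back to 64, and an output convolution to 3 channels.  Rectified-
linear activations follow every convolution except the last.

The network, its backpropagation and the Adam optimizer are implemented on
numpy: convolutions are lowered to patch-matrix multiplications (im2col), so
the heavy lifting runs in BLAS.  Training is fully deterministic for a fixed
seed.  Inputs are standardized per channel and targets per axis around a
pooled scale, so the mean-squared loss is an honest squared distance in
metres.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, ShapeError, TrainingError
from .trajectory import Trajectory

__all__ = [
    "CnnConfig",
    "CnnModel",
    "TrainingReport",
    "build_model",
    "train",
    "predict",
    "smooth",
    "rmse",
    "make_dataset",
]


@dataclass
class CnnConfig:
    """Architecture and training hyper-parameters.

    The filter ladder must double exactly from ``base_filters`` to
    ``max_filters`` over ``n_stages`` encoder stages (64 -> 1024 by default)
    and mirrors on the decoder side; the sequence length must be divisible by
    ``2**n_stages`` so pooling and unpooling restore the input length.
    """

    input_channels: int = 6
    output_channels: int = 3
    sequence_length: int = 1392
    kernel_size: int = 41
    base_filters: int = 64
    max_filters: int = 1024
    n_stages: int = 4
    epochs: int = 500
    batch_size: int = 8
    learning_rate: float = 1e-3
    lr_schedule: str = "cosine"  # or "constant"
    warmup_epochs: int = 2
    adam_beta2: float = 0.99
    clip_norm: float = 1.0
    batch_norm: bool = True
    bn_freeze_fraction: float = 0.3  # final fraction of epochs with frozen stats
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_filters * 2 ** self.n_stages != self.max_filters:
            raise ConfigError(
                f"filter ladder must double each stage: "
                f"{self.base_filters} * 2^{self.n_stages} != {self.max_filters}"
            )
        if self.sequence_length % (2 ** self.n_stages) != 0:
            raise ConfigError(
                f"sequence_length {self.sequence_length} not divisible by "
                f"{2 ** self.n_stages}; pad the window first"
            )
        if self.kernel_size % 2 != 1:
            raise ConfigError("kernel_size must be odd")

    @property
    def n_conv_layers(self) -> int:
        # input conv + encoder stages + bottleneck + decoder stages + output conv
        return 2 * self.n_stages + 3

    def filter_sizes(self) -> list[tuple[int, int]]:
        """(in, out) channel pairs of the convolutions, in order."""
        enc = [self.base_filters * 2 ** i for i in range(self.n_stages + 1)]
        pairs = [(self.input_channels, enc[0])]
        pairs += list(zip(enc[:-1], enc[1:]))
        pairs.append((enc[-1], enc[-1]))
        dec = enc[::-1]
        pairs += list(zip(dec[:-1], dec[1:]))
        pairs.append((enc[0], self.output_channels))
        return pairs


# --------------------------------------------------------------- layer cores
# activations are carried channels-last, shape (batch, length, channels)


class _BufferPool:
    """Reusable float32 scratch arrays keyed by shape.

    Training repeatedly needs multi-megabyte patch matrices; allocating them
    afresh every step hands the pages back to the OS and the resulting fault
    churn dominates the BLAS time, so each layer keeps its buffers alive.
    """

    def __init__(self) -> None:
        self._store: dict[tuple, np.ndarray] = {}

    def get(self, name: str, shape: tuple) -> np.ndarray:
        key = (name, shape)
        buf = self._store.get(key)
        if buf is None:
            buf = np.empty(shape, dtype=np.float32)
            self._store[key] = buf
        return buf

    def clear(self) -> None:
        self._store.clear()


def _im2col(x: np.ndarray, K: int, pool: _BufferPool | None = None) -> np.ndarray:
    """Patch matrix of a same-padded 1-D window; x (B, L, C) -> (B*L, C*K).

    The batch is flattened into the GEMM rows so the (possibly huge) weight
    matrix is streamed once per multiplication rather than once per item.
    """
    B, L, C = x.shape
    p = K // 2
    if pool is None:
        pool = _BufferPool()
    xpad = pool.get("xpad", (B, L + 2 * p, C))
    xpad[:, :p, :] = 0.0
    xpad[:, p : p + L, :] = x
    xpad[:, p + L :, :] = 0.0
    view = np.lib.stride_tricks.sliding_window_view(xpad, K, axis=1)  # (B, L, C, K)
    S = pool.get("S", (B, L, C, K))
    np.copyto(S, view)
    return S.reshape(B * L, C * K)


def _conv_forward(
    S: np.ndarray, W: np.ndarray, b: np.ndarray, B: int, L: int,
    pool: _BufferPool | None = None,
) -> np.ndarray:
    """Same-padded convolution from the patch matrix; returns (B, L, O)."""
    O = W.shape[0]
    if pool is None:
        y = S @ W.reshape(O, -1).T
    else:
        y = np.matmul(S, W.reshape(O, -1).T, out=pool.get("y", (S.shape[0], O)))
    y += b
    return y.reshape(B, L, O)


def _conv_backward(
    S: np.ndarray,
    shape: tuple[int, int, int],
    W: np.ndarray,
    dy: np.ndarray,
    pool: _BufferPool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dW, db) of the same-padded convolution.

    ``S`` is the patch matrix cached by the forward pass; dx is recovered by
    folding the column gradient back over the overlapping windows (col2im),
    which avoids materializing a flipped copy of the weights.  The column
    gradient overwrites the patch buffer, which is dead after dW.
    """
    B, L, C = shape
    O, _, K = W.shape
    p = K // 2
    dY2 = dy.reshape(B * L, O)
    dW = np.matmul(dY2.T, S, out=pool.get("dW", (O, C * K))).reshape(O, C, K)
    db = dY2.sum(axis=0)
    dcol = np.matmul(dY2, W.reshape(O, C * K), out=S).reshape(B, L, C, K)
    dxpad = pool.get("dxpad", (B, L + 2 * p, C))
    dxpad[:] = 0.0
    for k in range(K):
        dxpad[:, k : k + L, :] += dcol[:, :, :, k]
    return dxpad[:, p : p + L, :], dW, db


class _Conv:
    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, k: int,
                 relu: bool, init_gain: float = 1.0) -> None:
        scale = init_gain * np.sqrt(2.0 / (c_in * k))
        self.W = rng.normal(0.0, scale, (c_out, c_in, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.relu = relu
        self._S = None
        self._pool = _BufferPool()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, _ = x.shape
        S = _im2col(x, self.W.shape[2], self._pool)
        if train:
            self._S, self._shape = S, x.shape
        y = _conv_forward(S, self.W, self.b, B, L, self._pool)
        if self.relu:
            np.maximum(y, 0.0, out=y)
        if train:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * (self._y > 0)
        dx, self.dW, self.db = _conv_backward(
            self._S, self._shape, self.W, dy, self._pool
        )
        self._S = self._y = None
        return dx

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _BatchNorm:
    """Per-channel batch normalization over (batch, position).

    A training aid the architecture statement leaves open: it removes the
    scale imbalance between the deep 1024-filter stages and the narrow ends,
    which otherwise slows the optimizer to a crawl on CPU-sized budgets.
    Batch statistics are used during training, running averages at inference.
    """

    def __init__(self, channels: int, momentum: float = 0.1) -> None:
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = 1e-5
        #: frozen: use running statistics even in training (final fine-tune
        #: phase); removes the batch-statistic noise floor of small batches
        self.frozen = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train and self.frozen:
            inv = (1.0 / np.sqrt(self.run_var + self.eps)).astype(np.float32)
            xh = (x - self.run_mean) * inv
            self._xh, self._inv = xh, None  # None marks the frozen path
            return self.gamma * xh + self.beta
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xh = (x - mean) * inv
            self._xh, self._inv = xh, inv.astype(np.float32)
            return self.gamma * xh + self.beta
        inv = 1.0 / np.sqrt(self.run_var + self.eps)
        return self.gamma * ((x - self.run_mean) * inv) + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xh, inv = self._xh, self._inv
        n = dy.shape[0] * dy.shape[1]
        self.dgamma = (dy * xh).sum(axis=(0, 1))
        self.dbeta = dy.sum(axis=(0, 1))
        dxh = dy * self.gamma
        if inv is None:  # frozen: the normalization is a fixed affine map
            run_inv = 1.0 / np.sqrt(self.run_var + self.eps)
            dx = dxh * run_inv
        else:
            dx = (inv / n) * (
                n * dxh - dxh.sum(axis=(0, 1)) - xh * (dxh * xh).sum(axis=(0, 1))
            )
        self._xh = None
        return dx.astype(np.float32)

    def params_grads(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy * (self._y > 0)
        self._y = None
        return dy

    def params_grads(self):
        return []


class _MaxPool2:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        xr = x.reshape(B, L // 2, 2, C)
        idx = xr.argmax(axis=2)
        if train:
            self._idx, self._shape = idx, xr.shape
        return np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dxr = np.zeros(self._shape, dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        return dxr.reshape(self._shape[0], self._shape[1] * 2, self._shape[3])

    def params_grads(self):
        return []


class _Unpool2:
    """Nearest-neighbour unpooling: each sample is duplicated once."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return np.repeat(x, 2, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L2, C = dy.shape
        return dy.reshape(B, L2 // 2, 2, C).sum(axis=2)

    def params_grads(self):
        return []


class CnnModel:
    """The assembled network plus input/target normalization state."""

    def __init__(self, config: CnnConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel_size
        pairs = config.filter_sizes()
        self.layers: list = []
        self.conv_layers: list[_Conv] = []

        self.bn_layers: list[_BatchNorm] = []

        def add_conv(c_in, c_out, relu=True, init_gain=1.0):
            if relu and config.batch_norm:
                conv = _Conv(rng, c_in, c_out, k, relu=False, init_gain=init_gain)
                self.layers.append(conv)
                self.conv_layers.append(conv)
                bn = _BatchNorm(c_out)
                self.bn_layers.append(bn)
                self.layers.append(bn)
                self.layers.append(_ReLU())
            else:
                conv = _Conv(rng, c_in, c_out, k, relu, init_gain)
                self.layers.append(conv)
                self.conv_layers.append(conv)

        i = 0
        add_conv(*pairs[i]); i += 1                      # input conv
        for _ in range(config.n_stages):                 # encoder
            add_conv(*pairs[i]); i += 1
            self.layers.append(_MaxPool2())
        add_conv(*pairs[i]); i += 1                      # bottleneck
        for _ in range(config.n_stages):                 # decoder
            add_conv(*pairs[i]); i += 1
            self.layers.append(_Unpool2())
        # small-gain output layer: the untrained network predicts (nearly)
        # the training-mean trajectory, a safe starting point for residual
        # target learning
        add_conv(*pairs[i], relu=False, init_gain=0.01)  # output conv

        # identity normalization until fit on data; targets are centred by
        # the per-position training-mean trajectory so capacity is spent on
        # per-subject deviations, not on the ramp every walk shares
        self.x_mean = np.zeros(config.input_channels, dtype=np.float32)
        self.x_std = np.ones(config.input_channels, dtype=np.float32)
        self.y_mean = np.zeros(
            (config.sequence_length, config.output_channels), dtype=np.float32
        )
        self.y_scale = 1.0

    # -- bookkeeping ---------------------------------------------------------
    @property
    def n_params(self) -> int:
        total = sum(conv.W.size + conv.b.size for conv in self.conv_layers)
        total += sum(bn.gamma.size + bn.beta.size for bn in self.bn_layers)
        return total

    def encoder_decoder_filters(self) -> tuple[list[int], list[int]]:
        """Output channel counts of encoder-side and decoder-side convolutions."""
        n = self.config.n_stages
        sizes = [conv.W.shape[0] for conv in self.conv_layers]
        return sizes[1 : n + 1], sizes[n + 2 : 2 * n + 2]

    # -- compute -------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def predict_raw(self, x_std: np.ndarray) -> np.ndarray:
        """Forward pass on standardized input, returning standardized output."""
        return self.forward(x_std.astype(np.float32), train=False)

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        """Self-describing checkpoint: config as JSON plus the weight arrays."""
        arrays = {}
        for i, conv in enumerate(self.conv_layers):
            arrays[f"W{i}"] = conv.W
            arrays[f"b{i}"] = conv.b
        for i, bn in enumerate(self.bn_layers):
            arrays[f"bn_gamma{i}"] = bn.gamma
            arrays[f"bn_beta{i}"] = bn.beta
            arrays[f"bn_mean{i}"] = bn.run_mean
            arrays[f"bn_var{i}"] = bn.run_var
        arrays["x_mean"], arrays["x_std"] = self.x_mean, self.x_std
        arrays["y_mean"] = self.y_mean
        arrays["y_scale"] = np.float32(self.y_scale)
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "CnnModel":
        with np.load(path) as data:
            cfg = CnnConfig(**json.loads(bytes(data["config_json"].tobytes()).decode()))
            model = cls(cfg)
            for i, conv in enumerate(model.conv_layers):
                conv.W = data[f"W{i}"]
                conv.b = data[f"b{i}"]
            for i, bn in enumerate(model.bn_layers):
                bn.gamma = data[f"bn_gamma{i}"]
                bn.beta = data[f"bn_beta{i}"]
                bn.run_mean = data[f"bn_mean{i}"]
                bn.run_var = data[f"bn_var{i}"]
            model.x_mean = data["x_mean"]
            model.x_std = data["x_std"]
            model.y_mean = data["y_mean"]
            model.y_scale = float(data["y_scale"])
        return model


def build_model(config: CnnConfig | None = None, **kwargs) -> CnnModel:
    """Construct the 11-convolution encoder-decoder for a configuration."""
    if config is None:
        config = CnnConfig(**kwargs)
    return CnnModel(config)


@dataclass
class TrainingReport:
    """Per-epoch losses (mean squared error, m^2) and held-out RMSE (m)."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    test_rmse: float = float("nan")
    baseline_rmse: float = float("nan")


def _clip_gradients(params_grads, max_norm: float) -> None:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for _, g in params_grads:
        flat = g.ravel()
        total += float(np.dot(flat, flat))
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = np.float32(max_norm / norm)
        for _, g in params_grads:
            g *= scale


class _Adam:
    def __init__(self, params_grads_fn, lr: float, beta2: float = 0.999) -> None:
        self.fn = params_grads_fn
        self.lr = lr
        self.beta2 = beta2
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, self.beta2, 1e-8
        # bias-corrected step size folded into the learning rate, with a
        # reusable scratch buffer so the update allocates nothing
        lr_t = self.lr * np.sqrt(1.0 - b2 ** self.t) / (1.0 - b1 ** self.t)
        for i, (p, g) in enumerate(self.fn()):
            if i not in self.state:
                self.state[i] = (np.zeros_like(p), np.zeros_like(p), np.empty_like(p))
            m, v, buf = self.state[i]
            m *= b1
            np.multiply(g, 1 - b1, out=buf)
            m += buf
            v *= b2
            np.square(g, out=buf)
            buf *= 1 - b2
            v += buf
            np.sqrt(v, out=buf)
            buf += eps
            np.divide(m, buf, out=buf)
            buf *= lr_t
            p -= buf


def train(
    model: CnnModel,
    dataset: tuple[np.ndarray, np.ndarray],
    split: float = 0.2,
    epochs: int | None = None,
    seed: int = 0,
) -> TrainingReport:
    """Fit the model on (windows, coordinate labels) pairs.

    ``dataset`` is ``(X, Y)`` with X shaped (n, 6, L) and Y (n, 3, L) in the
    conventional channels-first layout.  A fraction ``split`` is held out for
    validation; the report carries per-epoch train/validation MSE in m^2 and
    the final held-out RMSE in metres, next to the RMSE of the train-mean
    predictor on the same held-out windows.  Deterministic for fixed seeds.
    """
    X, Y = dataset
    X = np.asarray(X, dtype=np.float32)
    Y = np.asarray(Y, dtype=np.float32)
    if X.ndim != 3 or Y.ndim != 3 or X.shape[0] != Y.shape[0]:
        raise TrainingError("dataset must be (n, 6, L) windows with (n, 3, L) labels")
    n = X.shape[0]
    if n < 2:
        raise TrainingError(f"need >= 2 entries to train, got {n}")
    cfg = model.config
    if X.shape[1] != cfg.input_channels or X.shape[2] != cfg.sequence_length:
        raise ShapeError(
            f"windows {X.shape[1:]} do not match config "
            f"({cfg.input_channels}, {cfg.sequence_length})"
        )
    epochs = cfg.epochs if epochs is None else epochs

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(split * n))) if split > 0 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if tr_idx.size == 0:
        raise TrainingError("empty training split")

    # channels-last activations
    Xt = X.transpose(0, 2, 1)
    Yt = Y.transpose(0, 2, 1)
    model.x_mean = Xt[tr_idx].mean(axis=(0, 1))
    model.x_std = Xt[tr_idx].std(axis=(0, 1)) + 1e-8
    model.y_mean = Yt[tr_idx].mean(axis=0)  # per position and axis
    model.y_scale = float(np.sqrt(((Yt[tr_idx] - model.y_mean) ** 2).mean()) + 1e-8)

    Xn = (Xt - model.x_mean) / model.x_std
    Yn = (Yt - model.y_mean) / model.y_scale

    def params_grads():
        out = []
        for layer in model.layers:
            out.extend(layer.params_grads())
        return out

    opt = _Adam(params_grads, cfg.learning_rate, beta2=cfg.adam_beta2)
    report = TrainingReport()
    scale2 = model.y_scale ** 2

    freeze_at = int(np.floor(epochs * (1.0 - cfg.bn_freeze_fraction)))
    for epoch in range(epochs):
        if cfg.batch_norm and epoch == freeze_at:
            for bn in model.bn_layers:
                bn.frozen = True
        if epoch < cfg.warmup_epochs:
            opt.lr = cfg.learning_rate * (epoch + 1) / (cfg.warmup_epochs + 1)
        elif cfg.lr_schedule == "cosine":
            opt.lr = cfg.learning_rate * 0.5 * (1.0 + np.cos(np.pi * epoch / epochs))
        else:
            opt.lr = cfg.learning_rate
        perm = rng.permutation(tr_idx)
        ep_loss = 0.0
        for start in range(0, perm.size, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = Xn[idx], Yn[idx]
            pred = model.forward(xb, train=True)
            err = pred - yb
            ep_loss += float((err ** 2).mean()) * idx.size
            model.backward(2.0 * err / err.size)
            if cfg.clip_norm > 0:
                _clip_gradients(params_grads(), max_norm=cfg.clip_norm)
            opt.step()
        report.train_loss.append(ep_loss / perm.size * scale2)
        if n_val:
            pv = model.forward(Xn[val_idx], train=False)
            report.val_loss.append(float(((pv - Yn[val_idx]) ** 2).mean()) * scale2)

    if n_val:
        pv = model.forward(Xn[val_idx], train=False)
        resid = (pv - Yn[val_idx]) * model.y_scale
        report.test_rmse = float(np.sqrt((resid ** 2).mean()))
        mean_pred = Yt[tr_idx].mean(axis=0)
        report.baseline_rmse = float(
            np.sqrt(((Yt[val_idx] - mean_pred) ** 2).mean())
        )
    return report


def predict(
    model: CnnModel, window: np.ndarray, t: np.ndarray | None = None
) -> Trajectory:
    """Map one six-axis window (6, L) to a coordinate trajectory.

    Windows shorter or longer than the configured length are symmetrically
    zero-padded or center-cropped for the forward pass and the output is cut
    back to the input length.  ``t`` defaults to a unit-rate sample index.
    """
    window = np.asarray(window, dtype=np.float32)
    cfg = model.config
    if window.ndim != 2 or window.shape[0] != cfg.input_channels:
        raise ShapeError(
            f"window must be ({cfg.input_channels}, L), got {window.shape}"
        )
    L = window.shape[1]
    target = cfg.sequence_length
    if L < target:
        lo = (target - L) // 2
        padded = np.zeros((cfg.input_channels, target), dtype=np.float32)
        padded[:, lo : lo + L] = window
        sl = slice(lo, lo + L)
    elif L > target:
        lo = (L - target) // 2
        padded = window[:, lo : lo + target]
        sl = slice(0, target)
    else:
        padded, sl = window, slice(0, L)

    xn = (padded.T[None] - model.x_mean) / model.x_std
    out = model.forward(xn.astype(np.float32), train=False)[0]
    coords = (out * model.y_scale + model.y_mean).T[:, sl]
    if L > target:  # re-embed the cropped center into the full span
        full = np.full((cfg.output_channels, L), np.nan, dtype=np.float32)
        full[:, lo : lo + target] = coords
        coords = full
        coords = np.where(np.isnan(coords), 0.0, coords)
    if t is None:
        t = np.arange(L, dtype=float)
    return Trajectory(
        t=np.asarray(t, float),
        x=coords[0].astype(float),
        y=coords[1].astype(float),
        z=coords[2].astype(float),
        pitch=np.zeros(L),
        calibrated=True,
    )


def smooth(series: np.ndarray, halfwidth: int = 10) -> np.ndarray:
    """Centred moving average over ``2*halfwidth + 1`` points.

    Edges average over the shorter window that fits, so constants pass
    through unchanged everywhere.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ShapeError("smooth expects a 1-D series")
    w = 2 * halfwidth + 1
    kernel = np.ones(w)
    num = np.convolve(series, kernel, mode="same")
    den = np.convolve(np.ones_like(series), kernel, mode="same")
    return num / den


def rmse(pred, truth) -> float:
    """Root-mean-square error pooled over axes and samples, in metres."""
    a = pred.xyz if isinstance(pred, Trajectory) else np.asarray(pred, float)
    b = truth.xyz if isinstance(truth, Trajectory) else np.asarray(truth, float)
    if a.shape != b.shape:
        raise ShapeError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def make_dataset(
    sessions, side: str = "right", length: int = 96, duration_s: float = 16.0
) -> tuple[np.ndarray, np.ndarray]:
    """Resample simulated sessions into fixed-length training windows.

    Each session contributes one window covering a fixed ``duration_s`` span
    from the start of the recording at a fixed (decimated) rate — a shared
    time base keeps the acceleration-to-position integral well-posed across
    subjects walking at different speeds.  The six body-frame channels are
    anti-alias averaged before decimation; labels are the ground-truth
    coordinates at the same instants.  Recordings shorter than the span are
    edge-extended (the subject stands still at the lane end).  Returns
    (X, Y) with shapes (n, 6, length) and (n, 3, length).
    """
    from scipy.ndimage import uniform_filter1d

    Xs, Ys = [], []
    tq_rel = np.linspace(0.0, duration_s, length)
    for sess in sessions:
        rec = getattr(sess.session, side)
        truth = getattr(sess, f"truth_{side}")
        t = rec.t
        tq = t[0] + tq_rel
        decim = max(1, int(np.ceil((tq_rel[1] - tq_rel[0]) / (t[1] - t[0]))))
        chans = []
        for arr in (rec.six_axis.gyro.T, rec.six_axis.acc.T):
            for ch in arr:
                smoothed = uniform_filter1d(ch, size=decim, mode="nearest")
                chans.append(np.interp(tq, t, smoothed))
        Xs.append(np.stack(chans))
        Ys.append(
            np.stack(
                [np.interp(tq, truth.t, getattr(truth, ax)) for ax in ("x", "y", "z")]
            )
        )
    return np.stack(Xs), np.stack(Ys)
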