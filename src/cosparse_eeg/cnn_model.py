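"""1D convolutional network for segment classification, in NumPy.

Architecture: four blocks of conv -> batch-norm -> ReLU -> dropout ->
max-pool, with (filters, kernel) = (20, 60), (40, 40), (60, 20), (80, 10),
stride 1, pool 2/2, followed by fully connected layers of width 64, 32 and 2
with a softmax head.  Per-block symmetric padding (30, 10, 7, 2) gives, for a
178-sample input, conv output lengths 179/70/30/10 and floor-mode pooled
lengths 89/35/15/5 (the published per-layer map sizes are mutually
inconsistent under any single padding/rounding convention; the first block is
reproduced exactly and the rest follow deterministically).

Training minimizes cross-entropy by backpropagation with Adam
(defaults: learning rate 1e-4, beta1 0.5, beta2 0.55, batch 200, 250 epochs).
Dropout is active only in training; inference is deterministic.

The module also carries small reference implementations of the three formula
primitives — direct-summation convolution s(t) = sum_a x(a) w(t-a), a
batch-normalization variant whose scale term is delta + mean squared
deviation (no square root; the trainable network uses standard BN with a
square root and eps = 1e-5), and a shift-invariant softmax — used as oracles
against the network's layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reference formula implementations (oracles)


def conv1d_reference(x: np.ndarray, w: np.ndarray, padding: int = 0) -> np.ndarray:
    """Direct-summation 1D convolution: s(t) = sum_a x(a) w(t - a).

    Output length is len(x) + 2*padding - len(w) + 1.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if padding > 0:
        x = np.concatenate([np.zeros(padding), x, np.zeros(padding)])
    n, k = len(x), len(w)
    out_len = n - k + 1
    if out_len < 1:
        raise ValueError(
            f"kernel of length {k} longer than padded input of length {n}")
    out = np.zeros(out_len)
    for t in range(out_len):
        acc = 0.0
        for a in range(k):
            acc += x[t + a] * w[k - 1 - a]   # w(t - a) with t anchored at k-1
        out[t] = acc
    return out


def batch_norm_reference(H: np.ndarray, delta: float = 1e-8) -> np.ndarray:
    """Normalize a batch with sigma = delta + mean((H - mu)^2) (as printed,
    without a square root): H' = (H - mu) / sigma.  Output batch mean is 0
    regardless of sigma."""
    H = np.asarray(H, dtype=float)
    if H.shape[0] < 2:
        raise ValueError("batch size must be >= 2")
    if not delta > 0:
        raise ValueError("delta must be > 0")
    mu = H.mean(axis=0)
    sigma = delta + np.mean((H - mu) ** 2, axis=0)
    return (H - mu) / sigma


def softmax_reference(scores: np.ndarray) -> np.ndarray:
    """Exp-normalized probabilities, computed shift-invariantly."""
    s = np.asarray(scores, dtype=float)
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# architecture


@dataclass(frozen=True)
class CNNArchitecture:
    """Four conv blocks + three FC layers; defaults mirror the fixed design."""

    filters: tuple[int, ...] = (20, 40, 60, 80)
    kernels: tuple[int, ...] = (60, 40, 20, 10)
    paddings: tuple[int, ...] = (30, 10, 7, 2)
    pool: int = 2
    pool_stride: int = 2
    fc_widths: tuple[int, ...] = (64, 32, 2)
    #: dropout after the FC ReLUs; convolutional blocks use the (milder)
    #: conv_dropout — heavy dropout on early feature maps slows learning
    #: far more than it regularizes at the epoch budgets this package runs.
    dropout: float = 0.3
    conv_dropout: float = 0.1

    def __post_init__(self) -> None:
        if not (len(self.filters) == len(self.kernels) == len(self.paddings)):
            raise ValueError("filters/kernels/paddings must align")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 <= self.conv_dropout < 1.0:
            raise ValueError("conv_dropout must be in [0, 1)")

    def layer_shapes(self, input_length: int) -> list[tuple[str, int, int]]:
        """(layer name, channels, length) after each conv and pool stage."""
        shapes = []
        length, channels = input_length, 1
        for b, (f, k, p) in enumerate(zip(self.filters, self.kernels,
                                          self.paddings), start=1):
            conv_len = length + 2 * p - k + 1
            if conv_len < 1:
                raise ValueError(
                    f"input too short: block {b} conv output would be "
                    f"{conv_len}; minimal input length is "
                    f"{self.min_input_length()}")
            pool_len = (conv_len - self.pool) // self.pool_stride + 1
            if pool_len < 1:
                raise ValueError(
                    f"input too short: block {b} pooled output would be "
                    f"empty; minimal input length is "
                    f"{self.min_input_length()}")
            shapes.append((f"conv{b}", f, conv_len))
            shapes.append((f"pool{b}", f, pool_len))
            length, channels = pool_len, f
        return shapes

    def flat_dim(self, input_length: int) -> int:
        name, c, l = self.layer_shapes(input_length)[-1]
        return c * l

    def min_input_length(self, limit: int = 8192) -> int:
        for L in range(1, limit):
            try:
                self._shapes_nocheck(L)
            except ValueError:
                continue
            return L
        raise ValueError("no valid input length below limit")

    def _shapes_nocheck(self, input_length: int) -> None:
        length = input_length
        for f, k, p in zip(self.filters, self.kernels, self.paddings):
            conv_len = length + 2 * p - k + 1
            if conv_len < 1:
                raise ValueError("too short")
            pool_len = (conv_len - self.pool) // self.pool_stride + 1
            if pool_len < 1:
                raise ValueError("too short")
            length = pool_len


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.55
    batch_size: int = 200
    epochs: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# layers


_DTYPE = np.float32


class _Conv1d:
    """True convolution (kernel reversed relative to cross-correlation),
    stride 1, symmetric zero padding; im2col matmul implementation.

    Parameters and activations are single precision: the network is
    matmul-bound and float32 halves its run time at no cost to the
    classification task."""

    def __init__(self, in_ch, out_ch, kernel, padding, rng):
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.W = (rng.standard_normal((out_ch, in_ch, kernel)) * scale
                  ).astype(_DTYPE)
        self.b = np.zeros(out_ch, dtype=_DTYPE)
        self.kernel = kernel
        self.padding = padding

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x, train):
        B, C, L = x.shape
        p, k = self.padding, self.kernel
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        Lout = xp.shape[2] - k + 1
        if Lout < 1:
            raise ValueError("kernel longer than padded input")
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        # (B, C, Lout, k) -> (B*Lout, C*k)
        cols = win.transpose(0, 2, 1, 3).reshape(B * Lout, C * k)
        Wcol = self.W[:, :, ::-1].reshape(self.W.shape[0], C * k).T
        out = cols @ Wcol + self.b
        self._cache = (cols, x.shape, Lout)
        return out.reshape(B, Lout, -1).transpose(0, 2, 1)

    def backward(self, dout):
        cols, xshape, Lout = self._cache
        B, C, L = xshape
        k, p = self.kernel, self.padding
        out_ch = self.W.shape[0]
        dcol = dout.transpose(0, 2, 1).reshape(B * Lout, out_ch)
        self.db = dcol.sum(axis=0)
        dWcol = cols.T @ dcol                      # (C*k, out_ch)
        self.dW = dWcol.T.reshape(out_ch, C, k)[:, :, ::-1]
        Wcol = self.W[:, :, ::-1].reshape(out_ch, C * k).T
        dcols = dcol @ Wcol.T                      # (B*Lout, C*k)
        dwin = dcols.reshape(B, Lout, C, k)
        # scatter-add windows in (batch, position, channel) layout so every
        # slice addition below is cache-friendly
        dxp_t = np.zeros((B, L + 2 * p, C), dtype=dout.dtype)
        for j in range(k):
            dxp_t[:, j:j + Lout, :] += dwin[:, :, :, j]
        dxp = dxp_t.transpose(0, 2, 1)
        return dxp[:, :, p:p + L] if p else dxp

    def grads(self):
        return [("W", self.dW), ("b", self.db)]


class _BatchNorm1d:
    """Per-channel batch norm over (batch, length); standard sqrt form."""

    def __init__(self, channels, eps=1e-5, momentum=0.1):
        self.gamma = np.ones(channels, dtype=_DTYPE)
        self.beta = np.zeros(channels, dtype=_DTYPE)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(_DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(_DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dout):
        xhat, inv, shape = self._cache
        B, C, L = shape
        m = B * L
        self.dgamma = np.sum(dout * xhat, axis=(0, 2))
        self.dbeta = np.sum(dout, axis=(0, 2))
        dxhat = dout * self.gamma[None, :, None]
        dx = (inv[None, :, None] / m) * (
            m * dxhat
            - np.sum(dxhat, axis=(0, 2), keepdims=True)
            - xhat * np.sum(dxhat * xhat, axis=(0, 2), keepdims=True))
        return dx

    def grads(self):
        return [("gamma", self.dgamma), ("beta", self.dbeta)]


class _ReLU:
    def params(self):
        return []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def grads(self):
        return []


class _Dropout:
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng

    def params(self):
        return []

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.uniform(size=x.shape) < keep) / keep
                      ).astype(x.dtype)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def grads(self):
        return []


class _MaxPool1d:
    def __init__(self, size=2, stride=2):
        if size != stride:
            raise NotImplementedError("pool size must equal stride")
        self.size = size

    def params(self):
        return []

    def forward(self, x, train):
        B, C, L = x.shape
        s = self.size
        Lo = L // s
        xr = x[:, :, :Lo * s].reshape(B, C, Lo, s)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dout):
        B, C, L = self._shape
        s = self.size
        Lo = L // s
        dx = np.zeros((B, C, Lo, s), dtype=dout.dtype)
        idx = np.indices((B, C, Lo))
        dx[idx[0], idx[1], idx[2], self._arg] = dout
        return dx.reshape(B, C, Lo * s) if Lo * s == L else np.pad(
            dx.reshape(B, C, Lo * s), ((0, 0), (0, 0), (0, L - Lo * s)))

    def grads(self):
        return []


class _Flatten:
    def params(self):
        return []

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def grads(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
                  ).astype(_DTYPE)
        self.b = np.zeros(n_out, dtype=_DTYPE)

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def grads(self):
        return [("W", self.dW), ("b", self.db)]


class _DropoutFC(_Dropout):
    pass


# ---------------------------------------------------------------------------
# network


class CNN1D:
    """The stacked network; ``train_mode`` toggles dropout and BN statistics."""

    def __init__(self, arch: CNNArchitecture, input_length: int, seed: int = 0):
        self.arch = arch
        self.input_length = input_length
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)
        arch.layer_shapes(input_length)  # validates the length
        self.layers = []
        in_ch = 1
        for f, k, p in zip(arch.filters, arch.kernels, arch.paddings):
            self.layers += [
                _Conv1d(in_ch, f, k, p, rng),
                _BatchNorm1d(f),
                _ReLU(),
                _Dropout(arch.conv_dropout, self._dropout_rng),
                _MaxPool1d(arch.pool, arch.pool_stride),
            ]
            in_ch = f
        self.layers.append(_Flatten())
        n_in = arch.flat_dim(input_length)
        for i, width in enumerate(arch.fc_widths):
            self.layers.append(_Dense(n_in, width, rng))
            if i < len(arch.fc_widths) - 1:
                self.layers.append(_ReLU())
                self.layers.append(_Dropout(arch.dropout, self._dropout_rng))
            n_in = width

    # -- plumbing

    def parameters(self):
        """Flat list of (layer, name, array) triples."""
        out = []
        for layer in self.layers:
            for name, arr in layer.params():
                out.append((layer, name, arr))
        return out

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [arr for _, _, arr in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, _BatchNorm1d):
                arrays += [layer.running_mean, layer.running_var]
        return arrays

    def copy_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class scores (logits) for segments x of shape (B, L)."""
        h = np.asarray(x, dtype=_DTYPE)[:, None, :]
        if h.shape[2] != self.input_length:
            raise ValueError(
                f"segment length {h.shape[2]} != build length "
                f"{self.input_length}")
        for layer in self.layers:
            h = layer.forward(h, train)
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax_reference(self.forward(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)


def build_network(arch: CNNArchitecture, input_length: int,
                  seed: int = 0) -> CNN1D:
    """Construct the network and log its per-layer output shapes."""
    net = CNN1D(arch, input_length, seed)
    for name, c, l in arch.layer_shapes(input_length):
        logger.info("%s: %d x %d", name, l, c)
    logger.info("flatten: %d; fc: %s", arch.flat_dim(input_length),
                arch.fc_widths)
    return net


def _cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    p = softmax_reference(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), y] + eps))
    grad = p.astype(logits.dtype)
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / np.asarray(n, dtype=logits.dtype)


class _Adam:
    def __init__(self, params, lr, beta1, beta2, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(arr, dtype=np.float64)
                  for _, _, arr in params]
        self.v = [np.zeros_like(arr, dtype=np.float64)
                  for _, _, arr in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (layer, name, arr) in enumerate(self.params):
            grad = dict(layer.grads())[name].astype(np.float64)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * grad ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            arr -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)
                    ).astype(arr.dtype)


def train(net: CNN1D, segments: np.ndarray, labels: np.ndarray,
          config: TrainConfig, class_order: list | None = None,
          ) -> tuple[CNN1D, list[float]]:
    """Minimize cross-entropy with Adam; returns the net and per-epoch loss.

    ``labels`` may be strings; classes are mapped to indices in sorted order
    (or ``class_order``).  Inputs are standardized per segment.  With
    ``epochs == 0`` the model is returned untouched and the trace is empty.
    """
    segments = np.asarray(segments, dtype=float)
    labels = np.asarray(labels)
    classes = class_order or sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes present to train")
    y = np.searchsorted(np.asarray(classes), labels)
    X = standardize_segments(segments)
    rng = np.random.default_rng(config.seed)
    opt = _Adam(net.parameters(), config.learning_rate, config.beta1,
                config.beta2)
    trace: list[float] = []
    n = X.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if idx.size < 2:
                continue  # BN needs >= 2 samples; shuffling makes this rare
            logits = net.forward(X[idx], train=True)
            loss, dlogits = _cross_entropy(logits, y[idx])
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)) if losses else float("nan"))
    net.classes_ = list(classes)
    return net, trace


def standardize_segments(segments: np.ndarray) -> np.ndarray:
    """Per-segment z-scoring (constant segments map to zero)."""
    segments = np.asarray(segments, dtype=float)
    mu = segments.mean(axis=1, keepdims=True)
    sd = segments.std(axis=1, keepdims=True)
    return (segments - mu) / np.where(sd > 0, sd, 1.0)


def predict(net: CNN1D, segments: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and class probabilities for new segments (eval mode)."""
    X = standardize_segments(segments)
    proba = net.predict_proba(X)
    idx = np.argmax(proba, axis=1)
    classes = getattr(net, "classes_", list(range(proba.shape[1])))
    labels = np.asarray([classes[i] for i in idx])
    return labels, proba
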