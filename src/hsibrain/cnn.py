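"""Patch-based 3D convolutional classifier, implemented in NumPy.

The network classifies a hyperspectral pixel from the 9x9x25 patch centered
on it.  Architecture (shape trace for the default configuration):

    input  9x9x25x1
    conv3d 3x3x5, 128 filters (valid)  -> 7x7x21x128
    batch norm
    max pool over the spectral axis only (2, stride 2) -> 7x7x10x128
    ReLU
    conv3d 3x3x5, 256 filters (valid)  -> 5x5x6x256
    batch norm
    spectral max pool                  -> 5x5x3x256
    ReLU
    flatten (19200) -> dense 256 -> ReLU -> dropout 0.3
                    -> dense 128 -> ReLU -> dropout 0.5
                    -> dense 5  -> softmax

Training uses mini-batches of 1024 patches, two passes over the shuffled
set, and AdamW (lr 5e-5, weight decay 0.01).  Convolutions are evaluated as
im2col + GEMM; gradients are hand-coded.  Everything is deterministic given
the seed.

Mini-batches are processed in micro-batches (default 128 patches) with
gradient accumulation so peak memory stays bounded; batch-norm statistics
are computed per micro-batch.  Running statistics are seeded from the first
batch seen, which matters in this few-step training regime: with momentum
alone they would still be near their (0, 1) initialization at evaluation
time.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_F = np.float32


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv3D:
    """Valid 3D convolution on (B, H, W, D, C) arrays, im2col + GEMM."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator):
        kh, kw, kd = kernel
        fan_in = kh * kw * kd * in_ch
        self.w = (rng.standard_normal((kh, kw, kd, in_ch, out_ch))
                  * np.sqrt(2.0 / fan_in)).astype(_F)
        self.b = np.zeros(out_ch, dtype=_F)
        self.kernel = kernel
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.gw, True), (self.b, self.gb, False)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        kh, kw, kd = self.kernel
        xw = sliding_window_view(x, (kh, kw, kd), axis=(1, 2, 3))
        # (B, H', W', D', C, kh, kw, kd)
        b, ho, wo, do = xw.shape[:4]
        cin = xw.shape[4]
        x_col = np.ascontiguousarray(xw).reshape(b * ho * wo * do,
                                                 cin * kh * kw * kd)
        w_col = self.w.transpose(3, 0, 1, 2, 4).reshape(x_col.shape[1], -1)
        y = x_col @ w_col + self.b
        if train:
            self._cache = (x.shape, x_col)
        return y.reshape(b, ho, wo, do, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        kh, kw, kd = self.kernel
        x_shape, x_col = self._cache
        b, ho, wo, do, cout = dy.shape
        dy_col = dy.reshape(-1, cout)
        gw_col = x_col.T @ dy_col                     # (C*kh*kw*kd, out)
        cin = x_shape[4]
        self.gw += gw_col.reshape(cin, kh, kw, kd, cout).transpose(1, 2, 3, 0, 4)
        self.gb += dy_col.sum(axis=0)
        # input gradient: scatter the 45 kernel offsets back
        dx = np.zeros(x_shape, dtype=_F)
        for i in range(kh):
            for j in range(kw):
                for k in range(kd):
                    wk = self.w[i, j, k]              # (C, out)
                    dx[:, i:i + ho, j:j + wo, k:k + do, :] += dy @ wk.T
        self._cache = None
        return dx


class BatchNorm:
    """Per-channel batch normalization over all spatial/spectral positions."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=_F)
        self.beta = np.zeros(channels, dtype=_F)
        self.run_mean = np.zeros(channels, dtype=_F)
        self.run_var = np.ones(channels, dtype=_F)
        self.momentum = momentum
        self.eps = eps
        self.initialized = False
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def params(self):
        return [(self.gamma, self.ggamma, False), (self.beta, self.gbeta, False)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if not self.initialized:
                self.run_mean[:] = mean
                self.run_var[:] = var
                self.initialized = True
            else:
                m = self.momentum
                self.run_mean[:] = (1 - m) * self.run_mean + m * mean
                self.run_var[:] = (1 - m) * self.run_var + m * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv.astype(_F), x.shape)
        return (self.gamma * xhat + self.beta).astype(_F)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        axes = tuple(range(dy.ndim - 1))
        n = dy.size // dy.shape[-1]
        self.ggamma += (dy * xhat).sum(axis=axes)
        self.gbeta += dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = (inv / n) * (n * dxhat - dxhat.sum(axis=axes)
                          - xhat * (dxhat * xhat).sum(axis=axes))
        self._cache = None
        return dx.astype(_F)


class SpectralMaxPool:
    """Max pooling that reduces the spectral axis only (kernel = stride)."""

    def __init__(self, kernel: int = 2):
        self.kernel = kernel

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.kernel
        b, h, w, d, c = x.shape
        do = d // k  # remainder spectral slices are dropped
        xr = x[:, :, :, :do * k, :].reshape(b, h, w, do, k, c)
        idx = xr.argmax(axis=4)
        y = np.take_along_axis(xr, idx[:, :, :, :, None, :], axis=4)[:, :, :, :, 0, :]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        k = self.kernel
        b, h, w, d, c = shape
        do = d // k
        dx = np.zeros(shape, dtype=_F)
        dxr = dx[:, :, :, :do * k, :].reshape(b, h, w, do, k, c)
        np.put_along_axis(dxr, idx[:, :, :, :, None, :],
                          dy[:, :, :, :, None, :], axis=4)
        self._cache = None
        return dx


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class Dropout:
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_F) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class Flatten:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            # zero-initialized classifier head: logits start unbiased, which
            # keeps the few-step training regime from fighting random
            # initial class preferences
            self.w = np.zeros((n_in, n_out), dtype=_F)
        else:
            self.w = (rng.standard_normal((n_in, n_out))
                      * np.sqrt(2.0 / n_in)).astype(_F)
        self.b = np.zeros(n_out, dtype=_F)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.gw, True), (self.b, self.gb, False)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gw += self._x.T @ dy
        self.gb += dy.sum(axis=0)
        dx = dy @ self.w.T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class AdamW:
    """Decoupled weight decay Adam; decay applied to weight matrices only."""

    def __init__(self, lr: float, weight_decay: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, params) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for w, g, decay in params:
            key = id(w)
            if key not in self.state:
                self.state[key] = (np.zeros_like(w), np.zeros_like(w))
            m, v = self.state[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            upd = mhat / (np.sqrt(vhat) + self.eps)
            if decay:
                upd = upd + self.wd * w
            w -= (self.lr * upd).astype(w.dtype)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

class CNN3DClassifier:
    """Patch-based 3D-CNN pixel classifier with the study's hyperparameters.

    ``fit`` expects patches of shape (N, ph, pw, bands) and labels in
    ``1..n_classes``; ``predict`` returns labels on the same scale.
    """

    def __init__(
        self,
        n_classes: int = 5,
        filters: tuple[int, int] = (128, 256),
        kernel: tuple[int, int, int] = (3, 3, 5),
        pool: int = 2,
        fc: tuple[int, int] = (256, 128),
        dropout: tuple[float, float] = (0.3, 0.5),
        lr: float = 5e-5,
        weight_decay: float = 0.01,
        batch_size: int = 1024,
        n_passes: int = 2,
        seed: int = 0,
        microbatch: int = 128,
    ):
        self.n_classes = n_classes
        self.filters = filters
        self.kernel = kernel
        self.pool = pool
        self.fc = fc
        self.dropout = dropout
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.n_passes = n_passes
        self.seed = seed
        self.microbatch = microbatch
        self.layers = None

    # -- architecture ------------------------------------------------------

    @staticmethod
    def trace_shapes(input_shape: tuple[int, int, int],
                     kernel=(3, 3, 5), pool=2, n_blocks=2) -> list[tuple]:
        """Spatial/spectral shape after each conv block, for shape checks."""
        h, w, d = input_shape
        out = [(h, w, d)]
        kh, kw, kd = kernel
        for _ in range(n_blocks):
            h, w, d = h - kh + 1, w - kw + 1, d - kd + 1
            if min(h, w, d) <= 0:
                raise ValueError("patch too small for the convolution stack")
            d = d // pool
            if d <= 0:
                raise ValueError("spectral axis exhausted by pooling")
            out.append((h, w, d))
        return out

    def _build(self, input_shape: tuple[int, int, int], rng: np.random.Generator):
        shapes = self.trace_shapes(input_shape, self.kernel, self.pool)
        f1, f2 = self.filters
        self.layers = [
            Conv3D(1, f1, self.kernel, rng),
            BatchNorm(f1),
            SpectralMaxPool(self.pool),
            ReLU(),
            Conv3D(f1, f2, self.kernel, rng),
            BatchNorm(f2),
            SpectralMaxPool(self.pool),
            ReLU(),
            Flatten(),
        ]
        flat = int(np.prod(shapes[-1])) * f2
        self.layers += [
            Dense(flat, self.fc[0], rng), ReLU(), Dropout(self.dropout[0], rng),
            Dense(self.fc[0], self.fc[1], rng), ReLU(), Dropout(self.dropout[1], rng),
            Dense(self.fc[1], self.n_classes, rng, zero_init=True),
        ]

    @property
    def n_parameters(self) -> int:
        if self.layers is None:
            raise RuntimeError("model not built; call fit first")
        return sum(int(w.size) for lyr in self.layers for w, _, _ in lyr.params())

    def _params(self):
        return [p for lyr in self.layers for p in lyr.params()]

    def _zero_grads(self):
        for _, g, _ in self._params():
            g[:] = 0

    # -- training ----------------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x, train)
        return x

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNN3DClassifier":
        X = np.asarray(X, dtype=_F)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 4:
            raise ValueError("X must be (N, ph, pw, bands) patches")
        if len(np.unique(y)) < 2:
            raise ValueError("cannot fit a discriminator on single-class data")
        if y.min() < 1 or y.max() > self.n_classes:
            raise ValueError(f"labels must lie in 1..{self.n_classes}")
        rng = np.random.default_rng(self.seed)
        self._build(X.shape[1:], rng)
        opt = AdamW(self.lr, self.weight_decay)
        n = X.shape[0]
        for _ in range(self.n_passes):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                batch = order[start:start + self.batch_size]
                self._zero_grads()
                for ms in range(0, batch.size, self.microbatch):
                    sel = batch[ms:ms + self.microbatch]
                    xb = X[sel][..., None]            # add channel axis
                    logits = self._forward(xb, train=True)
                    p = softmax(logits)
                    dlogits = p.copy()
                    dlogits[np.arange(sel.size), y[sel] - 1] -= 1.0
                    dlogits = (dlogits / batch.size).astype(_F)
                    dy = dlogits
                    for lyr in reversed(self.layers):
                        dy = lyr.backward(dy)
                opt.step(self._params())
        return self

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.layers is None:
            raise RuntimeError("model not fitted")
        X = np.asarray(X, dtype=_F)
        out = np.empty((X.shape[0], self.n_classes), dtype=np.float64)
        for start in range(0, X.shape[0], self.microbatch):
            xb = X[start:start + self.microbatch][..., None]
            out[start:start + xb.shape[0]] = softmax(self._forward(xb, train=False))
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1) + 1
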