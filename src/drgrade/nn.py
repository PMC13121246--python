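"""A minimal CNN engine: layers with explicit backprop, in numpy.

Just enough machinery for the tiny desk-scale backbones: same-padding
3x3 convolution via im2col, ReLU, 2x2 max pooling, global average
pooling, a dense head, softmax cross-entropy and Adam. Inputs are NCHW
float32. Nothing here is tuned for large models; clarity and exact
reproducibility (seeded init, no global state) win over speed.
"""

from __future__ import annotations

import numpy as np


def _sliding_windows(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H', W', C*k*k) patches, stride 1."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # win: (N, C, H', W', k, k) -> (N, H', W', C, k, k)
    win = win.transpose(0, 2, 3, 1, 4, 5)
    n, oh, ow = win.shape[:3]
    return win.reshape(n, oh, ow, -1)


class Conv2d:
    """3x3 (or kxk) same-padding convolution, stride 1, He-initialised."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = (rng.standard_normal((cout, cin, k, k)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k = k
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = _sliding_windows(xp, k)  # (N, H, W, C*k*k)
        self._cols = cols
        self._xshape = x.shape
        wmat = self.w.reshape(self.w.shape[0], -1)  # (cout, C*k*k)
        out = cols @ wmat.T + self.b  # (N, H, W, cout)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, cout, h, w = dout.shape
        k = self.k
        pad = k // 2
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, cout)  # (N*H*W, cout)
        cols = self._cols.reshape(-1, self._cols.shape[-1])
        self.dw[...] = (dflat.T @ cols).reshape(self.w.shape)
        self.db[...] = dflat.sum(axis=0)
        # dx is the full correlation of dout with the flipped kernel — one
        # more im2col + matmul instead of a slow scatter (col2im).
        cin = self._xshape[1]
        dout_p = np.pad(dout, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = _sliding_windows(dout_p, k)  # (N, H, W, cout*k*k)
        wflip = self.w[:, :, ::-1, ::-1]
        m = wflip.transpose(0, 2, 3, 1).reshape(cout * k * k, cin)
        dx = win @ m  # (N, H, W, cin)
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; spatial dims must be even."""

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        assert h % 2 == 0 and w % 2 == 0, "MaxPool2 needs even spatial dims"
        quads = (x[:, :, 0::2, 0::2], x[:, :, 0::2, 1::2],
                 x[:, :, 1::2, 0::2], x[:, :, 1::2, 1::2])
        out = np.maximum(np.maximum(quads[0], quads[1]), np.maximum(quads[2], quads[3]))
        self._quads = quads
        self._out = out
        self._xshape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        slices = ((slice(0, None, 2), slice(0, None, 2)), (slice(0, None, 2), slice(1, None, 2)),
                  (slice(1, None, 2), slice(0, None, 2)), (slice(1, None, 2), slice(1, None, 2)))
        taken = np.zeros(dout.shape, dtype=bool)
        for quad, (sr, sc) in zip(self._quads, slices):
            mask = (quad == self._out) & ~taken  # ties route to the first window slot
            dx[:, :, sr, sc] = dout * mask
            taken |= mask
        return dx


class GlobalAvgPool:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class GlobalMaxPool:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        flat = x.reshape(n, c, -1)
        self._argmax = flat.argmax(axis=2)
        self._shape = x.shape
        return flat.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dx = np.zeros((n, c, h * w), dtype=dout.dtype)
        ii, jj = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        dx[ii, jj, self._argmax] = dout
        return dx.reshape(self._shape)


class AvgMaxPool:
    """Concatenated global average + global max pooling: (N,C,H,W)->(N,2C).

    The average channel integrates lesion load over the field; the max
    channel detects the *presence* of even a single small lesion, which
    matters for the earliest disease grades.
    """

    params: list = []

    def __init__(self) -> None:
        self._avg = GlobalAvgPool()
        self._max = GlobalMaxPool()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.concatenate([self._avg.forward(x), self._max.forward(x)], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c = dout.shape[1] // 2
        return self._avg.backward(dout[:, :c]) + self._max.backward(dout[:, c:])


class Dense:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / cin)
        self.w = (rng.standard_normal((cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w.T


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam over a fixed list of (value, grad) array pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(v) for v, _ in self.params]
        self.v = [np.zeros_like(v) for v, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (value, grad) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * grad * grad
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
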