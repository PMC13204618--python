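"""Small dense / convolutional building blocks with hand-written gradients.

All models in this package are tiny (a few thousand parameters) and train
in seconds on one CPU, so plain numpy with explicit backward passes is both
sufficient and fully deterministic given a seed.
"""
from __future__ import annotations

import math

import numpy as np


def xavier_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = {k: np.zeros_like(v) for k, v in params.items()}
        self._v = {k: np.zeros_like(v) for k, v in params.items()}
        self._t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            if self.weight_decay and p.ndim > 1:  # decay weights, not biases
                g = g + self.weight_decay * p
            m = self._m[k] = b1 * self._m[k] + (1 - b1) * g
            v = self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# conv / pool primitives (valid padding, stride 1), used by the QC classifier
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H-k+1, W-k+1, C*k*k) view-based patch extraction."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # win: (B, C, H', W', k, k) -> (B, H', W', C, k, k)
    win = win.transpose(0, 2, 3, 1, 4, 5)
    b, hh, ww = win.shape[:3]
    return win.reshape(b, hh, ww, -1)


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """x (B,C,H,W); w (F, C, k, k); b (F,). Returns (out, cache)."""
    f, c, k, _ = w.shape
    cols = _im2col(x, k)                        # (B, H', W', C*k*k)
    wmat = w.reshape(f, -1)                     # (F, C*k*k)
    out = cols @ wmat.T + b                     # (B, H', W', F)
    out = out.transpose(0, 3, 1, 2)             # (B, F, H', W')
    return out, (x.shape, cols, wmat, k, c)


def conv2d_backward(dout: np.ndarray, cache):
    x_shape, cols, wmat, k, c = cache
    f = wmat.shape[0]
    d = dout.transpose(0, 2, 3, 1)              # (B, H', W', F)
    dw = np.einsum("bijf,bijp->fp", d, cols).reshape(f, c, k, k)
    db = d.sum(axis=(0, 1, 2))
    dcols = d @ wmat                            # (B, H', W', C*k*k)
    b, hh, ww = dcols.shape[:3]
    dcols = dcols.reshape(b, hh, ww, c, k, k)
    dx = np.zeros(x_shape)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + hh, j:j + ww] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dx, dw, db


def maxpool2_forward(x: np.ndarray):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""
    b, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, :, :h2 * 2, :w2 * 2].reshape(b, c, h2, 2, w2, 2)
    out = xc.max(axis=(3, 5))
    mask = xc == out[:, :, :, None, :, None]
    # break max ties so gradient flows to a single location
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2, w2, 4)
    cum = np.cumsum(flat, axis=-1)
    flat = flat & (cum <= 1)
    mask = flat.reshape(b, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return out, (mask, x.shape)


def maxpool2_backward(dout: np.ndarray, cache):
    mask, x_shape = cache
    b, c, h2, _, w2, _ = mask.shape
    dx = np.zeros(x_shape)
    dxc = mask * dout[:, :, :, None, :, None]
    dx[:, :, :h2 * 2, :w2 * 2] = dxc.reshape(b, c, h2 * 2, w2 * 2)
    return dx


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
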