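"""Minimal CPU neural-network layers with hand-written backpropagation.

Just enough machinery for a small dilated U-Net trained at toy scale:
stride-1 'same' 2-D convolutions with arbitrary dilation (im2col forward,
transposed-convolution backward), ReLU, 2x2 max pooling, nearest-neighbour
upsampling, sigmoid, and the Adam optimizer with a reduce-on-plateau
learning-rate scheduler and early stopping.

Tensors are NCHW float64 numpy arrays.  Everything is deterministic given
the seed used to initialize the parameters and shuffle the data.
"""

from __future__ import annotations

import numpy as np


def _conv2d_raw(x: np.ndarray, w: np.ndarray, dilation: int):
    """Stride-1 'same' correlation of NCHW input with (O, C, k, k) kernel.

    Returns (output, im2col matrix of shape (N*H*W, C*k*k))."""
    n, c, hh, ww = x.shape
    o, _, k, _ = w.shape
    pad = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ii = np.arange(hh)[:, None] + dilation * np.arange(k)[None, :]  # (H, k)
    jj = np.arange(ww)[:, None] + dilation * np.arange(k)[None, :]
    patches = xp[:, :, ii[:, None, :, None], jj[None, :, None, :]]
    # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
    cols = np.ascontiguousarray(patches.transpose(0, 2, 3, 1, 4, 5)) \
        .reshape(n * hh * ww, c * k * k)
    out = (cols @ w.reshape(o, -1).T).reshape(n, hh, ww, o) \
        .transpose(0, 3, 1, 2)
    return out, cols


class Conv2d:
    """Stride-1 'same' dilated convolution with bias."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        if k % 2 == 0 or k < 1:
            raise ValueError("kernel size must be odd and positive")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * k * k))  # He initialization
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.dilation = dilation
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        out, self._cols = _conv2d_raw(x, self.w, self.dilation)
        self._x_shape = x.shape
        return out + self.b[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, o, hh, ww = grad.shape
        grad_mat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)) \
            .reshape(n * hh * ww, o)
        self.gw += (grad_mat.T @ self._cols).reshape(self.w.shape)
        self.gb += grad.sum(axis=(0, 2, 3))
        # input gradient = correlation with the spatially flipped,
        # channel-transposed kernel at the same dilation
        w_flip = self.w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        gx, _ = _conv2d_raw(grad, w_flip, self.dilation)
        return gx

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask

    def params(self):
        return []


class MaxPool2x2:
    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("max pool needs even spatial dims")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._argmax = blocks.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(blocks, self._argmax[..., None],
                                  axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._in_shape
        gx = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(gx, self._argmax[..., None], grad[..., None],
                          axis=-1)
        return gx.reshape(n, c, h // 2, w // 2, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)

    def params(self):
        return []


class UpsampleNearest2x:
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def params(self):
        return []


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam optimizer over a flat list of (param, grad) array pairs."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for _, g in self.pairs:
            g[...] = 0.0


class PlateauScheduler:
    """Halve the learning rate after ``patience`` epochs without improvement
    of the monitored metric (higher is better), down to ``min_lr``."""

    def __init__(self, lr: float, factor: float = 0.5, patience: int = 5,
                 min_lr: float = 1e-6, min_delta: float = 1e-6):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.min_delta = min_delta
        self.best = -np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> float:
        if metric > self.best + self.min_delta:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
        return self.lr


class EarlyStopping:
    """Stop after ``patience`` epochs without improvement (higher better)."""

    def __init__(self, patience: int = 5, min_delta: float = 1e-6):
        self.patience = patience
        self.min_delta = min_delta
        self.best = -np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> bool:
        """Returns True when training should stop."""
        if metric > self.best + self.min_delta:
            self.best = metric
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience
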