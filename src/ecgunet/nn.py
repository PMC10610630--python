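"""Minimal 1D neural-network primitives with explicit backpropagation.

Implements exactly the layer types the segmentation network needs
(dilated/strided 1D convolution, batch normalization, ReLU, linear
2x upsampling) on float32 numpy arrays of shape ``(N, C, L)``, plus an
Adam optimizer.  Convolutions are evaluated as matrix products over
im2col patch matrices so the heavy lifting stays inside BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv1d", "BatchNorm1d", "ReLU", "Upsample2", "Adam"]


class Layer:
    """Base class: layers own parameters, gradients, and a train flag."""

    training = True

    def parameters(self):
        return []

    def gradients(self):
        return []

    def train(self, mode: bool = True):
        self.training = mode


class Conv1d(Layer):
    """1D convolution with optional dilation, stride and 'same' padding.

    'same' padding keeps the output length at ``ceil(L / stride)``; it is
    symmetric because the effective kernel span ``(k - 1) * dilation + 1``
    is odd for odd ``k``.  For the stride-2 downsampling convolution with
    ``k == 2`` no padding is applied and even input lengths halve exactly.
    """

    def __init__(self, cin, cout, k, stride=1, dilation=1, bias=False,
                 padding="same", rng=None):
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.dilation = stride, dilation
        if padding == "same":
            span = (k - 1) * dilation + 1
            if stride == 1:
                self.pad_left = span // 2
                self.pad_right = span - 1 - self.pad_left
            else:
                # stride-2, k=2 downsampler: exact halving of even lengths
                self.pad_left = self.pad_right = 0
        else:
            self.pad_left = self.pad_right = int(padding)
        rng = rng if rng is not None else np.random.default_rng(0)
        # Kaiming-uniform fan-in init
        fan_in = cin * k
        bound = np.sqrt(6.0 / fan_in)
        self.w = rng.uniform(-bound, bound, size=(cout, cin, k)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32) if bias else None
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b) if bias else None
        self._cols = None
        self._in_len = None

    def out_len(self, L):
        span = (self.k - 1) * self.dilation + 1
        Lp = L + self.pad_left + self.pad_right
        return (Lp - span) // self.stride + 1

    def _im2col(self, x):
        N, C, L = x.shape
        if self.pad_left or self.pad_right:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        span = (self.k - 1) * self.dilation + 1
        win = sliding_window_view(x, span, axis=2)            # (N,C,Lo',span)
        win = win[:, :, ::self.stride, ::self.dilation]       # (N,C,Lout,k)
        N, C, Lo, k = win.shape
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(N, C * k, Lo)
        return cols

    def forward(self, x):
        self._in_len = x.shape[2]
        cols = self._im2col(x)
        self._cols = cols if self.training else None
        w2 = self.w.reshape(self.cout, -1)
        y = np.matmul(w2, cols)
        if self.b is not None:
            y += self.b[None, :, None]
        return y

    def backward(self, dy):
        cols = self._cols
        N, _, Lo = dy.shape
        w2 = self.w.reshape(self.cout, -1)
        self.gw += np.matmul(dy, cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.w.shape)
        if self.b is not None:
            self.gb += dy.sum(axis=(0, 2))
        dcols = np.matmul(w2.T, dy)                           # (N, C*k, Lo)
        dcols = dcols.reshape(N, self.cin, self.k, Lo)
        Lp = self._in_len + self.pad_left + self.pad_right
        dxp = np.zeros((N, self.cin, Lp), dtype=np.float32)
        for j in range(self.k):
            off = j * self.dilation
            dxp[:, :, off:off + self.stride * Lo:self.stride] += dcols[:, :, j, :]
        if self.pad_left or self.pad_right:
            dxp = dxp[:, :, self.pad_left:Lp - self.pad_right]
        self._cols = None
        return dxp

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def gradients(self):
        return [self.gw] + ([self.gb] if self.b is not None else [])


class BatchNorm1d(Layer):
    """Per-channel batch normalization with affine scale/shift.

    Batch statistics are taken over the batch and length axes in training
    mode; exponential running estimates are used at inference.
    """

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.c = c
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros(c, dtype=np.float32)
        self.gbeta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            n = x.shape[0] * x.shape[2]
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * n / max(n - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        if self.training:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy):
        xhat, inv = self._cache
        n = dy.shape[0] * dy.shape[2]
        self.ggamma += (dy * xhat).sum(axis=(0, 2))
        self.gbeta += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma[None, :, None]
        dx = (dxhat - dxhat.mean(axis=(0, 2), keepdims=True)
              - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / n)
        dx *= inv[None, :, None]
        self._cache = None
        return dx.astype(np.float32)

    def parameters(self):
        return [self.gamma, self.beta]

    def gradients(self):
        return [self.ggamma, self.gbeta]


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        self._mask = mask if self.training else None
        return np.where(mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        dy = np.where(self._mask, dy, 0.0).astype(np.float32)
        self._mask = None
        return dy


class Upsample2(Layer):
    """Linear 2x upsampling (half-sample aligned, edges clamped).

    Output sample ``i`` interpolates the input at ``(i + 0.5) / 2 - 0.5``,
    matching the usual align_corners=False convention.
    """

    def forward(self, x):
        N, C, L = x.shape
        self._in_len = L
        y = np.empty((N, C, 2 * L), dtype=np.float32)
        y[:, :, 0] = x[:, :, 0]
        y[:, :, 2::2] = 0.25 * x[:, :, :-1] + 0.75 * x[:, :, 1:]
        y[:, :, 1:-1:2] = 0.75 * x[:, :, :-1] + 0.25 * x[:, :, 1:]
        y[:, :, -1] = x[:, :, -1]
        return y

    def backward(self, dy):
        N, C, _ = dy.shape
        L = self._in_len
        dx = np.zeros((N, C, L), dtype=np.float32)
        dx[:, :, 0] += dy[:, :, 0]
        de = dy[:, :, 2::2]            # even outputs 2..2L-2
        dx[:, :, :-1] += 0.25 * de
        dx[:, :, 1:] += 0.75 * de
        do = dy[:, :, 1:-1:2]          # odd outputs 1..2L-3
        dx[:, :, :-1] += 0.75 * do
        dx[:, :, 1:] += 0.25 * do
        dx[:, :, -1] += dy[:, :, -1]
        return dx


class Adam:
    """Adam with bias correction; operates in place on parameter arrays."""

    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.grads = list(grads)
        self.lr, self.beta1, self.beta2 = lr, beta1, beta2
        self.eps, self.weight_decay = eps, weight_decay
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0
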