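"""Tiny numpy neural-network toolkit: 3D convolutions (im2col), dense
layers, ReLU, and Adam.

Shapes follow the (batch, channels, D, H, W) convention.  Backward passes
are hand-derived; a finite-difference check lives in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list
    grads: list

    def forward(self, x, train=True):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution with 'same'-style zero padding and integer stride."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel ** 3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (c_out, c_in, kernel, kernel, kernel))
        self.b = np.zeros(c_out)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._xpad_shape = x.shape
        win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        # win: (B, C_in, D', H', W', k, k, k)
        B, C, D, H, W = win.shape[:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(B, D * H * W, -1)
        if train:
            self._cols = cols
            self._out_dims = (D, H, W)
        Wmat = self.W.reshape(self.W.shape[0], -1)
        out = cols @ Wmat.T + self.b
        return out.reshape(B, D, H, W, -1).transpose(0, 4, 1, 2, 3)

    def backward(self, dout):
        k, s = self.kernel, self.stride
        B = dout.shape[0]
        D, H, W = self._out_dims
        dflat = dout.transpose(0, 2, 3, 4, 1).reshape(B, D * H * W, -1)
        Wmat = self.W.reshape(self.W.shape[0], -1)
        self.grads[0][...] = np.einsum("bpo,bpi->oi", dflat, self._cols).reshape(self.W.shape)
        self.grads[1][...] = dflat.sum(axis=(0, 1))
        dcols = dflat @ Wmat  # (B, P, C_in*k^3)
        dcols = dcols.reshape(B, D, H, W, -1, k, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
        dxp = np.zeros(self._xpad_shape)
        for a in range(k):
            for b_ in range(k):
                for c in range(k):
                    dxp[:, :, a:a + s * D:s, b_:b_ + s * H:s, c:c + s * W:s] += \
                        dcols[..., a, b_, c]
        p = self.pad
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out))
        self.b = np.zeros(d_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class ReLU(Layer):
    params: list = []
    grads: list = []

    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    params: list = []
    grads: list = []

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
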