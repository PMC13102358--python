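"""Layers with forward/backward passes. float32 throughout.

Every layer exposes ``params`` and ``grads`` dicts (possibly empty) plus
``buffers`` for non-trained state (batch-norm running moments).  ``forward``
takes ``train`` to switch batch-norm statistics; caches required for the
backward pass live on the layer and are overwritten per call.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int):
    """Return (cols view copy (N, C, kh, kw, OH, OW), padded shape)."""
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    n, c, h, w = x.shape
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    if oh < 1 or ow < 1:
        raise ValueError(
            f"spatial input {h - 2 * ph}x{w - 2 * pw} too small for "
            f"{kh}x{kw} kernel with stride {sh}x{sw}"
        )
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2 * sh, s3 * sw)
    )
    return np.ascontiguousarray(cols), (n, c, h, w)


def _col2im(dcols: np.ndarray, padded_shape, sh: int, sw: int, ph: int, pw: int):
    """Scatter-add column gradients back to the (unpadded) input."""
    n, c, h, w = padded_shape
    _, _, kh, kw, oh, ow = dcols.shape
    dx = np.zeros(padded_shape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += dcols[:, :, i, j]
    if ph or pw:
        dx = dx[:, :, ph : h - ph, pw : w - pw]
    return dx


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, cin, cout, kernel, stride=1, pad=0, rng=None):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.kh, self.kw = kh, kw
        self.stride = stride
        self.pad = pad
        fan_in = cin * kh * kw
        rng = rng or np.random.default_rng()
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in)
        ).astype(np.float32)
        self.cin, self.cout = cin, cout

    def forward(self, x, train=False):
        cols, self._padded_shape = _im2col(
            x, self.kh, self.kw, self.stride, self.stride, self.pad, self.pad
        )
        n, c, kh, kw, oh, ow = cols.shape
        flat = cols.reshape(n, c * kh * kw, oh * ow)
        out = np.matmul(self.params["W"][None], flat)
        self._cols = flat
        self._oshape = (n, self.cout, oh, ow)
        return out.reshape(self._oshape)

    def backward(self, dout):
        n, cout, oh, ow = self._oshape
        d = dout.reshape(n, cout, oh * ow)
        self.grads["W"] = np.einsum("nol,nkl->ok", d, self._cols).astype(np.float32)
        dflat = np.matmul(self.params["W"].T[None], d)
        dcols = dflat.reshape(n, self.cin, self.kh, self.kw, oh, ow)
        return _col2im(dcols, self._padded_shape, self.stride, self.stride, self.pad, self.pad)


class BatchNorm2d(Layer):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.buffers["running_mean"] = np.zeros(channels, dtype=np.float32)
        self.buffers["running_var"] = np.ones(channels, dtype=np.float32)

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.buffers["running_mean"] = (
                (1 - self.momentum) * self.buffers["running_mean"] + self.momentum * mean
            ).astype(np.float32)
            self.buffers["running_var"] = (
                (1 - self.momentum) * self.buffers["running_var"] + self.momentum * var
            ).astype(np.float32)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train)
        return (
            self.params["gamma"][None, :, None, None] * xhat
            + self.params["beta"][None, :, None, None]
        ).astype(np.float32)

    def backward(self, dout):
        xhat, inv, train = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        self.grads["beta"] = dout.sum(axis=(0, 2, 3)).astype(np.float32)
        g = self.params["gamma"][None, :, None, None] * inv[None, :, None, None]
        if not train:
            return dout * g
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dsum = dout.sum(axis=(0, 2, 3))[None, :, None, None]
        dxhat_sum = (dout * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return g * (dout - dsum / m - xhat * dxhat_sum / m)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel=3, stride=2, pad=1):
        super().__init__()
        self.k, self.stride, self.pad = kernel, stride, pad

    def forward(self, x, train=False):
        cols, self._padded_shape = _im2col(
            x, self.k, self.k, self.stride, self.stride, self.pad, self.pad
        )
        n, c, kh, kw, oh, ow = cols.shape
        flat = cols.reshape(n, c, kh * kw, oh, ow)
        self._argmax = flat.argmax(axis=2)
        self._oshape = (n, c, oh, ow)
        return flat.max(axis=2)

    def backward(self, dout):
        n, c, oh, ow = self._oshape
        dcols = np.zeros((n, c, self.k * self.k, oh, ow), dtype=dout.dtype)
        np.put_along_axis(dcols, self._argmax[:, :, None], dout[:, :, None], axis=2)
        dcols = dcols.reshape(n, c, self.k, self.k, oh, ow)
        return _col2im(dcols, self._padded_shape, self.stride, self.stride, self.pad, self.pad)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).copy()


class Linear(Layer):
    def __init__(self, cin, cout, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = np.sqrt(1.0 / cin)
        self.params["W"] = rng.uniform(-bound, bound, size=(cout, cin)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = (dout.T @ self._x).astype(np.float32)
        self.grads["b"] = dout.sum(axis=0).astype(np.float32)
        return dout @ self.params["W"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean()
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), (d / n).astype(np.float32)
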