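"""Minimal NumPy building blocks for volumetric convolutional networks.

Arrays are channels-last ``(N, D, H, W, C)`` (batch, z, y, x, channels),
which lets every convolution run as 27 strided-slice matrix products with
no im2col blowup.  Each layer caches what it needs from the forward pass
and implements an exact backward pass (checked against finite
differences); all arithmetic is float32.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np


class Layer:
    params: List[np.ndarray]
    grads: List[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv3D(Layer):
    """3x3x3 convolution; 'same' mode zero-pads by one voxel per side."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, same: bool = True):
        super().__init__()
        fan_in = c_in * 27
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(3, 3, 3, c_in, c_out)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.same = same
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    @staticmethod
    def _slide(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Valid correlation of (N,D,H,W,Ci) with (3,3,3,Ci,Co) kernels."""
        n, D, H, W, _ = x.shape
        d, h, wd = D - 2, H - 2, W - 2
        out = None
        for kz in range(3):
            for ky in range(3):
                for kx in range(3):
                    xs = x[:, kz:kz + d, ky:ky + h, kx:kx + wd, :]
                    term = xs @ w[kz, ky, kx]
                    out = term if out is None else out + term
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(np.float32, copy=False)
        if self.same:
            x = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        self._x = x
        return self._slide(x, self.w) + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy.astype(np.float32, copy=False)
        x = self._x
        d, h, wd = dy.shape[1:4]
        dw = self.grads[0]
        dw[...] = 0
        dyf = dy.reshape(-1, dy.shape[-1])
        for kz in range(3):
            for ky in range(3):
                for kx in range(3):
                    xs = x[:, kz:kz + d, ky:ky + h, kx:kx + wd, :].reshape(-1, x.shape[-1])
                    dw[kz, ky, kx] = xs.T @ dyf
        self.grads[1][...] = dyf.sum(axis=0)
        # input gradient = full correlation with flipped, channel-swapped kernel
        w_back = self.w[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3)
        dy_pad = np.pad(dy, ((0, 0), (2, 2), (2, 2), (2, 2), (0, 0)))
        dx = self._slide(dy_pad, w_back)
        if self.same:
            dx = dx[:, 1:-1, 1:-1, 1:-1, :]
        return dx


class Conv1x1(Layer):
    """1x1x1 channel-mixing convolution (the classifier head)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dyf = dy.reshape(-1, dy.shape[-1])
        self.grads[0][...] = self._x.reshape(-1, self._x.shape[-1]).T @ dyf
        self.grads[1][...] = dyf.sum(axis=0)
        return dy @ self.w.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool3D(Layer):
    """Max pooling with per-axis factors (fd, fh, fw); axes must divide evenly."""

    def __init__(self, factors: Tuple[int, int, int]):
        super().__init__()
        self.f = factors

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, d, h, w, c = x.shape
        fd, fh, fw = self.f
        if d % fd or h % fh or w % fw:
            raise ValueError(f"pooling {self.f} does not divide spatial shape {(d, h, w)}")
        r = x.reshape(n, d // fd, fd, h // fh, fh, w // fw, fw, c)
        r = r.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(
            n, d // fd, h // fh, w // fw, c, fd * fh * fw
        )
        self._arg = r.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(r, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, d, h, w, c = self._in_shape
        fd, fh, fw = self.f
        r = np.zeros((n, d // fd, h // fh, w // fw, c, fd * fh * fw), dtype=dy.dtype)
        np.put_along_axis(r, self._arg[..., None], dy[..., None], axis=-1)
        r = r.reshape(n, d // fd, h // fh, w // fw, c, fd, fh, fw)
        return r.transpose(0, 1, 5, 2, 6, 3, 7, 4).reshape(n, d, h, w, c)


class ConvTranspose3D(Layer):
    """Transposed convolution with kernel = stride = per-axis factors (upsampling)."""

    def __init__(self, c_in: int, c_out: int, factors: Tuple[int, int, int],
                 rng: np.random.Generator):
        super().__init__()
        fd, fh, fw = factors
        self.w = rng.normal(0.0, np.sqrt(2.0 / c_in),
                            size=(c_in, c_out, fd, fh, fw)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.f = factors
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, d, h, w, c = x.shape
        fd, fh, fw = self.f
        y = np.einsum("ndhwc,coijk->ndihjwko", x, self.w, optimize=True)
        return y.reshape(n, d * fd, h * fh, w * fw, -1) + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, df, hf, wf, o = dy.shape
        fd, fh, fw = self.f
        dyr = dy.reshape(n, df // fd, fd, hf // fh, fh, wf // fw, fw, o)
        self.grads[0][...] = np.einsum("ndihjwko,ndhwc->coijk", dyr, self._x, optimize=True)
        self.grads[1][...] = dy.sum(axis=(0, 1, 2, 3))
        return np.einsum("ndihjwko,coijk->ndhwc", dyr, self.w, optimize=True)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: List[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
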