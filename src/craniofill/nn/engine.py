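"""Minimal 3-D convolutional network engine (numpy, CPU).

Implements exactly the primitives the two skull networks need — 3x3x3
'same' convolutions (dilation 1 or 2), 2x2x2 max pooling, x2
nearest-neighbour upsampling, ReLU/sigmoid, elementwise summation — with
hand-written backward passes and the Adadelta optimizer. Tensors are
channel-last ``(N, X, Y, Z, C)`` float32, which keeps the inner loop a
single BLAS matmul per kernel offset.

The engine is deliberately small: networks at desk-scale resolutions
(tens of voxels per axis, 4-8 channels) train in minutes on one CPU,
which is all the package's reproducible experiments require.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3d",
    "conv_param_count",
    "maxpool2",
    "maxpool2_backward",
    "upsample2",
    "upsample2_backward",
    "relu",
    "relu_backward",
    "sigmoid",
    "Adadelta",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Glorot/Xavier uniform init; fan counts include the kernel volume."""
    receptive = int(np.prod(shape[:-2])) if len(shape) > 2 else 1
    fan_in = shape[-2] * receptive
    fan_out = shape[-1] * receptive
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def conv_param_count(c_in: int, c_out: int, kernel: int = 3) -> int:
    return kernel**3 * c_in * c_out + c_out


class Conv3d:
    """3x3x3 convolution, stride 1, 'same' zero padding, optional dilation.

    Weights have shape (3, 3, 3, C_in, C_out); one bias per filter.

    Implementation note: the padded input is flattened to a 2-D
    (voxels, channels) matrix, so every kernel offset is one
    *contiguous* row slice and each tap is a single copy-free BLAS
    matmul. Out-of-row wrap-around contributions only ever read the
    zero padding (or write rows that are cropped), so the result is an
    exact 'same' convolution.
    """

    def __init__(self, name: str, c_in: int, c_out: int, dilation: int = 1):
        if dilation not in (1, 2):
            raise ValueError("dilation must be 1 or 2")
        self.name = name
        self.c_in, self.c_out, self.dilation = c_in, c_out, dilation
        self.W = np.zeros((3, 3, 3, c_in, c_out), dtype=np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def init(self, rng: np.random.Generator) -> None:
        self.W = glorot_uniform(rng, self.W.shape)
        self.b = np.zeros(self.c_out, dtype=np.float32)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def _geometry(self, shape):
        n, X, Y, Z, _ = shape
        d = self.dilation
        pdims = (X + 2 * d, Y + 2 * d, Z + 2 * d)
        P = pdims[0] * pdims[1] * pdims[2]
        shifts = [
            (i * d * pdims[1] + j * d) * pdims[2] + k * d
            for i in range(3)
            for j in range(3)
            for k in range(3)
        ]
        return d, pdims, P, shifts

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        d, pdims, P, shifts = self._geometry(x.shape)
        n, X, Y, Z, _ = x.shape
        xp = np.pad(x, ((0, 0), (d, d), (d, d), (d, d), (0, 0)))
        flat = xp.reshape(n * P, self.c_in)
        outf = np.zeros((n * P, self.c_out), dtype=x.dtype)
        Wf = self.W.reshape(27, self.c_in, self.c_out)
        tmp = np.empty_like(outf)
        for t, s in enumerate(shifts):
            rows = n * P - s
            np.matmul(flat[s:], Wf[t], out=tmp[:rows])
            outf[:rows] += tmp[:rows]
        # output voxel (x,y,z) lives at padded row (x,y,z): leading corner
        out = outf.reshape(n, *pdims, self.c_out)[:, :X, :Y, :Z, :]
        out = np.ascontiguousarray(out)
        out += self.b
        if cache is not None:
            cache[self.name] = flat
        return out

    def backward(self, cache: dict, grad: np.ndarray, grads: dict) -> np.ndarray:
        d, pdims, P, shifts = self._geometry(grad.shape)
        n, X, Y, Z, _ = grad.shape
        flat = cache[self.name]
        # embed the gradient on the padded grid (leading corner) once
        gp = np.zeros((n, *pdims, self.c_out), dtype=grad.dtype)
        gp[:, :X, :Y, :Z, :] = grad
        gpf = gp.reshape(n * P, self.c_out)
        gW = np.empty(self.W.shape, dtype=grad.dtype)
        gWf = gW.reshape(27, self.c_in, self.c_out)
        gxf = np.zeros_like(flat)
        Wf = self.W.reshape(27, self.c_in, self.c_out)
        tmp = np.empty_like(flat)
        for t, s in enumerate(shifts):
            rows = n * P - s
            src = flat[s:]
            dst = gpf[:rows]
            np.matmul(src.T, dst, out=gWf[t])
            np.matmul(dst, Wf[t].T, out=tmp[:rows])
            gxf[s:] += tmp[:rows]
        if self.name + ".W" in grads:  # shared layers accumulate
            grads[self.name + ".W"] = grads[self.name + ".W"] + gW
            grads[self.name + ".b"] = grads[self.name + ".b"] + grad.sum(axis=(0, 1, 2, 3))
        else:
            grads[self.name + ".W"] = gW
            grads[self.name + ".b"] = grad.sum(axis=(0, 1, 2, 3))
        # real input voxel x sits at padded coordinate x + d
        gx = gxf.reshape(n, *pdims, self.c_in)[:, d:-d, d:-d, d:-d, :]
        return np.ascontiguousarray(gx)


def maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2x2 max pooling; returns (pooled, argmax one-hot) for backward."""
    n, X, Y, Z, c = x.shape
    r = x.reshape(n, X // 2, 2, Y // 2, 2, Z // 2, 2, c)
    r = r.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(n, X // 2, Y // 2, Z // 2, c, 8)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, idx


def maxpool2_backward(grad: np.ndarray, idx: np.ndarray, in_shape: tuple) -> np.ndarray:
    n, X, Y, Z, c = in_shape
    r = np.zeros((n, X // 2, Y // 2, Z // 2, c, 8), dtype=grad.dtype)
    np.put_along_axis(r, idx[..., None], grad[..., None], axis=-1)
    r = r.reshape(n, X // 2, Y // 2, Z // 2, c, 2, 2, 2)
    r = r.transpose(0, 1, 5, 2, 6, 3, 7, 4)
    return r.reshape(in_shape)


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour x2 upsampling along the three spatial axes."""
    for ax in (1, 2, 3):
        x = np.repeat(x, 2, axis=ax)
    return x


def upsample2_backward(grad: np.ndarray) -> np.ndarray:
    n, X, Y, Z, c = grad.shape
    r = grad.reshape(n, X // 2, 2, Y // 2, 2, Z // 2, 2, c)
    return r.sum(axis=(2, 4, 6))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(grad: np.ndarray, activated: np.ndarray) -> np.ndarray:
    return grad * (activated > 0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adadelta:
    """Adadelta: per-parameter adaptive steps, no learning-rate tuning.

    Keeps running averages E[g^2] and E[dx^2] with decay ``rho`` and
    scales each gradient by sqrt(E[dx^2]+eps)/sqrt(E[g^2]+eps).
    """

    def __init__(self, params: dict[str, np.ndarray], rho: float = 0.95,
                 eps: float = 1e-6, lr: float = 1.0):
        self.params = params
        self.rho, self.eps, self.lr = rho, eps, lr
        self.eg2 = {k: np.zeros_like(v) for k, v in params.items()}
        self.edx2 = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            g = grads[k]
            self.eg2[k] = self.rho * self.eg2[k] + (1 - self.rho) * g * g
            dx = -np.sqrt(self.edx2[k] + self.eps) / np.sqrt(self.eg2[k] + self.eps) * g
            self.edx2[k] = self.rho * self.edx2[k] + (1 - self.rho) * dx * dx
            p += self.lr * dx
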