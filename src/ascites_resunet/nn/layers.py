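"""Minimal CNN building blocks on numpy, float32, channel-first layout.

Activations are carried as (C, N, H, W): flattening (C, N*H*W) is then
free, so every convolution reduces to large contiguous BLAS sgemm
calls.  Stride-1 3x3 convolutions use a shift-and-GEMM evaluation (one
GEMM per kernel tap, accumulated over shifted output windows); strided
and 1x1 convolutions use a channel-first im2col with a single GEMM.
Batch normalization follows the usual per-channel train/inference
split with running statistics.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _same_pads(n: int, k: int, stride: int) -> tuple[int, int, int]:
    """'same' padding: output ceil(n/stride); extra pad goes after."""
    out = -(-n // stride)
    total = max((out - 1) * stride + k - n, 0)
    before = total // 2
    return out, before, total - before


class Conv2D:
    """2-D convolution, 'same' zero padding, optional bias.

    Input/output layout (C, N, H, W); weights (cout, cin, k, k),
    He-uniform initialized from the supplied generator.
    """

    def __init__(
        self,
        name: str,
        cin: int,
        cout: int,
        k: int,
        stride: int,
        rng: np.random.Generator,
        bias: bool = True,
    ):
        self.name = name
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        limit = np.sqrt(6.0 / (k * k * cin))  # He-uniform
        self.W = rng.uniform(-limit, limit, size=(cout, cin, k, k)).astype(F32)
        self.b = np.zeros(cout, dtype=F32) if bias else None
        self.dW: np.ndarray | None = None
        self.db: np.ndarray | None = None
        self._x: np.ndarray | None = None
        self.last_output_shape: tuple[int, int, int] | None = None  # (H, W, C)

    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, int, int, int, int]:
        C, N, H, W = x.shape
        k, s = self.k, self.stride
        Ho, pt, pb = _same_pads(H, k, s)
        Wo, pl, pr = _same_pads(W, k, s)
        if pt or pb or pl or pr:
            x = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        return x, Ho, Wo, pt, pl

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        C, N = x.shape[:2]
        xp, Ho, Wo, _, _ = self._pad(x)
        k, s = self.k, self.stride
        if s == 1 and k > 1:
            # shift-and-GEMM: out[h, w] = sum_ij W_ij @ xp[h+i, w+j]
            Hp, Wp = xp.shape[2], xp.shape[3]
            xf = xp.reshape(C, N * Hp * Wp)
            out = np.zeros((self.cout, N, Ho, Wo), dtype=F32)
            for i in range(k):
                for j in range(k):
                    y = (self.W[:, :, i, j] @ xf).reshape(self.cout, N, Hp, Wp)
                    out += y[:, :, i : i + Ho, j : j + Wo]
        else:
            cols = self._cols(xp, Ho, Wo)
            out = (self.W.reshape(self.cout, -1) @ cols).reshape(self.cout, N, Ho, Wo)
        if self.b is not None:
            out += self.b[:, None, None, None]
        if training:
            self._x = x
        self.last_output_shape = (Ho, Wo, self.cout)
        return out

    def _cols(self, xp: np.ndarray, Ho: int, Wo: int) -> np.ndarray:
        """Channel-first patch matrix (cin*k*k, N*Ho*Wo)."""
        C, N = xp.shape[:2]
        k, s = self.k, self.stride
        cols = np.empty((C, k, k, N, Ho, Wo), dtype=F32)
        for i in range(k):
            for j in range(k):
                cols[:, i, j] = xp[:, :, i : i + Ho * s : s, j : j + Wo * s : s]
        return cols.reshape(C * k * k, N * Ho * Wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        C, N, H, W = x.shape
        k, s = self.k, self.stride
        co = self.cout
        Ho, Wo = dout.shape[2], dout.shape[3]
        if not (dout.flags.c_contiguous and dout.dtype == F32):
            dout = np.ascontiguousarray(dout, dtype=F32)
        d2 = dout.reshape(co, N * Ho * Wo)
        if self.b is not None:
            self.db = d2.sum(axis=1)
        xp, _, _, pt, pl = self._pad(x)
        # dW via one GEMM of contiguous buffers: scatter dout into a
        # per-tap stack aligned with the padded input, then contract
        # over all pixels at once
        dstack = np.zeros((k * k * co,) + xp.shape[1:], dtype=F32)
        for i in range(k):
            for j in range(k):
                dstack[(i * k + j) * co : (i * k + j + 1) * co, :,
                       i : i + Ho * s : s, j : j + Wo * s : s] = dout
        dWmat = dstack.reshape(k * k * co, -1) @ xp.reshape(C, -1).T
        self.dW = np.ascontiguousarray(
            dWmat.reshape(k, k, co, C).transpose(2, 3, 0, 1)
        )
        # dx: expand back through the kernel taps
        dcols = (self.W.reshape(co, -1).T @ d2).reshape(C, k, k, N, Ho, Wo)
        dxp = np.zeros(xp.shape, dtype=F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + Ho * s : s, j : j + Wo * s : s] += dcols[:, i, j]
        self._x = None
        return dxp[:, :, pt : pt + H, pl : pl + W]

    def named_params(self):
        yield f"{self.name}.W", self.W, lambda: self.dW
        if self.b is not None:
            yield f"{self.name}.b", self.b, lambda: self.db

    def named_buffers(self):
        return iter(())


class BatchNorm2D:
    """Per-channel batch normalization with running statistics.

    Momentum 0.9 so the running mean/variance converge within a few
    hundred optimizer steps (this package targets short CPU-scale
    training runs); epsilon 1e-3.
    """

    def __init__(self, name: str, c: int, momentum: float = 0.9, eps: float = 1e-3):
        self.name = name
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self.dgamma: np.ndarray | None = None
        self.dbeta: np.ndarray | None = None
        self._xhat: np.ndarray | None = None
        self._invstd: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            self.running_mean[:] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[:] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = x - mean.astype(F32)[:, None, None, None]
        xhat *= invstd[:, None, None, None]
        if training:
            self._xhat, self._invstd = xhat, invstd
        out = xhat * self.gamma[:, None, None, None]
        out += self.beta[:, None, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        C, N, H, W = dout.shape
        m = N * H * W
        self.dbeta = dout.sum(axis=(1, 2, 3)).astype(F32)
        self.dgamma = (dout * xhat).sum(axis=(1, 2, 3)).astype(F32)
        dxhat = dout * self.gamma[:, None, None, None]
        s1 = dxhat.sum(axis=(1, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(1, 2, 3), keepdims=True)
        # dx = invstd/m * (m*dxhat - s1 - xhat*s2), built in place
        xhat *= s2
        dxhat *= m
        dxhat -= s1
        dxhat -= xhat
        dxhat *= invstd[:, None, None, None] / m
        self._xhat = self._invstd = None
        return dxhat.astype(F32, copy=False)

    def named_params(self):
        yield f"{self.name}.gamma", self.gamma, lambda: self.dgamma
        yield f"{self.name}.beta", self.beta, lambda: self.dbeta

    def named_buffers(self):
        yield f"{self.name}.running_mean", self.running_mean
        yield f"{self.name}.running_var", self.running_var


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # dout is a fresh array from the downstream conv: mutate in place
        dout *= self._mask
        self._mask = None
        return dout


class Upsample2x:
    """Nearest-neighbour x2 spatial up-sampling (axes 2, 3)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return (
            dout[:, :, 0::2, 0::2]
            + dout[:, :, 0::2, 1::2]
            + dout[:, :, 1::2, 0::2]
            + dout[:, :, 1::2, 1::2]
        )
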