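"""Minimal 1-D convolutional network primitives on numpy.

Forward and backward passes are written explicitly (im2col views feeding BLAS
GEMMs), which keeps the whole training loop dependency-free, deterministic and
fast enough for desk-scale genomes on a single CPU core. Layers operate on
float32 batches of shape (B, C, L) and use zero ("same") padding so output
length always equals input length. Correctness of every backward pass is
enforced by finite-difference gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = ["Conv1d", "ReLU", "Sigmoid", "ResidualBlock", "Adam"]

#: compute dtype; float32 feeds BLAS sgemm (float64 available for numeric checks)
DTYPE = np.float32


class Layer:
    """Base layer: forward caches what backward needs; params() lists tensors."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[dict]:
        return []


def _im2col(xp: np.ndarray, kernel: int, dilation: int, out_len: int) -> np.ndarray:
    """(C, Lp) padded array -> (C*K, out_len) column matrix (copies)."""
    c, _ = xp.shape
    s0, s1 = xp.strides
    view = as_strided(
        xp,
        shape=(c, kernel, out_len),
        strides=(s0, dilation * s1, s1),
        writeable=False,
    )
    return view.reshape(c * kernel, out_len)


class Conv1d(Layer):
    """Same-padded dilated 1-D convolution (cross-correlation), bias included.

    Weights are He-initialized: N(0, sqrt(2 / (C_in * K))) suits the ReLU
    nonlinearity used throughout the network.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
    ):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same-length output")
        if min(in_channels, out_channels, kernel, dilation) < 1:
            raise ValueError("conv hyperparameters must be >= 1")
        self.cin, self.cout, self.kernel, self.dilation = (
            in_channels, out_channels, kernel, dilation,
        )
        self.pad = (kernel - 1) * dilation // 2
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_channels * kernel))
        self.W = rng.normal(0.0, std, size=(out_channels, in_channels * kernel)).astype(
            DTYPE
        )
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None  # padded input cached for backward

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, L = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        y = np.empty((B, self.cout, L), dtype=self.W.dtype)
        for i in range(B):  # per-sample GEMM keeps the im2col buffer small
            col = _im2col(xp[i], self.kernel, self.dilation, L)
            y[i] = self.W @ col
        y += self.b[None, :, None]
        if train:
            self._xp = xp
        return y

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        assert self._xp is not None, "backward before forward(train=True)"
        xp = self._xp
        B, _, L = d_out.shape
        K, d = self.kernel, self.dilation
        dxp = np.zeros_like(xp)
        for i in range(B):
            col = _im2col(xp[i], K, d, L)
            self.gW += d_out[i] @ col.T
            dcol = (self.W.T @ d_out[i]).reshape(self.cin, K, L)
            # col2im scatter-add: tap k of the kernel saw xp[:, k*d : k*d + L]
            for k in range(K):
                dxp[i, :, k * d : k * d + L] += dcol[:, k, :]
        self.gb += d_out.sum(axis=(0, 2))
        self._xp = None
        if self.pad:
            return dxp[:, :, self.pad : -self.pad]
        return dxp

    def params(self) -> list[dict]:
        return [
            {"value": self.W, "grad": self.gW},
            {"value": self.b, "grad": self.gb},
        ]


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        dx = d_out * self._mask
        self._mask = None
        return dx


class Sigmoid(Layer):
    def __init__(self) -> None:
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.exp(-np.logaddexp(0.0, -x))  # overflow-safe for large |x|
        if train:
            self._y = y
        return y

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        assert self._y is not None
        dx = d_out * self._y * (1.0 - self._y)
        self._y = None
        return dx


class Log1p(Layer):
    """Fixed monotone compression y = log(1 + x) for nonnegative inputs.

    Coverage values span orders of magnitude; compressing them keeps the
    downstream stage's pre-activations in a trainable range without altering
    which bases rank above which.
    """

    def __init__(self) -> None:
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return np.log1p(x)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        assert self._x is not None
        dx = d_out / (1.0 + self._x)
        self._x = None
        return dx


class ResidualBlock(Layer):
    """Three same-length dilated convolutions with ReLUs and an identity skip.

    The block input is added to the output of the third convolution; when the
    channel counts differ the skip is a learned kernel-1 projection. A final
    ReLU follows the addition (ReLU is used throughout the network except the
    classification output).
    """

    def __init__(
        self,
        in_channels: int,
        channels: int,
        kernel: int,
        dilation: int,
        rng: np.random.Generator,
    ):
        self.conv1 = Conv1d(in_channels, channels, kernel, dilation, rng)
        self.conv2 = Conv1d(channels, channels, kernel, dilation, rng)
        self.conv3 = Conv1d(channels, channels, kernel, dilation, rng)
        self.relu1, self.relu2, self.relu_out = ReLU(), ReLU(), ReLU()
        self.skip: Conv1d | None = None
        if in_channels != channels:
            self.skip = Conv1d(in_channels, channels, 1, 1, rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.relu1.forward(self.conv1.forward(x, train), train)
        h = self.relu2.forward(self.conv2.forward(h, train), train)
        h = self.conv3.forward(h, train)
        s = self.skip.forward(x, train) if self.skip is not None else x
        return self.relu_out.forward(h + s, train)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        d_sum = self.relu_out.backward(d_out)
        dx_skip = self.skip.backward(d_sum) if self.skip is not None else d_sum
        dh = self.conv3.backward(d_sum)
        dh = self.conv2.backward(self.relu2.backward(dh))
        dx_main = self.conv1.backward(self.relu1.backward(dh))
        return dx_main + dx_skip

    def params(self) -> list[dict]:
        out = self.conv1.params() + self.conv2.params() + self.conv3.params()
        if self.skip is not None:
            out += self.skip.params()
        return out


class Adam:
    """Adam optimizer with standard defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(
        self,
        params: list[dict],
        lr: float = 2e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p["value"] -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p["grad"][...] = 0.0
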