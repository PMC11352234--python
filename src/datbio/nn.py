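"""A small 1-D convolutional encoder with manual backpropagation.

The shared-weight encoder maps a fixed-length EEG epoch to an embedding
vector.  Architecture: three convolution blocks (kernel 7, stride 2,
channels 16 -> 32 -> 64, ReLU), global average pooling over time, a linear
projection to the embedding dimension, and optional L2 normalization of
the output (default on, so embedding distances are bounded by 2).

Everything is plain numpy: each layer implements ``forward``/``backward``
and exposes its parameters and gradients to the Adam optimizer below.
Gradient correctness is verified against finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv1D", "ReLU", "GlobalAvgPool", "Dense", "L2Normalize",
           "Encoder", "Adam"]


class Conv1D:
    """Valid cross-correlation with stride; input/output layout (B, C, L)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, rng: np.random.Generator):
        fan_in = in_channels * kernel
        self.w = rng.standard_normal((out_channels, in_channels, kernel)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(out_channels)
        self.kernel = kernel
        self.stride = stride
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        win = sliding_window_view(x, self.kernel, axis=2)[:, :, ::self.stride, :]
        self._win = win
        y = np.einsum("bclk,ock->bol", win, self.w, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        # in-place so the (param, grad) pairs handed to the optimizer stay valid
        self.gw[...] = np.einsum("bol,bclk->ock", gy, self._win, optimize=True)
        self.gb[...] = gy.sum(axis=(0, 2))
        gx = np.zeros(self._x_shape)
        L_out = gy.shape[2]
        for j in range(self.kernel):
            contrib = np.einsum("bol,oc->bcl", gy, self.w[:, :, j], optimize=True)
            gx[:, :, j:j + self.stride * L_out:self.stride] += contrib
        return gx

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def out_length(self, n: int) -> int:
        return (n - self.kernel) // self.stride + 1


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask

    def params(self):
        return []


class GlobalAvgPool:
    """Mean over the time axis: (B, C, L) -> (B, C)."""

    def forward(self, x):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gy):
        return np.repeat(gy[:, :, None], self._L, axis=2) / self._L

    def params(self):
        return []


class Dense:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.w = rng.standard_normal((in_dim, out_dim)) * np.sqrt(2.0 / in_dim)
        self.b = np.zeros(out_dim)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, gy):
        self.gw[...] = self._x.T @ gy
        self.gb[...] = gy.sum(axis=0)
        return gy @ self.w.T

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class L2Normalize:
    """Row-wise projection onto the unit sphere (guarded near zero)."""

    eps = 1e-12

    def forward(self, x):
        norm = np.linalg.norm(x, axis=1, keepdims=True)
        self._norm = np.maximum(norm, self.eps)
        self._y = x / self._norm
        return self._y

    def backward(self, gy):
        dot = np.sum(gy * self._y, axis=1, keepdims=True)
        return (gy - dot * self._y) / self._norm

    def params(self):
        return []


class Encoder:
    """Shared-weight EEG-epoch encoder Net(·).

    The same instance (hence the same weights) embeds every branch of a
    pair or triplet: weight sharing is structural, not copied.
    """

    def __init__(self, input_len: int, embedding_dim: int = 64,
                 base_channels: int = 16, n_blocks: int = 3,
                 kernel: int = 7, stride: int = 2,
                 normalize: bool = True, seed: int = 0):
        if embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        rng = np.random.default_rng(seed)
        self.input_len = input_len
        self.embedding_dim = embedding_dim
        self.normalize = normalize
        self.config = dict(input_len=input_len, embedding_dim=embedding_dim,
                           base_channels=base_channels, n_blocks=n_blocks,
                           kernel=kernel, stride=stride, normalize=normalize)
        self.layers: list = []
        channels = 1
        length = input_len
        for i in range(n_blocks):
            out_ch = base_channels * (2 ** i)
            conv = Conv1D(channels, out_ch, kernel, stride, rng)
            length = conv.out_length(length)
            if length < 1:
                raise ValueError(f"input of {input_len} samples is too short "
                                 f"for {n_blocks} stride-{stride} blocks")
            self.layers += [conv, ReLU()]
            channels = out_ch
        self.layers.append(GlobalAvgPool())
        self.layers.append(Dense(channels, embedding_dim, rng))
        if normalize:
            self.layers.append(L2Normalize())

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Embed a batch of epochs; x is (B, input_len)."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.input_len:
            raise ValueError(
                f"epoch length {x.shape[1]} does not match encoder input "
                f"length {self.input_len}")
        h = x[:, None, :]
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def backward(self, g_embedding: np.ndarray) -> None:
        g = g_embedding
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def params(self):
        out = []
        for layer in self.layers:
            out += layer.params()
        return out

    # --- weight persistence -------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        weights = {}
        for i, (p, _) in enumerate(self.params()):
            weights[f"p{i}"] = p.copy()
        return weights

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        own = self.params()
        if len(weights) != len(own):
            raise ValueError("weight archive does not match architecture")
        for i, (p, _) in enumerate(own):
            src = weights[f"p{i}"]
            if src.shape != p.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p[...] = src


class Adam:
    """Adam optimizer over an encoder's parameter list."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
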