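"""Neural layers used by the graph encoders and the pair model.

All layers follow a channels-last convention: the feature dimension is the
trailing axis, so a batched sequence is ``(batch, length, channels)``.
Weight initialization draws from the ``numpy.random.Generator`` passed to
each constructor, which makes whole models reproducible from one seed.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Module, Parameter, Tensor, concat

__all__ = [
    "Linear",
    "Dropout",
    "BatchNorm1d",
    "LayerNorm",
    "Conv1d",
    "MultiHeadSelfAttention",
    "MLPBlock",
]


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True,
                 dtype=np.float32):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.W = Parameter(rng.uniform(-bound, bound,
                                       size=(in_features, out_features)).astype(dtype))
        self.b = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    __call__ = forward


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Draws its masks from the
    generator it was built with, so runs are seed-reproducible."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape, dtype=np.float32) >= self.p).astype(x.data.dtype)
        return x * (keep / (1.0 - self.p))

    __call__ = forward


class BatchNorm1d(Module):
    """Per-channel normalization over all non-channel axes of the batch.

    Training uses batch statistics (biased variance) and updates running
    buffers; eval mode normalizes with the running statistics.  A training
    batch with a single element has undefined variance and is rejected.
    """

    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            count = int(np.prod([x.shape[a] for a in axes]))
            if count < 2:
                raise ValueError(
                    "batch normalization over a single element is undefined"
                )
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean.data.reshape(-1))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1))
            xhat = (x - mean) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - self.running_mean) * (
                (self.running_var + self.eps) ** -0.5
            )
        return xhat * self.gamma + self.beta

    __call__ = forward


class LayerNorm(Module):
    """Normalization over the trailing (feature) axis of each position."""

    def __init__(self, num_features: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=-1, keepdims=True)
        return (x - mean) * ((var + self.eps) ** -0.5) * self.gamma + self.beta

    __call__ = forward


class Conv1d(Module):
    """Length-preserving 1-D convolution on ``(batch, length, channels)``
    input with odd kernel size and zero padding ``(k-1)/2``."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd (length-preserving)")
        self.kernel_size = kernel_size
        bound = 1.0 / np.sqrt(in_channels * kernel_size)
        self.W = [
            Parameter(rng.uniform(-bound, bound,
                                  size=(in_channels, out_channels)).astype(dtype))
            for _ in range(kernel_size)
        ]
        self.b = Parameter(np.zeros(out_channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        length = x.shape[-2]
        half = (self.kernel_size - 1) // 2
        xp = x.pad_axis(x.ndim - 2, half, half)
        out = None
        for k, Wk in enumerate(self.W):
            term = xp.narrow(x.ndim - 2, k, length) @ Wk
            out = term if out is None else out + term
        return out + self.b

    __call__ = forward


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over the positions of
    ``(batch, length, dim)`` input, with ``heads`` parallel heads of width
    ``dim // heads`` and dropout on the attention weights."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 dropout: float = 0.0, dtype=np.float32):
        super().__init__()
        if dim % heads != 0:
            raise ValueError("dim must be divisible by the head count")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.Wq = Linear(dim, dim, rng, dtype=dtype)
        self.Wk = Linear(dim, dim, rng, dtype=dtype)
        self.Wv = Linear(dim, dim, rng, dtype=dtype)
        self.Wo = Linear(dim, dim, rng, dtype=dtype)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, length, _ = x.shape

        def split(t: Tensor) -> Tensor:
            return t.reshape(b, length, self.heads, self.head_dim).transpose(0, 2, 1, 3)

        q, k, v = split(self.Wq(x)), split(self.Wk(x)), split(self.Wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        attn = self.drop(scores.softmax(axis=-1))
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, length, self.dim)
        return self.Wo(out)

    __call__ = forward


class MLPBlock(Module):
    """Two linear layers around a 1-D batch norm and LeakyReLU:
    ``LeakyReLU(BN(x W1)) W2``."""

    def __init__(self, in_features: int, hidden: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.lin1 = Linear(in_features, hidden, rng, dtype=dtype)
        self.bn = BatchNorm1d(hidden, dtype=dtype)
        self.lin2 = Linear(hidden, out_features, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.lin2(self.bn(self.lin1(x)).leaky_relu())

    __call__ = forward


def stack_rows(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Stack ``(batch, dim)`` tensors into ``(batch, n, dim)`` rows."""
    expanded = [t.reshape(t.shape[0], 1, t.shape[1]) for t in tensors]
    return concat(expanded, axis=axis)
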