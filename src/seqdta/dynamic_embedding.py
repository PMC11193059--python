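"""Dynamic word-embedding layer.

Token indices are mapped to learned vectors, convolved along the sequence
axis with several kernel sizes at once (so each position's vector depends
on its neighbourhood, not just its own token), gated through a highway
layer, and projected back to the model width.  The padding index 0 embeds
to a frozen all-zero vector so padded tails carry no signal.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, concat, embedding_lookup
from .config import DynamicEmbeddingConfig


def _init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)


class Embedding:
    """Token-index lookup table with the padding row frozen at zero."""

    def __init__(self, vocab_size: int, embed_dim: int, rng: np.random.Generator):
        w = rng.normal(0.0, 0.1, size=(vocab_size, embed_dim))
        w[0] = 0.0
        self.weight = Parameter(w)
        self.vocab_size = vocab_size

    def __call__(self, indices: np.ndarray) -> Tensor:
        indices = np.asarray(indices)
        if indices.max(initial=0) >= self.vocab_size:
            raise ValueError("token index out of vocabulary range")
        return embedding_lookup(self.weight, indices)

    def freeze_padding(self) -> None:
        """Zero the padding row's accumulated gradient (call before optimizer step)."""
        if self.weight.grad is not None:
            self.weight.grad[0] = 0.0

    def parameters(self):
        return [self.weight]


class MultiScaleConv:
    """Parallel 1D convolutions (same padding) concatenated channel-wise.

    Kernel ``k`` with ``c`` filters contributes ``c`` output channels whose
    value at position ``i`` depends only on input rows ``i-k//2 .. i+k//2``.
    """

    def __init__(self, config: DynamicEmbeddingConfig, rng: np.random.Generator):
        self.config = config
        e = config.embed_dim
        self.weights = []
        self.biases = []
        for k, c in zip(config.kernel_sizes, config.filter_counts):
            self.weights.append(Parameter(_init(rng, (k * e, c), k * e)))
            self.biases.append(Parameter(np.zeros(c)))

    @staticmethod
    def _windows(x: Tensor, k: int) -> Tensor:
        """im2col: (..., L, E) -> (..., L, k*E) with zero same-padding."""
        if k == 1:
            return x
        left = k // 2
        right = k - 1 - left
        pad_shape = list(x.shape)
        slabs = []
        if left:
            pad_shape[-2] = left
            slabs.append(Tensor(np.zeros(pad_shape)))
        slabs.append(x)
        if right:
            pad_shape[-2] = right
            slabs.append(Tensor(np.zeros(pad_shape)))
        padded = concat(slabs, axis=-2)
        L = x.shape[-2]
        shifted = [padded[..., off:off + L, :] for off in range(k)]
        return concat(shifted, axis=-1)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.config.embed_dim:
            raise ValueError("input must have embed_dim columns")
        blocks = []
        for k, w, b in zip(self.config.kernel_sizes, self.weights, self.biases):
            blocks.append(self._windows(x, k) @ w + b)
        return concat(blocks, axis=-1)

    def parameters(self):
        return self.weights + self.biases


class Highway:
    """Gated residual layer: ``x = g*f + (1-g)*ReLU(W f + b)``, ``g = sigmoid(Wg f + bg)``."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.W = Parameter(_init(rng, (dim, dim), dim))
        self.b = Parameter(np.zeros(dim))
        self.Wg = Parameter(_init(rng, (dim, dim), dim))
        self.bg = Parameter(np.zeros(dim))

    def __call__(self, ft: Tensor) -> Tensor:
        g = (ft @ self.Wg + self.bg).sigmoid()
        transformed = (ft @ self.W + self.b).relu()
        return g * ft + (1.0 - g) * transformed

    def parameters(self):
        return [self.W, self.b, self.Wg, self.bg]


class Projection:
    """Per-position linear map from the hidden width H back to the model width E."""

    def __init__(self, hidden_dim: int, embed_dim: int, rng: np.random.Generator):
        self.W = Parameter(_init(rng, (hidden_dim, embed_dim), hidden_dim))
        self.b = Parameter(np.zeros(embed_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class DynamicWordEmbedding:
    """Full pipeline: lookup -> multi-scale conv -> highway stack -> projection."""

    def __init__(self, vocab_size: int, config: DynamicEmbeddingConfig,
                 rng: np.random.Generator, static: bool = False):
        self.config = config
        self.static = static
        self.embedding = Embedding(vocab_size, config.embed_dim, rng)
        if not static:
            self.conv = MultiScaleConv(config, rng)
            self.highways = [Highway(config.hidden_dim, rng)
                             for _ in range(config.highway_layers)]
            self.project = Projection(config.hidden_dim, config.embed_dim, rng)

    def __call__(self, indices: np.ndarray) -> Tensor:
        x = self.embedding(indices)
        if self.static:
            return x
        h = self.conv(x)
        for hw in self.highways:
            h = hw(h)
        return self.project(h)

    def parameters(self):
        ps = self.embedding.parameters()
        if not self.static:
            ps = ps + self.conv.parameters()
            for hw in self.highways:
                ps += hw.parameters()
            ps += self.project.parameters()
        return ps


def fuse_pocket(protein_vectors: Tensor, pocket_vectors: Tensor) -> Tensor:
    """Position-wise sum of protein and pocket feature matrices.

    The pocket stream is an index array that is zero away from active-site
    positions, so its feature rows vanish there and the sum boosts exactly
    the pocket positions.
    """
    if protein_vectors.shape != pocket_vectors.shape:
        raise ValueError("protein and pocket feature shapes must match")
    return protein_vectors + pocket_vectors
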