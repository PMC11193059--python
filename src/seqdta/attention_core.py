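"""Stacked split-head self-attention over a vector sequence.

The model width E is split into k contiguous blocks of width d_k = E/k.
Each block is projected (without bias) to per-head queries, keys and
values; scaled dot-product attention softmax(Q Kᵀ/√d_k) V runs per head;
the heads are concatenated and linearly mixed by an output matrix.
Padded positions (token index 0) are masked out as attention keys.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, concat, softmax
from .config import AttentionConfig

_MASK_SCORE = -1e9


def split_heads(x: Tensor | np.ndarray, num_heads: int) -> list:
    """Split the last axis into ``num_heads`` contiguous equal blocks."""
    width = x.shape[-1]
    if width % num_heads:
        raise ValueError("feature width must be divisible by the head count")
    d = width // num_heads
    return [x[..., i * d:(i + 1) * d] for i in range(num_heads)]


def head_attention(Q: Tensor, K: Tensor, V: Tensor,
                   key_mask: np.ndarray | None = None,
                   return_weights: bool = False):
    """Scaled dot-product attention for one head.

    ``key_mask`` is a boolean array over key positions (True = attendable);
    masked keys receive a large negative score so they get ~zero weight.
    """
    Q, K, V = Tensor._lift(Q), Tensor._lift(K), Tensor._lift(V)
    d_k = Q.shape[-1]
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    if key_mask is not None:
        bias = np.where(np.asarray(key_mask, dtype=bool), 0.0, _MASK_SCORE)
        scores = scores + Tensor(np.expand_dims(bias, -2))
    weights = softmax(scores, axis=-1)
    out = weights @ V
    if return_weights:
        return out, weights
    return out


def sinusoidal_positional_encoding(length: int, dim: int) -> np.ndarray:
    """Classic fixed sin/cos positional encoding, shape (length, dim)."""
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


class MultiHeadAttention:
    """One split-head attention layer with per-head square projections."""

    def __init__(self, config: AttentionConfig, rng: np.random.Generator):
        self.config = config
        d = config.head_dim
        k = config.num_heads
        scale = 1.0 / np.sqrt(d)
        self.Wq = [Parameter(rng.normal(0, scale, (d, d))) for _ in range(k)]
        self.Wk = [Parameter(rng.normal(0, scale, (d, d))) for _ in range(k)]
        self.Wv = [Parameter(rng.normal(0, scale, (d, d))) for _ in range(k)]
        self.Wo = Parameter(rng.normal(0, 1.0 / np.sqrt(config.model_dim),
                                       (config.model_dim, config.model_dim)))

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None,
                 return_weights: bool = False):
        if x.shape[-1] != self.config.model_dim:
            raise ValueError("input width must equal the attention model width")
        parts = split_heads(x, self.config.num_heads)
        heads, weights = [], []
        for xi, wq, wk, wv in zip(parts, self.Wq, self.Wk, self.Wv):
            out = head_attention(xi @ wq, xi @ wk, xi @ wv,
                                 key_mask=key_mask, return_weights=True)
            heads.append(out[0])
            weights.append(out[1])
        mixed = concat(heads, axis=-1) @ self.Wo
        if return_weights:
            return mixed, weights
        return mixed

    def parameters(self):
        return self.Wq + self.Wk + self.Wv + [self.Wo]


class AttentionStack:
    """``num_layers`` multi-head attention layers with optional residuals."""

    def __init__(self, config: AttentionConfig, rng: np.random.Generator):
        self.config = config
        self.layers = [MultiHeadAttention(config, rng)
                       for _ in range(config.num_layers)]

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None,
                 return_weights: bool = False):
        all_weights = []
        if self.config.use_positional_encoding and self.layers:
            pe = sinusoidal_positional_encoding(x.shape[-2], x.shape[-1])
            x = x + Tensor(pe)
        for layer in self.layers:
            out, w = layer(x, key_mask=key_mask, return_weights=True)
            all_weights.append(w)
            x = x + out if self.config.use_residual else out
        if return_weights:
            return x, all_weights
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]
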