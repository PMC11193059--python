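"""Protein-ligand interaction block and fully connected regression head.

The encoded protein (L_P x E) and ligand (L_S x E) streams interact through
a cross-attention map alpha = P Sᵀ; adaptive average pooling over the ligand
axis collapses alpha to a length-L_P vector beta, which three fully
connected layers (with dropout and PReLU) regress to a scalar affinity.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, concat
from .config import HeadConfig


def cross_attention_map(P: Tensor, S: Tensor) -> Tensor:
    """Interaction map alpha = P @ Sᵀ (plain matrix product)."""
    P, S = Tensor._lift(P), Tensor._lift(S)
    if P.shape[-1] != S.shape[-1]:
        raise ValueError("protein and ligand feature widths must match")
    return P @ S.swapaxes(-1, -2)


def pool_interaction(alpha: Tensor, ligand_mask: np.ndarray | None = None) -> Tensor:
    """Adaptive average pooling of the interaction map to one value per
    protein position (row mean over the ligand axis).

    ``ligand_mask`` (True = real ligand position) restricts the mean to
    non-padding columns so padded tails do not dilute the signal.
    """
    alpha = Tensor._lift(alpha)
    if ligand_mask is None:
        return alpha.mean(axis=-1)
    m = np.asarray(ligand_mask, dtype=float)
    counts = m.sum(axis=-1, keepdims=True)
    counts = np.maximum(counts, 1.0)
    weighted = alpha * Tensor(np.expand_dims(m, -2))
    return weighted.sum(axis=-1) / Tensor(counts)


def prelu(x: Tensor, alpha: Tensor | float) -> Tensor:
    """Parametric ReLU: x for x >= 0, alpha*x for x < 0."""
    x = Tensor._lift(x)
    pos = x.relu()
    neg = x - pos  # = min(0, x)
    return pos + Tensor._lift(alpha) * neg


def dropout(x: Tensor, p: float, rng: np.random.Generator | None,
            train: bool) -> Tensor:
    """Inverted dropout: active only in train mode; eval is the identity."""
    if not train or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in train mode requires an rng")
    keep = (rng.random(x.shape) >= p).astype(float) / (1.0 - p)
    return x * Tensor(keep)


class RegressionHead:
    """Stack of affine layers: affine -> dropout (train) -> PReLU per hidden
    layer, final affine to width 1."""

    def __init__(self, config: HeadConfig, rng: np.random.Generator):
        self.config = config
        widths = config.fc_widths
        self.weights, self.biases, self.alphas = [], [], []
        for w_in, w_out in zip(widths[:-1], widths[1:]):
            self.weights.append(Parameter(rng.normal(0, 1.0 / np.sqrt(w_in),
                                                     (w_in, w_out))))
            self.biases.append(Parameter(np.zeros(w_out)))
        for _ in widths[1:-1]:
            self.alphas.append(Parameter(np.array(config.prelu_init)))

    def __call__(self, beta: Tensor, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        x = Tensor._lift(beta)
        if x.shape[-1] != self.config.fc_widths[0]:
            raise ValueError(
                f"head expects input width {self.config.fc_widths[0]}, got {x.shape[-1]}")
        n_hidden = len(self.weights) - 1
        for i in range(n_hidden):
            x = x @ self.weights[i] + self.biases[i]
            x = dropout(x, self.config.dropout_p, rng, train)
            x = prelu(x, self.alphas[i])
        x = x @ self.weights[-1] + self.biases[-1]
        return x[..., 0]

    def parameters(self):
        return self.weights + self.biases + self.alphas


def mean_pool_concat(P: Tensor, S: Tensor,
                     protein_mask: np.ndarray | None = None,
                     ligand_mask: np.ndarray | None = None) -> Tensor:
    """Ablation interaction: mean-pool each stream over positions and
    concatenate (no cross-attention map)."""

    def pooled(x: Tensor, mask):
        if mask is None:
            return x.mean(axis=-2)
        m = np.asarray(mask, dtype=float)
        counts = np.maximum(m.sum(axis=-1, keepdims=True), 1.0)
        return (x * Tensor(np.expand_dims(m, -1))).sum(axis=-2) / Tensor(counts)

    return concat([pooled(P, protein_mask), pooled(S, ligand_mask)], axis=-1)
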