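"""Full affinity model assembly and checkpoint serialization.

Two streams (protein + pocket, ligand) pass through dynamic word-embedding
layers and separate self-attention stacks; their interaction map is pooled
and regressed to a scalar -log affinity.  Variant flags reproduce the
published ablations (static embedding, no attention, no interaction map,
positional encoding).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .attention_core import AttentionStack
from .autodiff import Tensor
from .config import AttentionConfig, ModelConfig
from .dynamic_embedding import DynamicWordEmbedding, fuse_pocket
from .interaction_head import (RegressionHead, cross_attention_map,
                               mean_pool_concat, pool_interaction)


class AffinityModel:
    """Sequence-only protein-ligand binding affinity regressor."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        static = config.variant == "model-I"
        self.protein_embed = DynamicWordEmbedding(
            config.protein_vocab, config.embedding, rng, static=static)
        self.ligand_embed = DynamicWordEmbedding(
            config.ligand_vocab, config.embedding, rng, static=static)
        att_cfg = config.attention
        if config.variant == "model-IV" and not att_cfg.use_positional_encoding:
            att_cfg = dataclasses.replace(att_cfg, use_positional_encoding=True)
        if config.variant == "model-II":
            att_cfg = dataclasses.replace(att_cfg, num_layers=0)
        self.attention_config = att_cfg
        self.protein_attention = AttentionStack(att_cfg, rng)
        self.ligand_attention = AttentionStack(att_cfg, rng)
        self.head = RegressionHead(config.head, rng)
        # target standardization (set by the trainer; identity by default)
        self.target_mean = 0.0
        self.target_std = 1.0

    # -- forward --------------------------------------------------------------
    def forward(self, protein_idx: np.ndarray, ligand_idx: np.ndarray,
                pocket_idx: np.ndarray | None = None, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Predict standardized affinities for a batch.

        ``protein_idx``/``ligand_idx``: integer arrays (B, L_P)/(B, L_S).
        ``pocket_idx``: same shape as ``protein_idx``; zero away from the
        active site.  Ignored for variant v2; a missing pocket for a
        pocket-aware variant is treated as all zeros (v2 behaviour).
        """
        protein_idx = np.atleast_2d(np.asarray(protein_idx))
        ligand_idx = np.atleast_2d(np.asarray(ligand_idx))
        P = self.protein_embed(protein_idx)
        if self.config.uses_pocket and pocket_idx is not None:
            pocket_idx = np.atleast_2d(np.asarray(pocket_idx))
            P = fuse_pocket(P, self.protein_embed(pocket_idx))
        S = self.ligand_embed(ligand_idx)
        protein_mask = protein_idx != 0
        ligand_mask = ligand_idx != 0
        P = self.protein_attention(P, key_mask=protein_mask)
        S = self.ligand_attention(S, key_mask=ligand_mask)
        if self.config.variant == "model-III":
            beta = mean_pool_concat(P, S, protein_mask, ligand_mask)
        else:
            alpha = cross_attention_map(P, S)
            beta = pool_interaction(alpha, ligand_mask=ligand_mask)
        return self.head(beta, train=train, rng=rng)

    def predict(self, protein_idx, ligand_idx, pocket_idx=None) -> np.ndarray:
        """Deterministic evaluation-mode prediction on the affinity scale."""
        out = self.forward(protein_idx, ligand_idx, pocket_idx, train=False)
        return out.data * self.target_std + self.target_mean

    # -- parameters -----------------------------------------------------------
    def parameters(self):
        return (self.protein_embed.parameters() + self.ligand_embed.parameters()
                + self.protein_attention.parameters()
                + self.ligand_attention.parameters() + self.head.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def freeze_padding(self):
        self.protein_embed.embedding.freeze_padding()
        self.ligand_embed.embedding.freeze_padding()

    # -- checkpoint -----------------------------------------------------------
    def save(self, path: str | Path, manifest: dict | None = None) -> None:
        """Serialize weights (npz) and config/manifest (json sidecar)."""
        path = Path(path)
        if path.suffix != ".npz":
            path = Path(str(path) + ".npz")
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        arrays["target_scale"] = np.array([self.target_mean, self.target_std])
        np.savez(path, **arrays)
        meta = {"config": self.config.to_dict(), "manifest": manifest or {}}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AffinityModel":
        path = Path(path)
        if path.suffix != ".npz":
            path = Path(str(path) + ".npz")
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig.from_dict(meta["config"]))
        with np.load(path) as data:
            for i, p in enumerate(model.parameters()):
                p.data = data[f"p{i}"]
            model.target_mean, model.target_std = data["target_scale"]
        return model
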