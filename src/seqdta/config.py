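"""Architecture configuration dataclasses.

The defaults reproduce the published architecture: 128-D embeddings,
four convolution branches (kernels 1/3/5/7 with 32/32/64/128 filters,
concatenated to a 256-D hidden vector), a single highway layer, a
6-layer 8-head attention stack of width 128, and a 1024/256/64/1 fully
connected regression head over the pooled protein-ligand interaction map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class DynamicEmbeddingConfig:
    embed_dim: int = 128
    kernel_sizes: tuple[int, ...] = (1, 3, 5, 7)
    filter_counts: tuple[int, ...] = (32, 32, 64, 128)
    highway_layers: int = 1

    def __post_init__(self):
        if len(self.kernel_sizes) != len(self.filter_counts):
            raise ValueError("kernel_sizes and filter_counts must have equal length")
        if self.highway_layers < 1:
            raise ValueError("highway_layers must be >= 1")

    @property
    def hidden_dim(self) -> int:
        """H: width of the concatenated convolution output."""
        return sum(self.filter_counts)


@dataclass
class AttentionConfig:
    num_heads: int = 8
    num_layers: int = 6
    model_dim: int = 128
    use_positional_encoding: bool = False
    use_residual: bool = True

    def __post_init__(self):
        if self.model_dim % self.num_heads:
            raise ValueError("model_dim must be divisible by num_heads")

    @property
    def head_dim(self) -> int:
        return self.model_dim // self.num_heads


@dataclass
class HeadConfig:
    fc_widths: tuple[int, ...] = (1024, 256, 64, 1)
    dropout_p: float = 0.1
    prelu_init: float = 0.25

    def __post_init__(self):
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.fc_widths[-1] != 1:
            raise ValueError("final FC width must be 1")


@dataclass
class ModelConfig:
    """Everything needed to build one affinity model.

    ``variant`` selects the published model family:

    - ``"v1"``: protein + pocket + ligand (position-wise pocket fusion)
    - ``"v2"``: protein + ligand only
    - ``"model-I"``: static embedding (convolution/highway branch removed)
    - ``"model-II"``: self-attention stack removed
    - ``"model-III"``: interaction map replaced by mean-pool concatenation
    - ``"model-IV"``: v1 plus sinusoidal positional encoding
    """

    protein_length: int = 1024
    ligand_length: int = 256
    protein_vocab: int = 21
    ligand_vocab: int = 53
    embedding: DynamicEmbeddingConfig = field(default_factory=DynamicEmbeddingConfig)
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    variant: str = "v1"

    _VARIANTS = ("v1", "v2", "model-I", "model-II", "model-III", "model-IV")

    def __post_init__(self):
        if self.variant not in self._VARIANTS:
            raise ValueError(f"variant must be one of {self._VARIANTS}")
        if self.variant == "model-III":
            expect = 2 * self.attention.model_dim
        else:
            expect = self.protein_length
        if self.head.fc_widths[0] != expect:
            raise ValueError(
                f"head.fc_widths[0] must equal {expect} for variant {self.variant}")

    @property
    def uses_pocket(self) -> bool:
        return self.variant in ("v1", "model-I", "model-II", "model-III", "model-IV")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["embedding"] = DynamicEmbeddingConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d["embedding"].items()})
        d["attention"] = AttentionConfig(**d["attention"])
        head = dict(d["head"])
        head["fc_widths"] = tuple(head["fc_widths"])
        d["head"] = HeadConfig(**head)
        return cls(**d)


def small_config(variant: str = "v1", *, num_heads: int = 2,
                 num_layers: int = 2, dropout_p: float = 0.0) -> ModelConfig:
    """A scaled-down configuration for CPU-scale experiments and tests.

    Shrinks sequence lengths and widths (L_P=64, L_S=32, E=16, H=32)
    while keeping every architectural element of the full model.
    """
    emb = DynamicEmbeddingConfig(embed_dim=16, kernel_sizes=(1, 3, 5, 7),
                                 filter_counts=(4, 4, 8, 16))
    att = AttentionConfig(num_heads=num_heads, num_layers=num_layers, model_dim=16,
                          use_positional_encoding=(variant == "model-IV"))
    first = 32 if variant == "model-III" else 64
    head = HeadConfig(fc_widths=(first, 32, 16, 1), dropout_p=dropout_p)
    return ModelConfig(protein_length=64, ligand_length=32,
                       embedding=emb, attention=att, head=head, variant=variant)
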