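"""Token dictionaries and fixed-length label encoding.

Protein and SMILES sequences are encoded character by character against an
ordered token dictionary whose index 0 is reserved for the padding token
``<MASK>``.  Sequences longer than the fixed length are truncated (prefix
kept); shorter sequences are right-padded with zeros.  Two canonical
dictionaries ship with the package: a 21-entry protein dictionary
(alphabetical over the 20 standard amino acids) and a 53-entry SMILES
dictionary.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

PAD_TOKEN = "<MASK>"
PROTEIN_FIXED_LENGTH = 1024
SMILES_FIXED_LENGTH = 256

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TokenDictionary:
    """Ordered single-character token -> index mapping; index 0 is padding.

    Parameters
    ----------
    tokens
        Mapping from token to index.  Must contain ``<MASK> -> 0`` and
        consecutive indices ``0..V-1``.
    ordering_mode
        How non-padding tokens were ranked: ``"frequency"`` (descending
        corpus count, ties lexicographic) or ``"alphabetical"``.
    """

    tokens: dict[str, int]
    ordering_mode: str = "frequency"
    pad_token: str = PAD_TOKEN

    def __post_init__(self):
        if self.tokens.get(self.pad_token) != 0:
            raise ValueError(f"{self.pad_token!r} must map to index 0")
        indices = sorted(self.tokens.values())
        if indices != list(range(len(self.tokens))):
            raise ValueError("indices must be consecutive 0..V-1 without duplicates")

    def __len__(self) -> int:
        return len(self.tokens)

    def __getitem__(self, token: str) -> int:
        return self.tokens[token]

    def __contains__(self, token: str) -> bool:
        return token in self.tokens

    @property
    def inverse(self) -> dict[int, str]:
        return {i: t for t, i in self.tokens.items()}

    def save(self, path: str | Path) -> None:
        """Write the two-column ``token<TAB>index`` text format (pad row first)."""
        rows = sorted(self.tokens.items(), key=lambda kv: kv[1])
        Path(path).write_text("".join(f"{t}\t{i}\n" for t, i in rows))

    @classmethod
    def load(cls, path: str | Path, ordering_mode: str = "frequency") -> "TokenDictionary":
        tokens: dict[str, int] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            tok, idx = line.rsplit("\t", 1)
            tokens[tok] = int(idx)
        return cls(tokens=tokens, ordering_mode=ordering_mode)


@dataclass
class EncodedSequence:
    """Fixed-length integer index array for one sequence."""

    indices: np.ndarray
    original_length: int
    fixed_length: int

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.shape != (self.fixed_length,):
            raise ValueError("indices must have shape (fixed_length,)")


def build_dictionary(corpus, mode: str = "frequency") -> TokenDictionary:
    """Build a :class:`TokenDictionary` from an iterable of sequences.

    ``frequency`` mode ranks tokens by descending corpus character count
    (ties broken lexicographically); ``alphabetical`` by character code.
    An empty corpus yields the padding-only dictionary with a warning.
    """
    if mode not in ("frequency", "alphabetical"):
        raise ValueError(f"unknown ordering mode {mode!r}")
    counts: Counter[str] = Counter()
    for seq in corpus:
        counts.update(seq)
    if not counts:
        warnings.warn("empty corpus: dictionary contains only the padding token")
        return TokenDictionary(tokens={PAD_TOKEN: 0}, ordering_mode=mode)
    if mode == "frequency":
        ordered = sorted(counts, key=lambda t: (-counts[t], t))
    else:
        ordered = sorted(counts)
    tokens = {PAD_TOKEN: 0}
    tokens.update({t: i + 1 for i, t in enumerate(ordered)})
    return TokenDictionary(tokens=tokens, ordering_mode=mode)


def encode(sequence: str, dictionary: TokenDictionary, fixed_length: int) -> EncodedSequence:
    """Label-encode ``sequence`` to a fixed-length index array.

    Characters missing from the dictionary map to the padding index 0 with
    a logged warning (nonstandard residues such as X/B/Z occur in real
    PDB-derived sequences).
    """
    if fixed_length < 1:
        raise ValueError("fixed_length must be >= 1")
    out = np.zeros(fixed_length, dtype=np.int64)
    unknown: set[str] = set()
    for i, ch in enumerate(sequence[:fixed_length]):
        idx = dictionary.tokens.get(ch)
        if idx is None:
            unknown.add(ch)
            idx = 0
        out[i] = idx
    if unknown:
        logger.warning("characters %s not in dictionary; mapped to padding index 0",
                       sorted(unknown))
    return EncodedSequence(indices=out, original_length=len(sequence),
                           fixed_length=fixed_length)


def decode(encoded: EncodedSequence, dictionary: TokenDictionary) -> str:
    """Inverse of :func:`encode` for un-truncated inputs (stops at padding)."""
    inv = dictionary.inverse
    chars = []
    for idx in encoded.indices[: encoded.original_length]:
        if idx == 0:
            break
        chars.append(inv[int(idx)])
    return "".join(chars)


def _load_shipped(name: str, mode: str) -> TokenDictionary:
    ref = resources.files("seqdta.data").joinpath(name)
    with resources.as_file(ref) as path:
        return TokenDictionary.load(path, ordering_mode=mode)


def protein_dictionary() -> TokenDictionary:
    """The shipped 21-entry protein dictionary (pad + 20 amino acids, A=1..Y=20)."""
    return _load_shipped("protein_dict.tsv", "alphabetical")


def smiles_dictionary() -> TokenDictionary:
    """The shipped 53-entry SMILES character dictionary.

    A synthetic frequency-ordered stand-in for a dictionary built from a
    large training corpus: common organic-chemistry SMILES characters rank
    first (C:1, '(':2, ')':3, O:5, '=':10, ...).
    """
    return _load_shipped("smiles_dict.tsv", "frequency")
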