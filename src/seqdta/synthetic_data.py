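"""Synthetic affinity datasets with a planted pocket x ligand signal.

Each record gets a random protein over the 20-letter alphabet with a
contiguous binding pocket, a random character-level SMILES-like ligand
string, and an affinity

    affinity = base
             + w_motif * (#motif inside the pocket) * (#ligand_token in SMILES)
               / normalizer
             + Gaussian(0, noise_sd),      clamped to [2, 12]

The signal is multiplicative between a pocket feature and a ligand
feature, so models without a cross-interaction pathway are measurably
handicapped.  Optional decoy motif copies outside the pocket make pocket
awareness (v1) informative relative to the protein-only variant (v2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AffinityRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SMILES_CHARS = "Cc(=)N1O2n3"  # drawn from the shipped 53-token alphabet
AFFINITY_RANGE = (2.0, 12.0)


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults give a strong, learnable signal with
    mild measurement noise at a desk-scale sample size."""

    n_records: int = 200
    protein_length_range: tuple[int, int] = (40, 60)
    pocket_fraction: float = 0.3
    ligand_length_range: tuple[int, int] = (12, 24)
    motif: str = "KW"
    ligand_token: str = "O"
    w_motif: float = 1.5
    normalizer: float = 2.0
    base_affinity: float = 4.0
    noise_sd: float = 0.1
    max_motif_copies: int = 2
    max_ligand_tokens: int = 4
    decoy_copies: int = 0  # max motif copies planted OUTSIDE the pocket
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.pocket_fraction <= 1.0:
            raise ValueError("pocket_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def planted_affinity(motif_count: int, token_count: int,
                     spec: SyntheticSpec, noise: float = 0.0) -> float:
    """The planted affinity formula (before clamping applied here too)."""
    raw = (spec.base_affinity
           + spec.w_motif * motif_count * token_count / spec.normalizer
           + noise)
    return float(np.clip(raw, *AFFINITY_RANGE))


def _plant(seq: list[str], motif: str, start: int) -> None:
    seq[start:start + len(motif)] = list(motif)


def generate_dataset(spec: SyntheticSpec) -> list[AffinityRecord]:
    """Generate ``spec.n_records`` records; same seed -> identical output."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_records):
        lo, hi = spec.protein_length_range
        plen = int(rng.integers(lo, hi + 1))
        # protein without accidental motif copies: draw, then scrub
        protein = "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, size=plen))
        while spec.motif in protein:  # scrub accidental copies
            protein = protein.replace(spec.motif, spec.motif[0] * len(spec.motif))
        protein = list(protein)
        # contiguous pocket
        pocket_len = max(len(spec.motif) * spec.max_motif_copies + 2,
                         int(round(spec.pocket_fraction * plen)))
        pocket_len = min(pocket_len, plen)
        pocket_start = int(rng.integers(0, plen - pocket_len + 1))
        pocket_positions = list(range(pocket_start + 1, pocket_start + pocket_len + 1))
        # plant motif copies inside the pocket at disjoint slots
        n_motif = int(rng.integers(0, spec.max_motif_copies + 1))
        slot = pocket_start
        for _ in range(n_motif):
            _plant(protein, spec.motif, slot)
            slot += len(spec.motif) + 1
        # decoy copies outside the pocket (after it, or before if no room);
        # the per-record count is random so the total motif count is a noisy
        # proxy for the pocket count
        n_decoys = int(rng.integers(0, spec.decoy_copies + 1)) if spec.decoy_copies else 0
        slot = pocket_start + pocket_len + 1
        for _ in range(n_decoys):
            if slot + len(spec.motif) > plen:
                slot = 0 if pocket_start > spec.decoy_copies * (len(spec.motif) + 1) else None
                if slot is None:
                    break
            _plant(protein, spec.motif, slot)
            slot += len(spec.motif) + 1
        protein_str = "".join(protein)
        # ligand: scrub the signal token, then plant a controlled count
        llo, lhi = spec.ligand_length_range
        llen = int(rng.integers(llo, lhi + 1))
        pool = SMILES_CHARS.replace(spec.ligand_token, "")
        ligand = [pool[j] for j in rng.integers(0, len(pool), size=llen)]
        n_tok = int(rng.integers(0, spec.max_ligand_tokens + 1))
        for pos in rng.choice(llen, size=min(n_tok, llen), replace=False):
            ligand[pos] = spec.ligand_token
        smiles = "".join(ligand)
        motif_count = _count_in_pocket(protein_str, pocket_positions, spec.motif)
        token_count = smiles.count(spec.ligand_token)
        noise = float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0
        records.append(AffinityRecord(
            complex_id=f"syn{i:04d}", protein_seq=protein_str, smiles=smiles,
            affinity=planted_affinity(motif_count, token_count, spec, noise),
            pocket_positions=pocket_positions))
    return records


def _count_in_pocket(protein: str, pocket_positions: list[int], motif: str) -> int:
    """Motif occurrences lying entirely inside the pocket (1-based positions)."""
    pocket = set(pocket_positions)
    count = 0
    start = protein.find(motif)
    while start != -1:
        if all(p in pocket for p in range(start + 1, start + len(motif) + 1)):
            count += 1
        start = protein.find(motif, start + 1)
    return count


def generate_worked_examples() -> list[dict]:
    """Machine-readable fixtures for the canonical label-encoding examples."""
    return [
        {"kind": "protein", "sequence": "PTAPSD", "fixed_length": 6,
         "expected": [13, 17, 1, 13, 16, 3]},
        {"kind": "smiles", "sequence": "C(=O)CCC", "fixed_length": 8,
         "expected": [1, 2, 10, 5, 3, 1, 1, 1]},
    ]
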