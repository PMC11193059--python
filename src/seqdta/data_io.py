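"""Input formats: dataset tables, FASTA, .smi ligand lists, binding-pocket
PDB records and PDBbind-style index files.

A dataset table is a CSV with header columns ``complex_id, protein_seq,
smiles, affinity`` and optionally ``pocket_positions`` (space-separated
1-based residue positions) or ``pocket_seq``.  Affinities are on the
-log molar scale (-logKi / -logKd / -logIC50).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import seq1

from .vocabulary import EncodedSequence, TokenDictionary, encode

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("complex_id", "protein_seq", "smiles", "affinity")


@dataclass
class AffinityRecord:
    """One protein-ligand complex with its measured -log affinity."""

    complex_id: str
    protein_seq: str
    smiles: str
    affinity: float
    pocket_positions: list[int] | None = None  # 1-based into protein_seq
    pocket_seq: str | None = None

    def __post_init__(self):
        if not self.protein_seq:
            raise ValueError(f"{self.complex_id}: empty protein sequence")
        if not self.smiles:
            raise ValueError(f"{self.complex_id}: empty SMILES")
        if self.pocket_positions is not None:
            for p in self.pocket_positions:
                if not 1 <= p <= len(self.protein_seq):
                    raise ValueError(
                        f"{self.complex_id}: pocket position {p} outside protein")


@dataclass
class PocketMask:
    """Fixed-length index array: the protein's token index at pocket
    positions, zero elsewhere."""

    indices: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)


def read_dataset_table(path: str | Path):
    """Read a dataset CSV; returns (records, row_errors).

    ``row_errors`` is a list of (line_number, message) for malformed rows;
    a missing required column is a hard error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset table missing required columns: {missing}")
    records: list[AffinityRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            affinity = float(row["affinity"])
        except ValueError:
            errors.append((line, f"unparseable affinity {row['affinity']!r}"))
            continue
        pocket_positions = None
        if "pocket_positions" in df.columns and row["pocket_positions"].strip():
            try:
                pocket_positions = [int(t) for t in row["pocket_positions"].split()]
            except ValueError:
                errors.append((line, "unparseable pocket_positions"))
                continue
        pocket_seq = row.get("pocket_seq") or None
        try:
            records.append(AffinityRecord(
                complex_id=row["complex_id"], protein_seq=row["protein_seq"],
                smiles=row["smiles"], affinity=affinity,
                pocket_positions=pocket_positions, pocket_seq=pocket_seq))
        except ValueError as exc:
            errors.append((line, str(exc)))
    if errors:
        logger.warning("%d malformed rows in %s: %s", len(errors), path, errors[:5])
    return records, errors


def write_dataset_table(records, path: str | Path) -> None:
    """Write records back to the dataset CSV format."""
    rows = []
    for r in records:
        rows.append({
            "complex_id": r.complex_id, "protein_seq": r.protein_seq,
            "smiles": r.smiles, "affinity": r.affinity,
            "pocket_positions": " ".join(map(str, r.pocket_positions or [])),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA id -> sequence (multi-line sequences joined)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def read_smi(path: str | Path) -> dict[str, str]:
    """.smi file: one ``SMILES [id]`` per line; id defaults to the line number."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        parts = line.split()
        if not parts:
            continue
        name = parts[1] if len(parts) > 1 else f"mol{i + 1}"
        out[name] = parts[0]
    return out


def parse_pocket_pdb(path: str | Path) -> list[tuple[int, str]]:
    """Extract pocket residues from PDB ATOM records.

    Collapses ATOM lines to one entry per (chain, residue number), maps
    3-letter residue names to 1-letter codes (unknown -> 'X' with a
    warning), and orders by chain then residue number.
    """
    seen: dict[tuple[str, int], str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.startswith("ATOM"):
            continue
        resname = line[17:20].strip()
        chain = line[21]
        resnum = int(line[22:26])
        key = (chain, resnum)
        if key in seen:
            continue
        one = seq1(resname.capitalize())
        if one == "X" and resname.upper() not in ("XAA", "UNK"):
            warnings.warn(f"unknown residue name {resname!r}; using 'X'")
        seen[key] = one
    return [(resnum, seen[(chain, resnum)])
            for chain, resnum in sorted(seen)]


def derive_pocket_mask(protein_seq: str, pocket_residues,
                       dictionary: TokenDictionary,
                       fixed_length: int) -> PocketMask:
    """Build the pocket index mask: the protein's own token index at each
    listed (1-based position, residue) pair, zero elsewhere.

    Residue letters are cross-checked against the protein sequence; a
    mismatch warns but the position is honoured.  Out-of-range positions
    are hard errors.
    """
    encoded = encode(protein_seq, dictionary, fixed_length)
    mask = np.zeros(fixed_length, dtype=np.int64)
    for pos, residue in pocket_residues:
        if not 1 <= pos <= len(protein_seq):
            raise ValueError(f"pocket position {pos} outside protein of "
                             f"length {len(protein_seq)}")
        if residue and protein_seq[pos - 1] != residue:
            warnings.warn(f"pocket residue mismatch at position {pos}: "
                          f"pocket says {residue!r}, protein has "
                          f"{protein_seq[pos - 1]!r}")
        if pos - 1 < fixed_length:
            mask[pos - 1] = encoded.indices[pos - 1]
    return PocketMask(indices=mask)


def pocket_mask_from_record(record: AffinityRecord,
                            dictionary: TokenDictionary,
                            fixed_length: int) -> PocketMask:
    """Pocket mask for a dataset record (empty pocket -> all-zero mask)."""
    residues = [(p, record.protein_seq[p - 1])
                for p in (record.pocket_positions or [])]
    return derive_pocket_mask(record.protein_seq, residues, dictionary,
                              fixed_length)


def read_pdbbind_index(path: str | Path) -> dict[str, float]:
    """PDBbind-style index: ``code resolution year -log_value measurement``
    per line; '#' comment lines skipped; duplicate codes -> last wins."""
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 4:
            logger.warning("skipping malformed index line: %r", line)
            continue
        code = fields[0]
        if code in out:
            logger.warning("duplicate PDB code %s; keeping the last occurrence", code)
        out[code] = float(fields[3])
    return out


def encode_records(records, protein_dict: TokenDictionary,
                   smiles_dict: TokenDictionary, protein_length: int,
                   ligand_length: int, with_pocket: bool = True) -> dict:
    """Encode records into batched index arrays for the model."""
    proteins = np.stack([encode(r.protein_seq, protein_dict,
                                protein_length).indices for r in records])
    ligands = np.stack([encode(r.smiles, smiles_dict,
                               ligand_length).indices for r in records])
    out = {"protein": proteins, "ligand": ligands,
           "affinity": np.array([r.affinity for r in records], dtype=np.float64),
           "ids": [r.complex_id for r in records]}
    if with_pocket:
        out["pocket"] = np.stack([
            pocket_mask_from_record(r, protein_dict, protein_length).indices
            for r in records])
    return out
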