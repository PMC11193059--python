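"""Dataset tables, FASTA, .smi, pocket PDB records and index files."""

import numpy as np
import pytest

from seqdta.data_io import (AffinityRecord, derive_pocket_mask, encode_records,
                            parse_pocket_pdb, pocket_mask_from_record,
                            read_dataset_table, read_fasta, read_pdbbind_index,
                            read_smi, write_dataset_table, write_fasta)

CSV = """complex_id,protein_seq,smiles,affinity,pocket_positions
c1,PTAPSD,C(=O)CCC,5.2,1 4
c2,ACDE,CCO,6.0,
c3,GGG,CC,4.1,2
"""


def _pdb_line(serial, atom, resname, chain, resnum):
    return (f"ATOM  {serial:>5} {atom:<4}{resname:>4} {chain}{resnum:>4}    "
            f"{0.0:8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}{0.0:6.2f}")


class TestDatasetTable:
    def test_well_formed_rows_parse(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(CSV)
        records, errors = read_dataset_table(path)
        assert len(records) == 3 and not errors
        assert records[0].pocket_positions == [1, 4]
        assert records[1].pocket_positions is None
        assert records[0].affinity == 5.2

    def test_missing_required_column_is_hard_error(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("complex_id,smiles,affinity\nc1,CC,5\n")
        with pytest.raises(ValueError, match="protein_seq"):
            read_dataset_table(path)

    def test_malformed_rows_reported_with_line_numbers(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("complex_id,protein_seq,smiles,affinity\n"
                        "c1,AC,CC,bad\n"    # line 2: unparseable affinity
                        "c2,AC,,5.0\n"      # line 3: empty smiles
                        "c3,AC,CC,5.0\n")
        records, errors = read_dataset_table(path)
        assert [r.complex_id for r in records] == ["c3"]
        assert sorted(line for line, _ in errors) == [2, 3]

    def test_crlf_endings_parse_identically(self, tmp_path):
        lf, crlf = tmp_path / "lf.csv", tmp_path / "crlf.csv"
        lf.write_bytes(CSV.encode())
        crlf.write_bytes(CSV.replace("\n", "\r\n").encode())
        a, _ = read_dataset_table(lf)
        b, _ = read_dataset_table(crlf)
        assert [r.__dict__ for r in a] == [r.__dict__ for r in b]

    def test_round_trip_write_read(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(CSV)
        records, _ = read_dataset_table(path)
        out = tmp_path / "out.csv"
        write_dataset_table(records, out)
        again, _ = read_dataset_table(out)
        assert [r.complex_id for r in again] == [r.complex_id for r in records]
        assert [r.pocket_positions for r in again] == \
               [r.pocket_positions for r in records]

    def test_out_of_range_pocket_position_rejected(self):
        with pytest.raises(ValueError, match="outside protein"):
            AffinityRecord("x", "ACD", "CC", 5.0, pocket_positions=[4])


class TestFastaAndSmi:
    def test_multiline_sequences_joined(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">p1 some description\nPTAP\nSD\n>p2\nACD\n")
        seqs = read_fasta(path)
        assert seqs == {"p1": "PTAPSD", "p2": "ACD"}

    def test_empty_file_empty_mapping(self, tmp_path):
        path = tmp_path / "e.fasta"
        path.write_text("")
        assert read_fasta(path) == {}

    def test_write_read_round_trip(self, tmp_path):
        seqs = {"a": "PTAPSD", "b": "MKV"}
        path = tmp_path / "w.fasta"
        write_fasta(seqs, path)
        assert read_fasta(path) == seqs

    def test_smi_with_and_without_ids(self, tmp_path):
        path = tmp_path / "l.smi"
        path.write_text("CCO ethanol\nCC\n")
        assert read_smi(path) == {"ethanol": "CCO", "mol2": "CC"}


class TestPocketPdb:
    def test_atoms_collapse_to_residues(self, tmp_path):
        lines = [_pdb_line(1, "N", "GLY", "A", 10),
                 _pdb_line(2, "CA", "GLY", "A", 10),
                 _pdb_line(3, "C", "GLY", "A", 10),
                 _pdb_line(4, "N", "ALA", "A", 11),
                 _pdb_line(5, "CA", "ALA", "A", 11)]
        path = tmp_path / "p.pdb"
        path.write_text("\n".join(lines) + "\n")
        assert parse_pocket_pdb(path) == [(10, "G"), (11, "A")]

    def test_hetatm_only_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "h.pdb"
        path.write_text("HETATM    1  O   HOH A 301       0.0 0.0 0.0\n")
        assert parse_pocket_pdb(path) == []

    def test_unknown_residue_maps_to_x_with_warning(self, tmp_path):
        path = tmp_path / "u.pdb"
        path.write_text(_pdb_line(1, "CA", "XYZ", "A", 5) + "\n")
        with pytest.warns(UserWarning, match="unknown residue"):
            assert parse_pocket_pdb(path) == [(5, "X")]


class TestPocketMask:
    def test_full_pocket_equals_encoded_protein(self, protein_dict):
        protein = "PTAPSD"
        residues = [(i + 1, ch) for i, ch in enumerate(protein)]
        mask = derive_pocket_mask(protein, residues, protein_dict, 6)
        assert mask.indices.tolist() == [13, 17, 1, 13, 16, 3]

    def test_empty_pocket_is_all_zero(self, protein_dict):
        mask = derive_pocket_mask("PTAPSD", [], protein_dict, 8)
        assert not mask.indices.any()

    def test_selected_positions_carry_protein_tokens(self, protein_dict):
        mask = derive_pocket_mask("PTAPSD", [(1, "P"), (4, "P")], protein_dict, 6)
        assert mask.indices.tolist() == [13, 0, 0, 13, 0, 0]

    def test_out_of_range_position_is_hard_error(self, protein_dict):
        with pytest.raises(ValueError, match="outside protein"):
            derive_pocket_mask("ACD", [(9, "A")], protein_dict, 6)

    def test_residue_mismatch_warns_but_honours_position(self, protein_dict):
        with pytest.warns(UserWarning, match="mismatch"):
            mask = derive_pocket_mask("PTAPSD", [(2, "A")], protein_dict, 6)
        assert mask.indices.tolist() == [0, 17, 0, 0, 0, 0]

    def test_pdb_to_mask_pipeline_counts_match(self, tmp_path, protein_dict):
        """Pocket PDB -> residue list -> mask: nonzero count equals the
        pocket residue count when every position maps."""
        protein = "GAVLI"
        lines = [_pdb_line(1, "CA", "GLY", "A", 1),
                 _pdb_line(2, "CA", "VAL", "A", 3)]
        path = tmp_path / "p.pdb"
        path.write_text("\n".join(lines) + "\n")
        residues = parse_pocket_pdb(path)
        mask = derive_pocket_mask(protein, residues, protein_dict, 10)
        assert np.count_nonzero(mask.indices) == len(residues) == 2

    def test_mask_nonzero_positions_subset_of_protein(self, protein_dict):
        record = AffinityRecord("c", "PTAPSD", "CC", 5.0,
                                pocket_positions=[1, 2, 6])
        mask = pocket_mask_from_record(record, protein_dict, 10)
        protein_nonzero = set(np.nonzero(
            np.array([13, 17, 1, 13, 16, 3, 0, 0, 0, 0]))[0])
        assert set(np.nonzero(mask.indices)[0]) <= protein_nonzero


class TestPdbbindIndex:
    def test_documented_layout_parses(self, tmp_path):
        path = tmp_path / "INDEX"
        path.write_text("# comment line\n"
                        "1abc  2.00  1999  5.32  Kd=4.8uM\n"
                        "2xyz  1.80  2005  7.10  Ki=80nM\n")
        assert read_pdbbind_index(path) == {"1abc": 5.32, "2xyz": 7.10}

    def test_all_comment_file_is_empty(self, tmp_path):
        path = tmp_path / "INDEX"
        path.write_text("# a\n# b\n")
        assert read_pdbbind_index(path) == {}

    def test_duplicate_id_last_wins(self, tmp_path):
        path = tmp_path / "INDEX"
        path.write_text("1abc 2.0 1999 5.0 Kd\n1abc 2.0 1999 6.0 Kd\n")
        assert read_pdbbind_index(path) == {"1abc": 6.0}


class TestEncodeRecords:
    def test_every_ingested_record_encodes(self, protein_dict, smiles_dict):
        records = [AffinityRecord("a", "PTAPSD", "C(=O)CCC", 5.0,
                                  pocket_positions=[1, 2]),
                   AffinityRecord("b", "ACDEF", "CCO", 6.0)]
        batch = encode_records(records, protein_dict, smiles_dict, 10, 8)
        assert batch["protein"].shape == (2, 10)
        assert batch["ligand"].shape == (2, 8)
        assert batch["pocket"].shape == (2, 10)
        assert batch["affinity"].tolist() == [5.0, 6.0]
        assert batch["ids"] == ["a", "b"]
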