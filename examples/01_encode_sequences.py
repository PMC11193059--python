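"""Label-encode a protein and a ligand SMILES string.

Each character maps to an integer index from a fixed dictionary (index 0
is padding); sequences are truncated/right-padded to a fixed length.
"""

from seqdta import encode, protein_dictionary, smiles_dictionary

prot_dict = protein_dictionary()
smi_dict = smiles_dictionary()

protein = "PTAPSD"
smiles = "C(=O)CCC"

enc_p = encode(protein, prot_dict, fixed_length=10)
enc_s = encode(smiles, smi_dict, fixed_length=10)

print(f"protein dictionary: {len(prot_dict)} tokens; "
      f"SMILES dictionary: {len(smi_dict)} tokens")
print(f"{protein!r} -> {enc_p.indices.tolist()}")
print(f"{smiles!r} -> {enc_s.indices.tolist()}")
# Nonzero entries are the per-character indices (A=1 ... Y=20 for proteins);
# trailing zeros are padding up to the fixed length.
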