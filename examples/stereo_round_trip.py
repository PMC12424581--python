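"""Chirality-aware encoding: CIP labels ride on fragment tokens.

Parities are perceived on the intact molecule and stored as '|<atom><R|S>'
suffixes; decoding re-imposes the tetrahedral tag that reproduces each
stored label, so enantiomers stay distinct through the round trip.
"""

from fragsmiles import decode_string, encode
from fragsmiles.chem import assigned_stereocenters, canonical_smiles, mol_from_smiles

for name, smiles in [
    ("L-alanine", "N[C@@H](C)C(=O)O"),
    ("D-alanine", "N[C@H](C)C(=O)O"),
    ("(R)-CHFClBr", "F[C@H](Cl)Br"),
    ("threonine-like diol", "C[C@H](O)[C@@H](N)C"),
]:
    tokens = encode(smiles)
    back = canonical_smiles(decode_string(tokens))
    centers = assigned_stereocenters(mol_from_smiles(back))
    ok = back == canonical_smiles(smiles)
    print(f"{name:22s} {tokens:55s} centers={centers} roundtrip={'exact' if ok else 'LOST'}")

# Note the two alanines produce different '|0S' / '|0R' suffixes on the
# alpha-carbon fragment; every round trip restores the same CIP labels.
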