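"""Encode molecules as chemical-word strings and decode them back.

Each token is a whole fragment (node) or a connector bond (edge) of the
reduced graph obtained by cleaving every exocyclic single bond; ring
systems always stay inside a single fragment word.
"""

from fragsmiles import decode_string, encode
from fragsmiles.chem import canonical_smiles

for smiles in ["Cc1ccccc1", "CC(=O)N", "CC(=O)Oc1ccccc1", "CCOC(C)=O"]:
    tokens = encode(smiles)
    back = canonical_smiles(decode_string(tokens))
    print(f"{smiles:20s} -> {tokens:45s} -> {back}")

# The middle column is the fragSMILES string: fragment words (e.g.
# 'c1ccccc1', 'C=O'), connector tokens '-<i>.<j>' naming the attachment
# atom on each side, and '(' ')' wrapping all but the last branch of a
# node.  The right column shows the decoded molecule: identical to the
# input's canonical form in every case.
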