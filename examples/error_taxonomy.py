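"""Plant and classify syntax errors in both notations.

The corruptor mutates a valid string until re-parsing reproduces the
requested error class, so every emission is classification-verified.
Classes differ by notation: fragSMILES has no ring-closure syntax (rings
live inside fragment words), while atom-level SMILES has no connectors.
"""

from fragsmiles import (
    UnreachableClassError,
    check_validity,
    corrupt,
    encode,
    reachable_classes,
)

molecule = "CC(C)[C@H](N)C(=O)Oc1ccccc1"
for notation, ref in [("fragsmiles", encode(molecule)), ("smiles", molecule)]:
    print(f"\n{notation}: {ref}")
    for cls in reachable_classes(notation):
        try:
            bad = corrupt(ref, notation, cls, seed=5)
        except UnreachableClassError as exc:
            print(f"  {cls:22s} unreachable ({exc})")
            continue
        got = check_validity(bad, notation).error_class
        print(f"  {cls:22s} -> {bad[:60]:62s} classified: {got}")

# Every planted corruption is classified back into its own class; trying
# ring_closure_error on fragSMILES (or connector_bond_error on SMILES)
# raises UnreachableClassError instead of emitting a bogus fixture.
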