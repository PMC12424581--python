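# fragsmiles

Fragment- and chirality-aware molecular strings, plus the evaluation
toolkit used to benchmark string notations for reaction prediction and
retrosynthesis.

## The problem

Sequence-to-sequence models for synthesis planning read and write
molecules as strings. Atom-level notations (SMILES, SELFIES, ...) make the
model spell out every ring-closure digit, branch parenthesis and chiral
tag, and a single wrong character yields an unparseable or stereochemically
illegal molecule. This package implements a *chemical-word* notation that
sidesteps both failure modes, and the scoring machinery needed to compare
notations fairly.

## The notation

A molecule is turned into a string in three steps:

1. **Cleave** every exocyclic single bond between heavy atoms. Ring bonds,
   double/triple bonds and bonds to hydrogen are never cut, so each ring
   system survives intact.
2. **Collapse** the resulting fragments into the nodes of a *reduced
   graph* — necessarily a forest — whose edges remember the attachment
   atom on each side by a context-free local index.
3. **Serialize** the forest depth-first as space-separated words:
   - *fragment words*: the canonical SMILES of the hydrogen-capped
     fragment, e.g. `c1ccccc1`, `C=O`; a stereocenter adds a suffix
     `|<atom><R|S>` carrying its CIP label perceived on the intact
     molecule (`C|0S`);
   - *connector tokens* `-<i>.<j>`: local atom `i` of the parent fragment
     bonds to local atom `j` of the child;
   - `(` `)` wrap all but the last child of a node; `.` separates
     disconnected molecules.

Encoding is canonical (one molecule, one string, for any input atom
order) and exactly invertible, stereocenters included: decoding rebuilds
the cleaved bonds and re-imposes each stored CIP label by choosing the
tetrahedral tag that reproduces it.

Because a whole ring is one vocabulary word, sequences are several-fold
shorter than atom-level SMILES and contain no ring-closure syntax at all;
the notation's own failure modes are confined to connector bookkeeping,
which the error taxonomy below makes measurable.

## The evaluation stack

- `check_validity` — chirality-aware validity: a candidate counts as valid
  only if it parses *and* every stereo annotation sits on a perceivable
  stereocenter; failures are classified into a six-class syntax-error
  taxonomy (`chirality`, `ring_closure`, `branch`, `connector_bond`,
  `valence`, `token`).
- `topk_report` — cumulative top-k validity and accuracy over ranked beam
  candidates (match = stereo-sensitive canonical multiset equality,
  denominator = all test records).
- `similarity_of_errors` — Tanimoto on 2048-bit radius-2 Morgan
  fingerprints between valid-but-wrong top-1 products and the truth.
- `overlap_correct` — pairwise percentage overlap of correct-prediction
  sets across notations.
- `substructure_report` — which substructure level a wrong prediction got
  right: ring systems, Bemis–Murcko scaffold, acyclic substituents.
- Reaction plumbing: reaction-SMILES reading, curation (no-ops,
  duplicates), stereo subset tagging (conserved / created / destroyed /
  stereoselective), forward/retro pair construction and leakage-free
  splits.
- `fixtures` + `harness` — synthetic molecule/reaction generators with
  controllable ring and stereocenter content, a corruptor that plants
  verification-checked syntax errors, and memorizer/mock predictors so the
  whole prepare → predict → evaluate path runs without a trained model.

## Worked example

```python
>>> from fragsmiles import encode, decode_string
>>> from fragsmiles.chem import canonical_smiles
>>> encode("N[C@@H](C)C(=O)O")          # L-alanine
'C -0.0 C|0S ( -0.0 C=O -0.0 O ) -0.0 N'
>>> encode("N[C@H](C)C(=O)O")           # D-alanine differs only in |0R
'C -0.0 C|0R ( -0.0 C=O -0.0 O ) -0.0 N'
>>> canonical_smiles(decode_string('C -0.0 C|0S ( -0.0 C=O -0.0 O ) -0.0 N'))
'C[C@H](N)C(=O)O'
```

The two enantiomers differ only in the `|0S` / `|0R` suffix on the
alpha-carbon fragment, and the decoded string is the exact canonical form
of the input. Compactness comes from rings — aspirin
(`CC(=O)Oc1ccccc1C(=O)O`) encodes as

```
C -0.0 C=O -0.0 O -0.2 c1ccccc1 -3.0 C=O -0.0 O
```

11 chemical words against 21 atom-level SMILES tokens, with the benzene
ring a single vocabulary word. The scripts in `examples/` walk through
each capability (encoding, stereo round trips, reaction preparation,
candidate scoring, error planting, compactness) and print what the
numbers mean.

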