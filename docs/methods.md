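# Methods

This note documents the model behind the notation, the choices that were
genuinely open, the synthetic-data conditions, and what the test suite
does and does not demonstrate.

## Fragmentation model

The cleavage rule is fixed: every single bond between two heavy atoms that
belongs to no ring is cut. Consequences worth stating explicitly:

- acyclic regions decompose to single-heavy-atom fragments unless held
  together by a double or triple bond (acetamide gives `C`, `C=O`, `N`);
- fused and bridged ring systems share ring bonds and therefore collapse
  into one node;
- the reduced graph is always a forest: any cycle of the parent molecule
  lies inside one node, so `|edges| = |nodes| − |components|`;
- bonds to hydrogen are never cut and hydrogens stay implicit.

Fragment words are the canonical SMILES of the *hydrogen-capped* induced
subgraph: each severed bond is replaced by a hydrogen. This is what makes
the word context-free — a piperidine ring reads `C1CCNCC1` no matter what
it was attached to — at the cost of some bookkeeping at decode time
(restoring a bond consumes one hydrogen cap on each side). The cap is
implicit for ordinary atoms; an explicit-H increment is applied only where
RDKit will not recompute implicit counts, i.e. fixed-valence bracket atoms
(`[NH3+]`, quaternary nitrogen, which caps to `[NH4+]`) and aromatic
non-carbons (the ring of N-methylpyrrole caps to `c1cc[nH]c1`, the same
word plain pyrrole produces).

## Chirality

Tetrahedral parities are stored as CIP R/S labels perceived on the intact
molecule, attached to the owning fragment as `(local atom, label)` pairs.
CIP labels — unlike `@`/`@@` tags — are independent of atom order and of
fragment-local neighbor enumeration, which is what makes the suffix
portable. Decoding seeds every labelled center with a clockwise tag,
perceives CIP on the reassembled molecule, and flips mismatching centers
until the labels agree; interdependent centers that fail to converge fall
back to exhaustive enumeration over tag assignments (bounded at 12
centers). A label that no assignment can realize, or a label on an atom
that is not a perceivable stereocenter, raises a chirality error — such
inputs are flagged, never silently dropped.

Double-bond (E/Z) stereo is preserved only when all four defining atoms
fall inside one fragment (it is then copied into the fragment word).
Cross-fragment E/Z assignments are not carried by the notation; the
fixture generator produces none, so round-trip guarantees quoted below are
for tetrahedral stereo.

## Canonical determinism

One molecule must map to one string regardless of input atom order.
RDKit's canonical atom ranking breaks symmetry ties in an input-dependent
way, so determinism is obtained structurally: the parent molecule is
re-parsed from its own canonical SMILES before fragmentation, making every
downstream index decision a pure function of the molecular graph.
Fragment-local numbering is the canonical SMILES output order of the
fragment in isolation; the serialization root is the node with the
lexicographically smallest `(fragment word, degree)` pair (ties by
smallest parent atom rank), and children are visited in ascending
`(parent attachment index, child word)` order.

## Token grammar

The grammar is a deliberately simple, whitespace-tokenizable dialect:
fragment words with optional `|<i><R|S>` suffixes, connectors `-<i>.<j>`,
branch words `(` `)`, separator `.`. Token class is decidable from the
first character, so corpus files tokenize by splitting on spaces. The
contract of the parser is semantic: `parse(serialize(g))` is isomorphic to
`g`, and `decode(parse(encode(m)))` restores `m`'s canonical form
exactly. Surface-syntax compatibility with other chemical-word dialects
is a non-goal.

Parse and decode failures map onto six stable error classes
(`token_error`, `branch_error`, `connector_bond_error`,
`chirality_error`, `valence_error`, plus `ring_closure_error` for
atom-level notations). For SMILES, whose reference parser reports no
categories, a light pre-scan classifies unbalanced parentheses and
unpaired ring-closure digits before RDKit parses the string; sanitize
failures map to valence errors and chiral tags on non-stereocenters
(detected via potential-stereo perception on an unsanitized parse) to
chirality errors.

## Evaluation semantics

- **Validity** is cumulative in k ("any of the first k candidates is
  valid") and chirality-aware: syntactic parse success plus legal stereo
  annotation.
- **Accuracy** is cumulative, stereo-sensitive, order-free multiset
  equality of canonical component SMILES, with all test records as the
  denominator (not only valid generations). Retro-direction matching
  compares the full reactant+reagent multiset; no partial credit.
- **Similarity of errors** uses stereo-insensitive 2048-bit radius-2
  Morgan fingerprints, so a parity-flipped but otherwise correct product
  scores 1.0 — deliberately separating "wrong molecule" from "wrong
  stereochemistry".
- **Overlap** entries are |A∩B|/|A|×100 and intentionally asymmetric.
- **Substructure grouping** compares multisets of ring-containing
  fragment words, acyclic fragment words, and per-component Bemis–Murcko
  scaffolds, all stereo-free.

Stereo subset tags for reactions: *conserved* means identical
(environment, parity) multisets on both sides, where an environment is the
stereo-free canonical SMILES of the radius-2 neighborhood with the center
marked; *created*/*destroyed* mean one side's multiset strictly contains
the other's; everything else — parity flips, substitution at a center,
simultaneous creation and destruction — is *stereoselective*. These
definitions are explicit but provisional: an SN2 displacement changes the
center's environment along with its parity, and this rule deliberately
classifies it as stereoselective rather than created+destroyed.

## Synthetic data

The generator assembles molecules from curated building blocks (ten ring
systems, nine chains/heteroatom units, three halogens) by random
single-bond joining, which guarantees validity by construction. Defaults:
2–5 blocks per molecule, ≤30 heavy atoms, ring probability 0.7, stereo
probability 0.5 — chosen as a plausible drug-like mix in which both ring
handling and stereochemistry are constantly exercised; both probabilities
are enforced per molecule, not just in expectation (a stereocenter is
grafted via a C(F)Cl unit when random assembly yields none). Reaction
fixtures come from four template families with known ground-truth tags:
esterification (achiral), SN2 azide/cyanide displacement (parity
inversion), ketone reduction (center creation), and an untouched-spectator
esterification (conservation).

What the generator does *not* emulate: USPTO-scale reaction diversity,
reagent-role ambiguity, atom-mapping noise, macrocycles, organometallics,
axial/double-bond stereochemistry. Passing tests therefore demonstrate
correctness of the notation and of the metric machinery on controlled
chemistry, not model performance on patent data.

The corruptor verifies every emission by re-parsing before returning it,
so taxonomy tests measure classification *stability*, not luck; classes
that cannot exist in a notation (ring-closure errors in chemical-word
strings, connector errors in atom-level strings or in connector-free
sequences) raise an explicit unreachable-class signal instead.

## Predictors

The memorizer returns stored targets for seen sources (rank 1) and
nearest-neighbour targets by token-set Jaccard overlap otherwise — an
oracle that exercises the full prepare → predict → evaluate path. The
mock predictor samples per-rank outcome categories (match,
valid-but-wrong, or a planted error class) with configured probabilities,
independently per record and rank, so observed cumulative top-k metrics
can be checked against closed-form expectations
`1 − Π(1 − p_rank)` within binomial confidence bounds. Determinism is
guaranteed by seeding every stream from CRC32 of the content rather than
Python's process-randomized `hash()`. Transformer training and beam
search are out of scope; any external model plugs in through the same
predict surface.

## Problem sizes and numerical choices

The acceptance script and test suite run at: 1000 molecules for
round-trip fidelity, 100 permutations × 50 molecules for determinism, 500
molecules for graph invariants, 500 trials per reachable error class, and
1000 records × 5 ranks for metric recovery (3σ binomial tolerance, the
standard bound for a stochastic recovery check). These sizes give
sub-minute module runtimes while keeping binomial standard errors below
1.6 percentage points. Derived seeds are masked to 31 bits. The
decode-side CIP search is exact, not heuristic: the flip loop converges
for independent centers in one pass, and the exhaustive fallback bounds
the worst case.

## Known limitations

- Cross-fragment double-bond stereo is not encoded (flagged above).
- Stereocenters RDKit cannot label with CIP (unstable or undefined CIP
  under symmetry) raise an unsupported-stereo error at encode time.
- The SELFIES/SAFE/t-SMILES codecs are not bundled; the registry accepts
  external codecs implementing the same four-method surface.
- Reaction curation implements generic filters (parse failure, no-op,
  exact duplicate); corpus-specific cleaning beyond that is the caller's
  responsibility.
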