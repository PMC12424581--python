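"""Token grammar, round trips, canonical determinism and token stats."""

import random

import pytest
from rdkit import Chem

from fragsmiles import (
    BranchError,
    ChiralityError,
    ConnectorBondError,
    TokenError,
    decode,
    decode_string,
    encode,
    fragment_molecule,
    parse,
    serialize,
    token_stats,
    tokenize,
)
from fragsmiles.chem import atom_level_tokens, canonical_smiles, mol_from_smiles


@pytest.mark.parametrize(
    "smiles, n_tokens, kinds",
    [
        ("c1ccccc1", 1, ["fragment"]),
        ("Cc1ccccc1", 3, ["fragment", "connector", "fragment"]),
        (
            "c1ccccc1.c1ccccc1",
            3,
            ["fragment", "molecule_separator", "fragment"],
        ),
    ],
)
def test_serialize_token_shapes(smiles, n_tokens, kinds):
    seq = serialize(fragment_molecule(smiles))
    assert len(seq) == n_tokens
    assert seq.kinds() == kinds


def test_branch_tokens_wrap_all_but_last_child():
    # neopentane: the root is a terminal methyl (smallest word/degree), so
    # the central carbon keeps 3 children -> 2 of them are branch-wrapped
    seq = serialize(fragment_molecule("CC(C)(C)C"))
    words = str(seq).split()
    assert words.count("(") == 2
    assert words.count(")") == 2
    assert words.count("C") == 5


@pytest.mark.parametrize(
    "smiles",
    [
        "CCO",
        "CC(=O)N",
        "N[C@@H](C)C(=O)O",
        "F[C@H](Cl)Br",
        "Cn1cccc1",
        "C[N+](C)(C)C",
        "CS(=O)(=O)c1ccc(Br)cc1",
        "O=C(O)[C@@H]1CCCN1",
        "C[C@H](O)[C@@H](N)C",
        "CC(F)(Cl)c1ccc(cc1)[C@@H](N)CC",
        "c1ccccc1.CCO",
    ],
)
def test_round_trip_canonical_form(smiles):
    """decode(parse(encode(m))) restores the exact canonical isomeric form,
    stereocenters included."""
    assert canonical_smiles(decode_string(encode(smiles))) == canonical_smiles(
        smiles
    )


def test_round_trip_generated_corpus(small_corpus):
    for smi in small_corpus:
        assert canonical_smiles(decode_string(encode(smi))) == canonical_smiles(
            smi
        )


def test_parse_serialize_is_isomorphic_round_trip(small_corpus):
    for smi in small_corpus[:20]:
        raw = encode(smi)
        assert str(serialize(parse(raw))) == raw


def test_encode_invariant_under_atom_permutation(small_corpus):
    rng = random.Random(0)
    for smi in small_corpus[:15]:
        mol = mol_from_smiles(smi)
        outs = set()
        for _ in range(25):
            perm = list(range(mol.GetNumAtoms()))
            rng.shuffle(perm)
            shuffled = Chem.MolToSmiles(
                Chem.RenumberAtoms(mol, perm), canonical=False
            )
            outs.add(encode(shuffled))
        assert len(outs) == 1


def test_encode_idempotent_through_round_trip():
    smi = "CC(C)[C@H](N)C(=O)O"
    once = encode(smi)
    assert encode(canonical_smiles(decode_string(once))) == once


@pytest.mark.parametrize(
    "mutation, error",
    [
        (lambda w: w + [")"], BranchError),
        (lambda w: ["("] + w, BranchError),
        (lambda w: w + ["-0.0"], ConnectorBondError),
        (lambda w: w + ["?garbage?"], TokenError),
        (lambda w: [".", *w], TokenError),
        (lambda w: [*w, "."], TokenError),
    ],
)
def test_parse_error_classes(mutation, error):
    words = encode("CC(=O)Oc1ccccc1").split()
    with pytest.raises(error):
        parse(" ".join(mutation(words)))


def test_connector_index_out_of_range_is_connector_error():
    raw = encode("Cc1ccccc1")
    words = raw.split()
    conn = next(i for i, w in enumerate(words) if w.startswith("-"))
    pi, ci = words[conn][1:].split(".")
    words[conn] = f"-{int(pi) + 50}.{ci}"
    with pytest.raises(ConnectorBondError):
        parse(" ".join(words))


def test_conflicting_chirality_suffix_is_chirality_error():
    with pytest.raises(ChiralityError):
        parse("C|0R|0S")


def test_chirality_suffix_index_out_of_range():
    with pytest.raises(ChiralityError):
        parse("C|3R")


def test_decode_flipped_parity_gives_enantiomer():
    """Flipping the stored label of L-alanine's alpha carbon decodes to
    D-alanine."""
    graph = fragment_molecule("N[C@@H](C)C(=O)O")
    from fragsmiles import assign_fragment_chirality

    assign_fragment_chirality("N[C@@H](C)C(=O)O", graph)
    for node in graph.nodes:
        node.chirality_labels = [
            (i, "R" if p == "S" else "S") for i, p in node.chirality_labels
        ]
    d_ala = canonical_smiles(decode(graph))
    assert d_ala == canonical_smiles("N[C@H](C)C(=O)O")
    assert d_ala != canonical_smiles("N[C@@H](C)C(=O)O")


def test_chirality_label_on_non_stereocenter_fails_decode():
    graph = parse("C -0.0 C")
    graph.nodes[0].chirality_labels = [(0, "R")]
    with pytest.raises(ChiralityError):
        decode(graph)


def test_no_ring_closure_syntax_outside_fragment_words(small_corpus):
    """Every non-fragment token is a connector, branch or separator word;
    ring-closure digits therefore only occur inside fragment words."""
    import re

    connector = re.compile(r"^-\d+\.\d+$")
    for smi in small_corpus:
        for tok in tokenize(encode(smi)).tokens:
            if tok.kind == "connector":
                assert connector.match(tok.word)
            elif tok.kind != "fragment":
                assert tok.word in ("(", ")", ".")


def test_token_stats_counts_and_fractions(small_corpus):
    corpus = [encode(s) for s in small_corpus]
    stats = token_stats(corpus)
    assert stats["n_sequences"] == len(corpus)
    assert stats["vocabulary_size"] == len(stats["vocabulary"])
    assert sum(stats["kind_fractions"].values()) == pytest.approx(1.0)
    single = token_stats([encode("c1ccccc1")])
    assert single["vocabulary_size"] == 1
    assert single["length_quantiles"]["median"] == 1


def test_token_stats_rejects_empty_corpus():
    with pytest.raises(ValueError):
        token_stats([])


def test_vocabulary_file_is_frequency_sorted(tmp_path, small_corpus):
    from fragsmiles import write_vocabulary

    path = tmp_path / "vocab.txt"
    write_vocabulary([encode(s) for s in small_corpus[:20]], str(path))
    lines = path.read_text().splitlines()
    assert lines[:3] == ["(", ")", "."]  # reserved words lead
    assert len(lines) == len(set(lines))  # no duplicates


def test_compactness_on_ring_corpus(small_corpus):
    """Chemical-word sequences are shorter than atom-level SMILES token
    sequences on ring-containing molecules."""
    import numpy as np

    ringy = [s for s in small_corpus if mol_from_smiles(s).GetRingInfo().NumRings()]
    frag_lens = [len(encode(s).split()) for s in ringy]
    smi_lens = [len(atom_level_tokens(canonical_smiles(s))) for s in ringy]
    assert np.median(frag_lens) < np.median(smi_lens)
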