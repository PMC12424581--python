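"""Reaction reading, curation, task pairs, stereo tagging and splitting."""

import pytest

from fragsmiles import (
    ConfigError,
    curate,
    get_codec,
    make_pair,
    read_reaction_line,
    read_reactions,
    split,
    tag_stereo,
)
from fragsmiles.reactions import ReactionRecord


def test_read_esterification_line():
    rec = read_reaction_line("CCO.CC(=O)O>>CCOC(C)=O")
    assert len(rec.reactants) == 2
    assert len(rec.reagents) == 0
    assert len(rec.products) == 1
    assert rec.has_stereocenter is False


def test_read_rejects_wrong_arrow_count():
    with pytest.raises(ValueError):
        read_reaction_line("CCO.CC(=O)O>CCOC(C)=O")
    with pytest.raises(ValueError):
        read_reaction_line("CCO>O>S>CCOC(C)=O")


def test_read_rejects_unparseable_component():
    with pytest.raises(ValueError):
        read_reaction_line("CCO.X$Y>>CCOC(C)=O")


def test_stereo_flag_from_either_side():
    assert read_reaction_line("F[C@H](Cl)Br>>FC(Cl)Br").has_stereocenter
    assert read_reaction_line("FC(Cl)Br>>F[C@H](Cl)Br").has_stereocenter


def test_atom_maps_are_stripped():
    rec = read_reaction_line("[CH3:1][OH:2]>>[CH3:1][O:2][CH3:1].[OH2:2]")
    assert all(":" not in s for s in rec.reactants + rec.products)


def test_curate_drops_duplicates_and_noops():
    lines = [
        "CCO.CC(=O)O>>CCOC(C)=O",
        "CCO>>CCO",  # no-op
        "CC(=O)O.CCO>>CCOC(C)=O",  # same canonical key as line 1
        "CO.CC(=O)O>>COC(C)=O",
    ]
    records, log = read_reactions(lines)
    kept, log = curate(records, log)
    assert [r.record_id for r in kept] == ["r0", "r3"]
    assert log.counts() == {"no_op": 1, "duplicate": 1}


def test_curate_planted_fixture_bookkeeping():
    """100 reactions with 10 planted duplicates and 5 planted no-ops leave
    85 survivors."""
    base = [
        f"{'C' * (i + 1)}O.CC(=O)O>>{'C' * (i + 1)}OC(C)=O" for i in range(85)
    ]
    lines = base + base[:10] + ["CCN>>CCN"] * 5
    records, log = read_reactions(lines)
    kept, log = curate(records, log)
    assert len(kept) == 85
    assert log.counts()["duplicate"] == 10
    assert log.counts()["no_op"] == 5


@pytest.mark.parametrize("notation", ["fragsmiles", "smiles"])
def test_make_pair_forward_and_retro_are_mirrors(notation):
    rec = read_reaction_line("CCO.CC(=O)O>OS(=O)(=O)O>CCOC(C)=O")
    fwd = make_pair(rec, "forward", notation)
    rev = make_pair(rec, "retro", notation)
    assert fwd.source == rev.target
    assert fwd.target == rev.source
    codec = get_codec(notation)
    # reagents ride with reactants on the forward source side
    assert len(fwd.source.split(codec.separator)) == 3
    assert len(fwd.target.split(codec.separator)) == 1


def test_pair_strings_round_trip_through_codec():
    rec = read_reaction_line("N[C@@H](C)C(=O)O.CO>>N[C@@H](C)C(=O)OC.O")
    for notation in ("fragsmiles", "smiles"):
        pair = make_pair(rec, "forward", notation)
        codec = get_codec(notation)
        for raw in (pair.source, pair.target):
            comps = codec.canonical_components(raw)
            assert codec.join([codec.encode(c) for c in sorted(comps)])


@pytest.mark.parametrize(
    "line, expected",
    [
        ("CCO.CC(=O)O>>CCOC(C)=O", "none"),
        # SN2 azide displacement inverts the center
        ("C[C@@H](Br)CC.[N-]=[N+]=[N-]>>C[C@H](N=[N+]=[N-])CC", "stereoselective"),
        # ketone reduction creates a stereocenter
        ("CC(=O)CC>[H][H]>C[C@H](O)CC", "created"),
        # decarboxylation-style loss of the only stereocenter
        ("C[C@H](N)C(=O)O>>CCN", "destroyed"),
        # untouched spectator center
        ("C[C@H](N)C(=O)O.CO>>C[C@H](N)C(=O)OC.O", "conserved"),
    ],
)
def test_tag_stereo_subsets(line, expected):
    rec = read_reaction_line(line)
    has, tag = tag_stereo(rec)
    assert tag == expected
    assert has == (expected != "none")


def test_tag_agrees_with_template_ground_truth(reaction_fixtures):
    records, truths = reaction_fixtures
    for rec, truth in zip(records, truths):
        assert rec.stereo_tag == truth


def test_split_is_reproducible_and_exhaustive():
    lines = [f"{'C' * (i + 1)}O.CC(=O)O>>{'C' * (i + 1)}OC(C)=O" for i in range(100)]
    records, _ = read_reactions(lines)
    a = split(records, (0.8, 0.1, 0.1), seed=3)
    b = split(records, (0.8, 0.1, 0.1), seed=3)
    assert {len(a[k]) for k in a} == {80, 10, 10}
    for part in a:
        assert [r.record_id for r in a[part]] == [r.record_id for r in b[part]]
    all_ids = sorted(r.record_id for part in a.values() for r in part)
    assert all_ids == sorted(r.record_id for r in records)


def test_split_keeps_duplicate_keys_together():
    lines = ["CCO.CC(=O)O>>CCOC(C)=O"] * 4 + [
        f"{'C' * (i + 2)}O.CC(=O)O>>{'C' * (i + 2)}OC(C)=O" for i in range(16)
    ]
    records, _ = read_reactions(lines)
    parts = split(records, (0.5, 0.25, 0.25), seed=0)
    homes = {
        part
        for part, recs in parts.items()
        for r in recs
        if r.key == records[0].key
    }
    assert len(homes) == 1


def test_split_rejects_bad_fractions():
    with pytest.raises(ConfigError):
        split([], (0.5, 0.2, 0.2), seed=0)


def test_reaction_line_round_trip():
    line = "CCO.CC(=O)O>OS(=O)(=O)O>CCOC(C)=O"
    rec = read_reaction_line(line)
    again = read_reaction_line(rec.to_line())
    assert again.key == rec.key
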