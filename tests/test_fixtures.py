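"""Generator guarantees and corruptor class accuracy."""

import pytest

from fragsmiles import (
    GeneratorConfig,
    UnreachableClassError,
    check_validity,
    corrupt,
    corrupt_to_valid_variant,
    encode,
    gen_molecules,
    gen_reactions,
    reachable_classes,
    read_reaction_line,
)
from fragsmiles.chem import (
    assigned_stereocenters,
    canonical_smiles,
    mol_from_smiles,
)


def test_generation_is_reproducible():
    a = gen_molecules(GeneratorConfig(n=10, seed=7))
    b = gen_molecules(GeneratorConfig(n=10, seed=7))
    assert a == b
    c = gen_molecules(GeneratorConfig(n=10, seed=8))
    assert a != c


def test_stereo_probability_extremes():
    none = gen_molecules(GeneratorConfig(n=15, seed=1, stereo_probability=0.0))
    assert all(not assigned_stereocenters(mol_from_smiles(s)) for s in none)
    full = gen_molecules(GeneratorConfig(n=15, seed=1, stereo_probability=1.0))
    assert all(assigned_stereocenters(mol_from_smiles(s)) for s in full)


def test_ring_probability_extremes():
    ringless = gen_molecules(GeneratorConfig(n=10, seed=2, ring_probability=0.0))
    assert all(
        mol_from_smiles(s).GetRingInfo().NumRings() == 0 for s in ringless
    )
    ringed = gen_molecules(GeneratorConfig(n=10, seed=2, ring_probability=1.0))
    assert all(mol_from_smiles(s).GetRingInfo().NumRings() > 0 for s in ringed)


def test_generated_molecules_are_canonical_and_encodable(small_corpus):
    for smi in small_corpus:
        assert canonical_smiles(smi) == smi
        assert check_validity(encode(smi), "fragsmiles").valid


def test_reaction_lines_are_parseable(reaction_fixtures):
    records, truths = reaction_fixtures
    assert len(records) == len(truths) == 60
    for rec in records:
        again = read_reaction_line(rec.to_line())
        assert again.key == rec.key


def test_bad_config_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(n=0)
    with pytest.raises(ValueError):
        GeneratorConfig(n=1, ring_probability=1.5)


@pytest.mark.parametrize("notation", ["fragsmiles", "smiles"])
def test_corruptor_plants_every_reachable_class(notation, small_corpus):
    """Emitted corruptions reproduce their requested class on re-parse, for
    every reachable (notation, class) pair."""
    for smi in small_corpus[:10]:
        ref = encode(smi) if notation == "fragsmiles" else canonical_smiles(smi)
        for cls in reachable_classes(notation):
            try:
                bad = corrupt(ref, notation, cls, seed=3)
            except UnreachableClassError:
                continue  # legitimately unreachable for this string
            res = check_validity(bad, notation)
            assert not res.valid
            assert res.error_class == cls


def test_connector_error_unreachable_on_single_fragment_string():
    assert encode("c1ccccc1") == "c1ccccc1"  # no connector token exists
    with pytest.raises(UnreachableClassError):
        corrupt("c1ccccc1", "fragsmiles", "connector_bond_error", seed=0)


def test_ring_closure_unreachable_in_fragsmiles():
    with pytest.raises(UnreachableClassError):
        corrupt(encode("Cc1ccccc1"), "fragsmiles", "ring_closure_error", seed=0)


def test_valid_variant_is_valid_but_different():
    ref = encode("CC(C)c1ccccc1")
    variant = corrupt_to_valid_variant(ref, "fragsmiles", seed=4)
    res = check_validity(variant, "fragsmiles")
    assert res.valid
    assert res.components != check_validity(ref, "fragsmiles").components


def test_fixture_files_round_trip(tmp_path):
    from fragsmiles.fixtures import write_fixture_files

    paths = write_fixture_files(str(tmp_path), n_molecules=5, n_reactions=5, seed=0)
    mols = [l.strip() for l in open(paths["molecules"])]
    assert len(mols) == 5 and all(mol_from_smiles(m) for m in mols)
    rxns = [l.strip() for l in open(paths["reactions"])]
    assert len(rxns) == 5 and all(read_reaction_line(l) for l in rxns)
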