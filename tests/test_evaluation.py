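"""Validity, matching, top-k reports, similarity, overlap, substructures."""

import numpy as np
import pytest

from fragsmiles import (
    ConfigError,
    check_validity,
    corrupt,
    encode,
    is_match,
    overlap_correct,
    similarity_of_errors,
    substructure_report,
    topk_report,
)


def test_encoded_fixture_is_valid(small_corpus):
    for smi in small_corpus[:20]:
        res = check_validity(encode(smi), "fragsmiles")
        assert res.valid and res.error_class == "none"


def test_planted_branch_error_is_classified():
    ref = encode("CC(C)c1ccccc1")
    bad = corrupt(ref, "fragsmiles", "branch_error", seed=1)
    res = check_validity(bad, "fragsmiles")
    assert not res.valid
    assert res.error_class == "branch_error"


def test_smiles_chiral_tag_on_symmetric_carbon_is_chirality_error():
    res = check_validity("C[C@H](C)C", "smiles")
    assert not res.valid
    assert res.error_class == "chirality_error"


def test_unregistered_notation_is_config_error():
    with pytest.raises(ConfigError):
        check_validity("CC", "selfies")


def test_match_semantics():
    ref = "CCO.CC(=O)O"
    assert is_match("CCO.CC(=O)O", ref, "smiles")
    assert is_match("CC(=O)O.CCO", ref, "smiles")  # order-free multiset
    assert not is_match("CCO.CCO", ref, "smiles")
    assert not is_match("not a molecule", ref, "smiles")


def test_match_is_stereo_sensitive():
    ref = "N[C@@H](C)C(=O)O"
    assert is_match("N[C@@H](C)C(=O)O", ref, "smiles")
    assert not is_match("N[C@H](C)C(=O)O", ref, "smiles")  # flipped parity
    assert not is_match("NC(C)C(=O)O", ref, "smiles")  # stereo dropped


def test_topk_perfect_predictor_is_100_at_all_k():
    refs = {f"r{i}": encode(s) for i, s in enumerate(["CCO", "CCN", "CCC"])}
    preds = {rid: [ref] for rid, ref in refs.items()}
    rep = topk_report(preds, refs, "fragsmiles", k_max=5)
    assert rep.accuracy_fractions == [1.0] * 5
    assert rep.validity_fractions == [1.0] * 5


def test_topk_cumulative_semantics_and_dominance():
    refs = {"a": "CCO", "b": "CCN", "c": "CCC"}
    preds = {
        "a": ["CCO", "CCO"],  # match at rank 1
        "b": ["C(((", "CCN"],  # invalid then match at rank 2
        "c": ["C(((", "C((("],  # never valid
    }
    rep = topk_report(preds, refs, "smiles", k_max=2)
    assert rep.validity_counts == [1, 2]
    assert rep.accuracy_counts == [1, 2]
    assert rep.error_histogram["branch_error"] == 2
    for series in (rep.validity_counts, rep.accuracy_counts):
        assert series == sorted(series)  # monotone in k
    assert all(
        a <= v for a, v in zip(rep.accuracy_counts, rep.validity_counts)
    )


def test_topk_skips_records_without_reference():
    refs = {"a": "CCO"}
    preds = {"a": ["CCO"], "b": ["CCN"]}
    rep = topk_report(preds, refs, "smiles", k_max=1)
    assert rep.n_records == 1
    assert rep.skipped == ["b"]


def test_similarity_wrong_parity_scores_one():
    """A candidate equal to the reference except for parity is excluded from
    accuracy but counts 1.0 under stereo-insensitive fingerprints."""
    refs = {"a": "N[C@@H](C)C(=O)O"}
    preds = {"a": ["N[C@H](C)C(=O)O"]}
    out = similarity_of_errors(preds, refs, "smiles")
    assert out["n"] == 1
    assert out["mean"] == pytest.approx(1.0)


def test_similarity_disjoint_molecules_score_zero():
    refs = {"a": "c1ccccc1"}
    preds = {"a": ["C"]}
    out = similarity_of_errors(preds, refs, "smiles")
    assert out["mean"] == pytest.approx(0.0)


def test_similarity_excludes_matches_and_invalid():
    refs = {"a": "CCO", "b": "CCN"}
    preds = {"a": ["CCO"], "b": ["C((("]}
    assert similarity_of_errors(preds, refs, "smiles")["n"] == 0


def test_overlap_matrix_properties():
    mat = overlap_correct(
        {"A": set(range(1, 61)), "B": set(range(41, 101)), "C": set(range(1, 61))}
    )
    assert mat.loc["A", "A"] == 100.0
    assert mat.loc["A", "C"] == 100.0
    assert mat.loc["A", "B"] == pytest.approx(100 * 20 / 60)
    assert mat.loc["B", "A"] == pytest.approx(100 * 20 / 60)


def test_overlap_disjoint_and_empty_sets():
    mat = overlap_correct({"A": {1, 2}, "B": {3, 4}, "C": set()})
    assert mat.loc["A", "B"] == 0.0
    assert np.isnan(mat.loc["C", "A"])  # undefined denominator


def test_substructure_flags():
    # wrong acyclic substituent, same ring system
    rep = substructure_report(
        [("CCc1ccccc1", "CCCc1ccccc1")], "smiles"
    )
    assert rep["ring_systems"] == 1
    assert rep["acyclic"] == 0
    # different ring size: ring systems incorrect
    rep2 = substructure_report([("C1CCCCC1", "C1CCCC1")], "smiles")
    assert rep2["ring_systems"] == 0
    # stereo-only difference: graphs identical at every substructure level
    rep3 = substructure_report(
        [("N[C@H](C)C(=O)O", "N[C@@H](C)C(=O)O")], "smiles"
    )
    assert rep3["ring_systems"] == rep3["scaffold"] == rep3["acyclic"] == 1


def test_report_table_shape():
    refs = {"a": "CCO"}
    preds = {"a": ["CCO"]}
    frame = topk_report(preds, refs, "smiles", k_max=3).to_frame()
    assert list(frame["k"]) == [1, 2, 3]
    assert set(frame.columns) >= {"validity_pct", "accuracy_pct"}
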