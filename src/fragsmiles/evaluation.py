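"""Scoring of ranked candidate lists.

Implements the evaluation protocol for string-based reaction models:
chirality-aware validity, cumulative top-k accuracy over beam candidates,
a syntax-error taxonomy for invalid generations, Tanimoto similarity of
valid-but-wrong products, cross-notation overlap of correct predictions,
and substructure-correctness grouping of wrong predictions.

Validity is deliberately strict: a candidate counts as valid only when it
parses *and* every stereo annotation is chemically legal.  Accuracy uses
stereo-sensitive canonical-form multiset comparison, with the full test set
as denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from . import chem
from .errors import NO_ERROR, NotationError
from .fragmentation import fragment_molecule
from .notation import get_codec

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass
class ValidityResult:
    valid: bool
    error_class: str = NO_ERROR
    components: list[str] | None = None  # canonical SMILES, sorted

    def __post_init__(self) -> None:
        assert self.valid == (self.error_class == NO_ERROR)


def check_validity(candidate: str, notation: str) -> ValidityResult:
    """Parse ``candidate`` with the notation's codec; valid requires both
    syntactic parse success and legal stereo annotation."""
    codec = get_codec(notation)
    try:
        components = codec.canonical_components(candidate)
    except NotationError as exc:
        return ValidityResult(valid=False, error_class=exc.error_class)
    return ValidityResult(valid=True, components=components)


def is_match(candidate: str, reference: str, notation: str) -> bool:
    """Stereo-sensitive, order-free equality of molecule multisets."""
    codec = get_codec(notation)
    ref = Counter(codec.canonical_components(reference))
    res = check_validity(candidate, notation)
    if not res.valid:
        return False
    return Counter(res.components) == ref


@dataclass
class EvalReport:
    n_records: int
    k_max: int
    validity_counts: list[int]
    accuracy_counts: list[int]
    error_histogram: Counter = field(default_factory=Counter)
    skipped: list[str] = field(default_factory=list)

    @property
    def validity_fractions(self) -> list[float]:
        return [c / self.n_records for c in self.validity_counts]

    @property
    def accuracy_fractions(self) -> list[float]:
        return [c / self.n_records for c in self.accuracy_counts]

    def to_frame(self) -> pd.DataFrame:
        """Per-k table mirroring the usual top-k layout."""
        return pd.DataFrame(
            {
                "k": list(range(1, self.k_max + 1)),
                "validity_count": self.validity_counts,
                "validity_pct": [100 * f for f in self.validity_fractions],
                "accuracy_count": self.accuracy_counts,
                "accuracy_pct": [100 * f for f in self.accuracy_fractions],
            }
        )

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "k_max": self.k_max,
            "validity_counts": self.validity_counts,
            "validity_fractions": self.validity_fractions,
            "accuracy_counts": self.accuracy_counts,
            "accuracy_fractions": self.accuracy_fractions,
            "error_histogram_top1": dict(self.error_histogram),
            "n_skipped": len(self.skipped),
        }


def topk_report(
    prediction_sets: dict[str, list[str]],
    references: dict[str, str],
    notation: str,
    k_max: int = 5,
) -> EvalReport:
    """Cumulative top-k validity and accuracy over ranked candidates.

    A record is valid at k when any of its first k candidates is valid, and
    accurate at k when any of them matches the reference; both series are
    therefore non-decreasing in k, and accuracy never exceeds validity.
    The top-1 error histogram collects the taxonomy class of each invalid
    first candidate.
    """
    codec = get_codec(notation)
    validity = np.zeros(k_max, dtype=int)
    accuracy = np.zeros(k_max, dtype=int)
    histogram: Counter = Counter()
    skipped: list[str] = []
    n = 0
    for rid, candidates in prediction_sets.items():
        if rid not in references:
            skipped.append(rid)
            continue
        ref = Counter(codec.canonical_components(references[rid]))
        n += 1
        first_valid = None
        first_match = None
        for rank, cand in enumerate(candidates[:k_max]):
            res = check_validity(cand, notation)
            if rank == 0 and not res.valid:
                histogram[res.error_class] += 1
            if res.valid and first_valid is None:
                first_valid = rank
            if (
                res.valid
                and first_match is None
                and Counter(res.components) == ref
            ):
                first_match = rank
        if first_valid is not None:
            validity[first_valid:] += 1
        if first_match is not None:
            accuracy[first_match:] += 1
    return EvalReport(
        n_records=n,
        k_max=k_max,
        validity_counts=validity.tolist(),
        accuracy_counts=accuracy.tolist(),
        error_histogram=histogram,
        skipped=skipped,
    )


def _combined_mol(components: list[str]) -> Chem.Mol:
    return chem.mol_from_smiles(".".join(components))


def tanimoto(mol_a: Chem.Mol, mol_b: Chem.Mol) -> float:
    """Tanimoto coefficient on 2048-bit radius-2 Morgan (ECFP4-like)
    fingerprints, stereo-insensitive."""
    return DataStructs.TanimotoSimilarity(
        _MORGAN.GetFingerprint(mol_a), _MORGAN.GetFingerprint(mol_b)
    )


def similarity_of_errors(
    prediction_sets: dict[str, list[str]],
    references: dict[str, str],
    notation: str,
) -> dict:
    """Distribution of candidate/reference Tanimoto similarities over top-1
    candidates that are valid but not a match (forward direction)."""
    codec = get_codec(notation)
    values = []
    for rid, candidates in prediction_sets.items():
        if rid not in references or not candidates:
            continue
        ref_components = codec.canonical_components(references[rid])
        res = check_validity(candidates[0], notation)
        if not res.valid:
            continue
        if Counter(res.components) == Counter(ref_components):
            continue
        values.append(
            tanimoto(_combined_mol(res.components), _combined_mol(ref_components))
        )
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return {"n": 0, "mean": None, "median": None, "q25": None, "q75": None}
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "median": float(np.quantile(arr, 0.5)),
        "q25": float(np.quantile(arr, 0.25)),
        "q75": float(np.quantile(arr, 0.75)),
        "values": arr,
    }


def overlap_correct(correct_sets: dict[str, set]) -> pd.DataFrame:
    """Pairwise percentage overlap of correct-prediction id sets.

    Entry (A, B) = |A ∩ B| / |A| × 100 — the share of A's correct records
    also correct under B; not symmetric.  Rows with an empty reference set
    are reported missing (NaN).
    """
    names = list(correct_sets)
    mat = np.full((len(names), len(names)), np.nan)
    for i, a in enumerate(names):
        sa = correct_sets[a]
        if not sa:
            continue
        for j, b in enumerate(names):
            mat[i, j] = 100.0 * len(sa & correct_sets[b]) / len(sa)
    return pd.DataFrame(mat, index=names, columns=names)


def _substructure_profile(components: list[str]) -> dict:
    """Ring-fragment words, acyclic-fragment words and scaffold multisets of
    a molecule set (stereo-free, via the package's own fragmentation)."""
    rings: Counter = Counter()
    acyclic: Counter = Counter()
    scaffolds: Counter = Counter()
    for smi in components:
        mol = chem.mol_from_smiles(smi)
        flat = Chem.Mol(mol)
        Chem.RemoveStereochemistry(flat)
        graph = fragment_molecule(flat)
        for node in graph.nodes:
            word_mol = chem.mol_from_smiles(node.fragment_word)
            if word_mol.GetRingInfo().NumRings() > 0:
                rings[node.fragment_word] += 1
            else:
                acyclic[node.fragment_word] += 1
        scaffold = MurckoScaffold.GetScaffoldForMol(flat)
        scaffolds[Chem.MolToSmiles(scaffold)] += 1
    return {"rings": rings, "acyclic": acyclic, "scaffolds": scaffolds}


def substructure_report(
    wrong_valid_top1: list[tuple[str, str]], notation: str
) -> dict:
    """Group valid-but-wrong top-1 predictions by which substructure level
    they got right: ring systems, scaffold, acyclic substituents.

    ``wrong_valid_top1`` holds (candidate, reference) raw-string pairs.
    Returns per-category counts plus per-pair flags.
    """
    codec = get_codec(notation)
    flags = []
    counts = {"ring_systems": 0, "scaffold": 0, "acyclic": 0, "n": 0}
    for cand, ref in wrong_valid_top1:
        prof_c = _substructure_profile(codec.canonical_components(cand))
        prof_r = _substructure_profile(codec.canonical_components(ref))
        f = {
            "ring_systems": prof_c["rings"] == prof_r["rings"],
            "scaffold": prof_c["scaffolds"] == prof_r["scaffolds"],
            "acyclic": prof_c["acyclic"] == prof_r["acyclic"],
        }
        flags.append(f)
        counts["n"] += 1
        for key in ("ring_systems", "scaffold", "acyclic"):
            counts[key] += int(f[key])
    counts["flags"] = flags
    return counts
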