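"""Reaction-SMILES reading, curation, task-pair construction and stereo
subset tagging.

Reactions arrive as ``reactants>reagents>products`` lines with
dot-separated components.  Records are canonicalized on read (atom maps
stripped), deduplicated by a canonical reaction key, and turned into
forward (reactants+reagents -> products) or retro (products ->
reactants+reagents) source/target pairs in any registered notation.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field

from rdkit import Chem

from . import chem
from .errors import ConfigError
from .notation import get_codec

STEREO_TAGS = ("none", "conserved", "created", "destroyed", "stereoselective")


@dataclass
class ReactionRecord:
    record_id: str
    reactants: list[str]  # canonical SMILES
    reagents: list[str]
    products: list[str]
    has_stereocenter: bool = False
    stereo_tag: str = "none"

    @property
    def key(self) -> str:
        """Canonical dedup key: sorted canonical component strings."""
        return (
            ".".join(sorted(self.reactants))
            + ">"
            + ".".join(sorted(self.reagents))
            + ">"
            + ".".join(sorted(self.products))
        )

    def to_line(self) -> str:
        return (
            ".".join(self.reactants)
            + ">"
            + ".".join(self.reagents)
            + ">"
            + ".".join(self.products)
        )


@dataclass
class TaskPair:
    record_id: str
    direction: str  # forward | retro
    notation: str
    source: str
    target: str


@dataclass
class RejectionLog:
    entries: list[tuple[str, str]] = field(default_factory=list)

    def add(self, record_id: str, reason: str) -> None:
        self.entries.append((record_id, reason))

    def counts(self) -> Counter:
        return Counter(reason for _, reason in self.entries)


def _parse_side(part: str) -> list[str]:
    mols = []
    if not part:
        return mols
    for comp in part.split("."):
        mol = Chem.MolFromSmiles(comp)
        if mol is None:
            raise ValueError(f"unparseable component: {comp!r}")
        mol = chem.strip_atom_maps(mol)
        mols.append(chem.canonical_smiles(chem.canonical_mol(mol)))
    return mols


def read_reaction_line(line: str, record_id: str = "r0") -> ReactionRecord:
    """Parse one ``reactants>reagents>products`` line into a canonicalized
    record; raises ``ValueError`` on format or component errors."""
    parts = line.strip().split(">")
    if len(parts) != 3:
        raise ValueError(
            f"expected 'reactants>reagents>products' (2 '>'), got {line!r}"
        )
    reactants = _parse_side(parts[0])
    reagents = _parse_side(parts[1])
    products = _parse_side(parts[2])
    if not reactants or not products:
        raise ValueError("a reaction needs at least one reactant and product")
    record = ReactionRecord(
        record_id=record_id,
        reactants=reactants,
        reagents=reagents,
        products=products,
    )
    tag_stereo(record)
    return record


def read_reactions(
    lines: "list[str]",
) -> tuple[list[ReactionRecord], RejectionLog]:
    records, log = [], RejectionLog()
    for i, line in enumerate(lines):
        rid = f"r{i}"
        if not line.strip():
            continue
        try:
            records.append(read_reaction_line(line, record_id=rid))
        except ValueError as exc:
            log.add(rid, f"unparseable: {exc}")
    return records, log


def curate(
    records: list[ReactionRecord], log: RejectionLog | None = None
) -> tuple[list[ReactionRecord], RejectionLog]:
    """Drop no-op reactions (identical canonical reactant and product sets)
    and exact duplicates (by canonical reaction key)."""
    log = log if log is not None else RejectionLog()
    seen: set[str] = set()
    kept = []
    for rec in records:
        if sorted(rec.reactants) == sorted(rec.products):
            log.add(rec.record_id, "no_op")
            continue
        if rec.key in seen:
            log.add(rec.record_id, "duplicate")
            continue
        seen.add(rec.key)
        kept.append(rec)
    return kept, log


def make_pair(
    record: ReactionRecord, direction: str, notation: str
) -> TaskPair:
    """Build the seq2seq source/target pair for one curated record.

    Forward: reactants+reagents -> products.  Retro: products ->
    reactants+reagents (reagent identification is part of the retro task).
    Raises a NotationError subclass when the notation cannot encode a
    component.
    """
    if direction not in ("forward", "retro"):
        raise ConfigError(f"unknown direction {direction!r}")
    codec = get_codec(notation)
    inputs = record.reactants + record.reagents
    outputs = record.products
    if direction == "retro":
        inputs, outputs = outputs, inputs
    source = codec.join([codec.encode(s) for s in inputs])
    target = codec.join([codec.encode(s) for s in outputs])
    return TaskPair(
        record_id=record.record_id,
        direction=direction,
        notation=notation,
        source=source,
        target=target,
    )


def make_pairs(
    records: list[ReactionRecord], direction: str, notation: str
) -> tuple[list[TaskPair], RejectionLog]:
    pairs, log = [], RejectionLog()
    for rec in records:
        try:
            pairs.append(make_pair(rec, direction, notation))
        except ConfigError:
            raise
        except Exception as exc:
            log.add(rec.record_id, f"encoding_failed: {exc}")
    return pairs, log


def _stereo_env_multiset(smiles_list: list[str]) -> Counter:
    """Multiset of (environment key, parity) over all assigned stereocenters.

    The environment key is the stereo-free canonical SMILES of the radius-2
    neighborhood with the center atom map-numbered, so equivalent centers
    compare equal across reactant and product sides.
    """
    out: Counter = Counter()
    for smi in smiles_list:
        mol = chem.mol_from_smiles(smi)
        for idx, parity in chem.assigned_stereocenters(mol):
            flat = Chem.Mol(mol)
            Chem.RemoveStereochemistry(flat)
            flat.GetAtomWithIdx(idx).SetAtomMapNum(1)
            bonds = Chem.FindAtomEnvironmentOfRadiusN(flat, 2, idx)
            if bonds:
                atoms = set()
                for b in bonds:
                    bd = flat.GetBondWithIdx(b)
                    atoms.add(bd.GetBeginAtomIdx())
                    atoms.add(bd.GetEndAtomIdx())
                env = Chem.MolFragmentToSmiles(
                    flat, atomsToUse=sorted(atoms), bondsToUse=list(bonds)
                )
            else:
                env = Chem.MolToSmiles(flat)
            out[(env, parity)] += 1
    return out


def tag_stereo(record: ReactionRecord) -> tuple[bool, str]:
    """Set and return (has_stereocenter, subset tag) for a record.

    conserved: identical (environment, parity) multisets on both sides;
    created: the reactant multiset is a strict subset of the product's;
    destroyed: the converse; stereoselective: any other difference (parity
    flips, substitutions at a center, simultaneous creation/destruction).
    """
    r_env = _stereo_env_multiset(record.reactants)
    p_env = _stereo_env_multiset(record.products)
    has = bool(r_env) or bool(p_env)
    if not has:
        tag = "none"
    elif r_env == p_env:
        tag = "conserved"
    elif not (r_env - p_env):  # r strictly contained in p
        tag = "created"
    elif not (p_env - r_env):
        tag = "destroyed"
    else:
        tag = "stereoselective"
    record.has_stereocenter = has
    record.stereo_tag = tag
    return has, tag


def split(
    records: list[ReactionRecord],
    fractions: tuple[float, float, float],
    seed: int,
) -> dict[str, list[ReactionRecord]]:
    """Reproducible train/valid/test partition; records sharing a reaction
    key always land in the same split."""
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) < 0:
        raise ConfigError(f"fractions must be >=0 and sum to 1: {fractions}")
    groups: dict[str, list[ReactionRecord]] = {}
    for rec in records:
        groups.setdefault(rec.key, []).append(rec)
    keys = sorted(groups)
    random.Random(seed).shuffle(keys)
    n = len(records)
    n_train = round(fractions[0] * n)
    n_valid = round(fractions[1] * n)
    out = {"train": [], "valid": [], "test": []}
    count = 0
    for key in keys:
        if count < n_train:
            bucket = "train"
        elif count < n_train + n_valid:
            bucket = "valid"
        else:
            bucket = "test"
        out[bucket].extend(groups[key])
        count += len(groups[key])
    return out
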