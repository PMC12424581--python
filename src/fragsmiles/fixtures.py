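"""Synthetic molecules, reactions and controlled string corruptions.

Everything in the package is testable offline: molecules are assembled from
a curated building-block set by random single-bond joining (which
guarantees chemical validity and controllable ring/stereo content),
reactions come from templates with known stereochemical outcomes, and the
corruptor plants taxonomy-classified syntax errors that are verified by
re-parsing before they are emitted.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from rdkit import Chem

from . import chem
from .errors import UnreachableClassError
from .evaluation import check_validity
from .notation import get_codec
from .reactions import ReactionRecord, read_reaction_line

RING_BLOCKS = [
    "c1ccccc1",
    "C1CCCCC1",
    "c1ccncc1",
    "c1ccoc1",
    "C1CCNCC1",
    "C1CCOC1",
    "c1ccc2ccccc2c1",
    "c1cc[nH]c1",
    "C1CCCC1",
    "c1ccsc1",
]
CHAIN_BLOCKS = ["C", "N", "O", "C=O", "C=C", "CC", "C#N", "S", "C(=O)O"]
TERMINAL_BLOCKS = ["F", "Cl", "Br"]  # monovalent: attach once, never extended


@dataclass
class GeneratorConfig:
    n: int = 100
    seed: int = 0
    ring_probability: float = 0.7
    stereo_probability: float = 0.5
    max_heavy_atoms: int = 30
    min_blocks: int = 2
    max_blocks: int = 5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for p in (self.ring_probability, self.stereo_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _free_valence_atoms(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetTotalNumHs() > 0 and a.GetAtomicNum() > 1
    ]


def _join(mol: Chem.Mol, block: Chem.Mol, rng: random.Random) -> Chem.Mol | None:
    """Bond a random free-valence atom of ``mol`` to one of ``block``."""
    a_sites = _free_valence_atoms(mol)
    b_sites = _free_valence_atoms(block)
    if not a_sites or not b_sites:
        return None
    em = Chem.RWMol(Chem.CombineMols(mol, block))
    ia = rng.choice(a_sites)
    ib = mol.GetNumAtoms() + rng.choice(b_sites)
    em.AddBond(ia, ib, Chem.BondType.SINGLE)
    out = em.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _add_stereocenters(mol: Chem.Mol, rng: random.Random) -> Chem.Mol | None:
    """Set random tetrahedral tags on potential stereocenters; if none
    exist, graft a C(F)Cl unit (its carbon is then stereogenic)."""
    centers = sorted(chem.potential_stereocenters(mol))
    if not centers:
        graft = chem.mol_from_smiles("C(F)Cl")
        mol = _join(mol, graft, rng)
        if mol is None:
            return None
        centers = sorted(chem.potential_stereocenters(mol))
        if not centers:
            return None
    n_pick = rng.randint(1, min(2, len(centers)))
    picked = rng.sample(centers, n_pick)
    out = Chem.RWMol(mol)
    for idx in picked:
        tag = rng.choice(
            [
                Chem.ChiralType.CHI_TETRAHEDRAL_CW,
                Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
            ]
        )
        out.GetAtomWithIdx(idx).SetChiralTag(tag)
    final = chem.canonical_mol(out.GetMol())
    if not chem.assigned_stereocenters(final):
        return None
    return final


def gen_molecules(config: GeneratorConfig) -> list[str]:
    """Generate ``config.n`` canonical SMILES strings.

    Each molecule contains at least one ring with probability
    ``ring_probability`` (and none otherwise) and carries at least one
    assigned stereocenter with probability ``stereo_probability`` (and none
    otherwise) — both guaranteed per molecule, not just in expectation.
    """
    rng = random.Random(config.seed)
    out: list[str] = []
    while len(out) < config.n:
        want_ring = rng.random() < config.ring_probability
        want_stereo = rng.random() < config.stereo_probability
        mol = _assemble(config, rng, want_ring)
        if mol is None:
            continue
        if want_stereo:
            mol = _add_stereocenters(mol, rng)
            if mol is None:
                continue
        else:
            if chem.assigned_stereocenters(mol):
                continue
        if mol.GetNumAtoms() > config.max_heavy_atoms:
            continue
        smi = chem.canonical_smiles(mol)
        has_ring = mol.GetRingInfo().NumRings() > 0
        if has_ring != want_ring:
            continue
        out.append(smi)
    return out


def _assemble(
    config: GeneratorConfig, rng: random.Random, want_ring: bool
) -> Chem.Mol | None:
    n_blocks = rng.randint(config.min_blocks, config.max_blocks)
    pool = CHAIN_BLOCKS + TERMINAL_BLOCKS
    blocks = []
    if want_ring:
        blocks.append(rng.choice(RING_BLOCKS))
        pool = pool + RING_BLOCKS
    while len(blocks) < n_blocks:
        blocks.append(rng.choice(pool))
    rng.shuffle(blocks)
    mol = chem.mol_from_smiles(blocks[0])
    for b in blocks[1:]:
        nxt = _join(mol, chem.mol_from_smiles(b), rng)
        if nxt is None:
            break
        mol = nxt
    return chem.canonical_mol(mol)


# --- reaction templates -----------------------------------------------------

_ACIDS = ["CC(=O)O", "CCC(=O)O", "O=C(O)c1ccccc1", "CC(C)C(=O)O"]
_ALCOHOLS = ["CO", "CCO", "OCC(C)C", "OCc1ccccc1"]
_SN2_SUBSTRATES = [
    # (substrate with R center, nucleophile, product with S center): a
    # backside attack swaps the leaving group and inverts the parity.
    ("C[C@@H](Br)CC", "[N-]=[N+]=[N-]", "C[C@H](N=[N+]=[N-])CC"),
    ("CC[C@@H](Cl)c1ccccc1", "[C-]#N", "CC[C@H](C#N)c1ccccc1"),
]
_KETONES = [
    # reduction creates a stereocenter in the product
    ("CC(=O)CC", "C[C@H](O)CC"),
    ("CC(=O)c1ccccc1", "C[C@H](O)c1ccccc1"),
]
_CHIRAL_SPECTATORS = [
    # stereocenter untouched on both sides -> conserved
    ("C[C@H](N)C(=O)O.CO", "C[C@H](N)C(=O)OC.O"),
]


def gen_reactions(
    config: GeneratorConfig,
) -> tuple[list[ReactionRecord], list[str]]:
    """Template reactions with known ground-truth stereo subset tags.

    Returns (records, truth_tags); truths ride alongside so the tagger can
    be tested blind.
    """
    rng = random.Random(config.seed)
    records: list[ReactionRecord] = []
    truths: list[str] = []
    for i in range(config.n):
        kind = rng.choice(["ester", "sn2", "reduction", "conserved"])
        if kind == "ester":
            acid = rng.choice(_ACIDS)
            alcohol = rng.choice(_ALCOHOLS)
            ester = _esterify(acid, alcohol)
            line = f"{acid}.{alcohol}>OS(=O)(=O)O>{ester}.O"
            truth = "none"
        elif kind == "sn2":
            sub, nuc, prod = rng.choice(_SN2_SUBSTRATES)
            line = f"{sub}.{nuc}>>{prod}"
            truth = "stereoselective"
        elif kind == "reduction":
            ketone, alcohol = rng.choice(_KETONES)
            line = f"{ketone}>[H][H]>{alcohol}"
            truth = "created"
        else:
            src, dst = rng.choice(_CHIRAL_SPECTATORS)
            line = f"{src}>>{dst}"
            truth = "conserved"
        rec = read_reaction_line(line, record_id=f"fx{i}")
        records.append(rec)
        truths.append(truth)
    return records, truths


def _esterify(acid: str, alcohol: str) -> str:
    """Condense a carboxylic acid and an alcohol (string-level template)."""
    from rdkit.Chem import AllChem

    rxn = AllChem.ReactionFromSmarts(
        "[C:1](=[O:2])[OH].[OX2H:3][#6:4]>>[C:1](=[O:2])[O:3][#6:4]"
    )
    prods = rxn.RunReactants(
        (chem.mol_from_smiles(acid), chem.mol_from_smiles(alcohol))
    )
    mol = prods[0][0]
    Chem.SanitizeMol(mol)
    return chem.canonical_smiles(mol)


# --- corruptor --------------------------------------------------------------

_MAX_TRIES = 60


def corrupt(
    string: str, notation: str, error_class: str, seed: int = 0
) -> str:
    """Minimally mutate a valid string so it fails with ``error_class``.

    Every emission is verified by re-classification through
    :func:`check_validity` before being returned; when no mutation of this
    string can produce the class (e.g. ring-closure errors in a notation
    without ring-closure syntax, or connector errors in a connector-free
    string), :class:`UnreachableClassError` is raised.
    """
    rng = random.Random(seed)
    mutators = _MUTATORS.get((notation, error_class))
    if mutators is None:
        raise UnreachableClassError(
            f"class {error_class!r} is not reachable in notation {notation!r}"
        )
    for _ in range(_MAX_TRIES):
        mutated = mutators(string, rng)
        if mutated is None:
            break
        if mutated == string:
            continue
        res = check_validity(mutated, notation)
        if not res.valid and res.error_class == error_class:
            return mutated
    raise UnreachableClassError(
        f"could not plant {error_class!r} in {string!r} ({notation})"
    )


def corrupt_to_valid_variant(string: str, notation: str, seed: int = 0) -> str:
    """Produce a *valid* string for a different molecule (wrong-but-valid
    candidates for the mock predictor): decode, graft a methyl at a random
    free-valence atom, re-encode."""
    rng = random.Random(seed)
    codec = get_codec(notation)
    components = codec.canonical_components(string)
    for _ in range(_MAX_TRIES):
        idx = rng.randrange(len(components))
        mol = chem.mol_from_smiles(components[idx])
        grown = _join(mol, chem.mol_from_smiles("C"), rng)
        if grown is None:
            continue
        new_components = list(components)
        new_components[idx] = chem.canonical_smiles(grown)
        out = codec.join([codec.encode(s) for s in new_components])
        res = check_validity(out, notation)
        if res.valid and sorted(res.components) != sorted(components):
            return out
    raise UnreachableClassError(f"could not grow a valid variant of {string!r}")


# fragSMILES mutations (word level) ------------------------------------------


def _frag_words(string: str) -> list[str]:
    return string.split()


def _frag_token_error(string: str, rng: random.Random) -> str:
    words = _frag_words(string)
    words.insert(rng.randrange(len(words) + 1), "?!?")
    return " ".join(words)


def _frag_branch_error(string: str, rng: random.Random) -> str:
    words = _frag_words(string)
    closes = [i for i, w in enumerate(words) if w == ")"]
    if closes and rng.random() < 0.5:
        words.pop(rng.choice(closes))
    else:
        words.append(")")
    return " ".join(words)


def _frag_connector_error(string: str, rng: random.Random) -> str | None:
    words = _frag_words(string)
    conns = [i for i, w in enumerate(words) if w.startswith("-")]
    if not conns:
        return None  # connector-free string: class unreachable
    i = rng.choice(conns)
    pi, ci = words[i][1:].split(".")
    if rng.random() < 0.5:
        words[i] = f"-{int(pi) + 99}.{ci}"
    else:
        # drop the fragment that follows the connector
        del words[i + 1 :]
    return " ".join(words)


def _frag_chirality_error(string: str, rng: random.Random) -> str:
    words = _frag_words(string)
    frag_positions = [
        i
        for i, w in enumerate(words)
        if w not in ("(", ")", ".") and not w.startswith("-")
    ]
    i = rng.choice(frag_positions)
    base = words[i].split("|")[0]
    # conflicting parities on one atom are never legal
    words[i] = f"{base}|0R|0S"
    return " ".join(words)


def _frag_valence_error(string: str, rng: random.Random) -> str:
    # overload local atom 0 of the last fragment with extra children
    extra = rng.randint(4, 6)
    suffix = " ".join(
        f"( -0.0 C )" if k < extra - 1 else "-0.0 C" for k in range(extra)
    )
    return f"{string} {suffix}"


# SMILES mutations (character level) -----------------------------------------


def _smi_ring_closure_error(string: str, rng: random.Random) -> str:
    digit = rng.choice("89")
    tokens = chem.atom_level_tokens(string)
    # append the unmatched digit after a random atom token
    atom_positions = [
        i
        for i, t in enumerate(tokens)
        if t[0].isalpha() or t.startswith("[")
    ]
    if not atom_positions:
        return string + digit
    i = rng.choice(atom_positions)
    tokens.insert(i + 1, digit)
    return "".join(tokens)


def _smi_branch_error(string: str, rng: random.Random) -> str:
    if ")" in string and rng.random() < 0.5:
        i = string.rindex(")")
        return string[:i] + string[i + 1 :]
    return string + ")"


def _smi_token_error(string: str, rng: random.Random) -> str:
    i = rng.randrange(len(string) + 1)
    return string[:i] + "~" + string[i:]


def _smi_chirality_error(string: str, rng: random.Random) -> str | None:
    tokens = chem.atom_level_tokens(string)
    positions = [i for i, t in enumerate(tokens) if t == "C"]
    if not positions:
        return None
    i = rng.choice(positions)
    tokens[i] = "[C@H]"
    return "".join(tokens)


def _smi_valence_error(string: str, rng: random.Random) -> str | None:
    tokens = chem.atom_level_tokens(string)
    positions = [i for i, t in enumerate(tokens) if t in ("C", "c")]
    if not positions:
        return None
    i = rng.choice(positions)
    tokens[i] = tokens[i] + "(F)(F)(F)(F)"
    return "".join(tokens)


_MUTATORS = {
    ("fragsmiles", "token_error"): _frag_token_error,
    ("fragsmiles", "branch_error"): _frag_branch_error,
    ("fragsmiles", "connector_bond_error"): _frag_connector_error,
    ("fragsmiles", "chirality_error"): _frag_chirality_error,
    ("fragsmiles", "valence_error"): _frag_valence_error,
    ("smiles", "ring_closure_error"): _smi_ring_closure_error,
    ("smiles", "branch_error"): _smi_branch_error,
    ("smiles", "token_error"): _smi_token_error,
    ("smiles", "chirality_error"): _smi_chirality_error,
    ("smiles", "valence_error"): _smi_valence_error,
}


def reachable_classes(notation: str) -> list[str]:
    """Error classes the corruptor can plant for a notation."""
    return sorted(cls for (nt, cls) in _MUTATORS if nt == notation)


def write_fixture_files(
    out_dir: str, n_molecules: int, n_reactions: int, seed: int
) -> dict[str, str]:
    """Write .smi and reaction-SMILES fixture files; returns path map."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    cfg_m = GeneratorConfig(n=n_molecules, seed=seed)
    cfg_r = GeneratorConfig(n=n_reactions, seed=seed + 1)
    mol_path = os.path.join(out_dir, "molecules.smi")
    rxn_path = os.path.join(out_dir, "reactions.txt")
    with open(mol_path, "w") as fh:
        for smi in gen_molecules(cfg_m):
            fh.write(smi + "\n")
    records, _ = gen_reactions(cfg_r)
    with open(rxn_path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")
    return {"molecules": mol_path, "reactions": rxn_path}
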