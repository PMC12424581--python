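"""RDKit-backed molecule helpers.

Molecules are handled as :class:`rdkit.Chem.Mol` objects throughout the
package; the canonical isomeric SMILES string is the canonical form.  The
helpers here centralize parsing, canonicalization, stereocenter perception
and the CIP-label imposition used when decoding reduced graphs.
"""

from __future__ import annotations

import itertools
import re

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem  # noqa: F401  (registers descriptors)

from .errors import ChiralityError, TokenError

RDLogger.DisableLog("rdApp.*")

_CW = Chem.ChiralType.CHI_TETRAHEDRAL_CW
_CCW = Chem.ChiralType.CHI_TETRAHEDRAL_CCW


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES, raising :class:`TokenError` on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise TokenError(f"empty or non-string SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise TokenError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonical_smiles(mol_or_smiles: "Chem.Mol | str") -> str:
    """Canonical isomeric SMILES (the canonical form of a molecule)."""
    mol = (
        mol_from_smiles(mol_or_smiles)
        if isinstance(mol_or_smiles, str)
        else mol_or_smiles
    )
    return Chem.MolToSmiles(mol)


def canonical_mol(mol_or_smiles: "Chem.Mol | str") -> Chem.Mol:
    """Return the molecule re-parsed from its canonical SMILES.

    The resulting atom order is a pure function of the molecular graph,
    which makes every downstream atom-index decision independent of the
    caller's input atom order.
    """
    return mol_from_smiles(canonical_smiles(mol_or_smiles))


def strip_atom_maps(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.Mol(mol)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return mol


def _cip_labels(mol: Chem.Mol) -> dict[int, str]:
    """R/S labels of assigned tetrahedral centers via the modern CIP
    labeller (the single labelling authority for encode AND decode, so
    stored parities always re-impose consistently)."""
    work = Chem.Mol(mol)
    Chem.AssignStereochemistry(work, cleanIt=True, force=True)
    Chem.rdCIPLabeler.AssignCIPLabels(work)
    out: dict[int, str] = {}
    for atom in work.GetAtoms():
        if atom.HasProp("_CIPCode"):
            label = atom.GetProp("_CIPCode")
            if label in ("R", "S"):
                out[atom.GetIdx()] = label
    return out


def assigned_stereocenters(mol: Chem.Mol) -> list[tuple[int, str]]:
    """(atom index, 'R'|'S') for every assigned tetrahedral stereocenter."""
    return sorted(_cip_labels(mol).items())


def potential_stereocenters(mol: Chem.Mol) -> set[int]:
    """Atom indices that could carry tetrahedral stereo annotation."""
    out = set()
    for element in Chem.FindPotentialStereo(mol):
        if element.type == Chem.StereoType.Atom_Tetrahedral:
            out.add(int(element.centeredOn))
    return out


def smiles_output_order(mol: Chem.Mol) -> list[int]:
    """Atom indices in the order they appear in ``MolToSmiles(mol)``.

    Position in this list is the canonical, context-free local numbering
    used for fragment attachment points.
    """
    Chem.MolToSmiles(mol)
    order = mol.GetPropsAsDict(True, True)["_smilesAtomOutputOrder"]
    return list(order)


_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|@@|[BCNOSPFIbcnosp]|[0-9]|%[0-9]{2}|[-=#$:/\\.()@+~*])"
)


def atom_level_tokens(smiles: str) -> list[str]:
    """Tokenize a SMILES string at the atom level (standard regex scheme
    used for seq2seq reaction models)."""
    return _SMILES_TOKEN_RE.findall(smiles)


def impose_cip_labels(rwmol: Chem.RWMol, targets: dict[int, str]) -> Chem.Mol:
    """Set tetrahedral tags on ``rwmol`` so each atom in ``targets`` gets the
    requested CIP label, and return the sanitized molecule.

    Tags are seeded clockwise and mismatching centers flipped until the CIP
    perception agrees; interdependent centers that fail to converge fall
    back to exhaustive enumeration.  Raises :class:`ChiralityError` when a
    requested parity is unrealizable.
    """
    if not targets:
        Chem.SanitizeMol(rwmol)
        return rwmol.GetMol()
    for idx in targets:
        if idx >= rwmol.GetNumAtoms():
            raise ChiralityError(f"stereo label on missing atom {idx}")
        rwmol.GetAtomWithIdx(idx).SetChiralTag(_CW)
    Chem.SanitizeMol(rwmol)

    def _labels() -> dict[int, str | None]:
        got = _cip_labels(rwmol)
        return {idx: got.get(idx) for idx in targets}

    for _ in range(len(targets) + 2):
        got = _labels()
        if any(v is None for v in got.values()):
            bad = [i for i, v in got.items() if v is None]
            raise ChiralityError(
                f"atoms {bad} are not perceivable stereocenters in the "
                "decoded molecule"
            )
        wrong = [i for i in targets if got[i] != targets[i]]
        if not wrong:
            return rwmol.GetMol()
        for idx in wrong:
            atom = rwmol.GetAtomWithIdx(idx)
            atom.SetChiralTag(_CCW if atom.GetChiralTag() == _CW else _CW)

    # interdependent centers: exhaustive search over tag assignments
    idxs = sorted(targets)
    if len(idxs) <= 12:
        for combo in itertools.product((_CW, _CCW), repeat=len(idxs)):
            for idx, tag in zip(idxs, combo):
                rwmol.GetAtomWithIdx(idx).SetChiralTag(tag)
            got = _labels()
            if all(got[i] == targets[i] for i in idxs):
                return rwmol.GetMol()
    raise ChiralityError(f"no tetrahedral tag assignment realizes {targets}")
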