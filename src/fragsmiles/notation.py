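"""Pluggable notation codecs.

A codec turns molecules into raw strings of one notation and back, and maps
its parser's failures onto the shared error taxonomy.  Two codecs ship with
the package — ``fragsmiles`` (chemical-word level) and ``smiles``
(atom-level) — and external notations (SELFIES, SAFE, t-SMILES, ...) can be
attached through :func:`register_codec` with the same surface.
"""

from __future__ import annotations

import re
from abc import ABC, abstractmethod

from rdkit import Chem

from . import chem, serialization
from .errors import (
    BranchError,
    ChiralityError,
    ConfigError,
    NotationError,
    RingClosureError,
    TokenError,
    ValenceError,
)


class Codec(ABC):
    """Encode/decode one string notation, with taxonomy-mapped errors."""

    name: str

    @abstractmethod
    def encode(self, smiles: str) -> str:
        """Canonical raw string for one (possibly multi-component) SMILES."""

    @abstractmethod
    def canonical_components(self, raw: str) -> list[str]:
        """Canonical SMILES of each molecule in ``raw``.

        Raises a :class:`NotationError` subclass when ``raw`` is invalid,
        including illegal stereo annotation.
        """

    @abstractmethod
    def tokenize(self, raw: str) -> list[str]:
        """Model-level tokens of ``raw``."""

    def join(self, encoded: list[str]) -> str:
        """Join per-molecule encodings into one source/target string."""
        return self.separator.join(encoded)

    separator = "."


class FragSmilesCodec(Codec):
    """Chemical-word notation over reduced graphs (space-separated words)."""

    name = "fragsmiles"
    separator = " . "

    def encode(self, smiles: str) -> str:
        return serialization.encode(smiles)

    def canonical_components(self, raw: str) -> list[str]:
        mol = serialization.decode_string(raw)
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        return sorted(Chem.MolToSmiles(f) for f in frags)

    def tokenize(self, raw: str) -> list[str]:
        return raw.split()


_BRACKET_RE = re.compile(r"\[[^\]]*\]")


def _scan_smiles_syntax(raw: str) -> None:
    """Pre-classify branch and ring-closure defects in an atom-level string.

    RDKit reports parse failures without a category, so unbalanced
    parentheses and unpaired ring-closure digits are detected up front;
    digits inside brackets (isotopes, charges, H counts) are not ring bonds
    and are masked before scanning.
    """
    depth = 0
    for ch in raw:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise BranchError("unbalanced ')'")
    if depth != 0:
        raise BranchError("unclosed '('")
    masked = _BRACKET_RE.sub(lambda m: "A" * len(m.group()), raw)
    if "[" in masked or "]" in masked:
        raise TokenError("unbalanced brackets")
    open_rings: set[str] = set()
    i = 0
    while i < len(masked):
        ch = masked[i]
        if ch == "%" and i + 2 < len(masked) + 1:
            label = masked[i : i + 3]
            i += 3
        elif ch.isdigit():
            label = ch
            i += 1
        else:
            i += 1
            continue
        if label in open_rings:
            open_rings.discard(label)
        else:
            open_rings.add(label)
    if open_rings:
        raise RingClosureError(
            f"unmatched ring-closure digits: {sorted(open_rings)}"
        )


class SmilesCodec(Codec):
    """Atom-level SMILES with taxonomy-mapped validity checking."""

    name = "smiles"
    separator = "."

    def encode(self, smiles: str) -> str:
        return chem.canonical_smiles(smiles)

    def _parse_checked(self, raw: str) -> Chem.Mol:
        if not raw or raw != raw.strip() or " " in raw:
            raise TokenError(f"malformed SMILES string: {raw!r}")
        _scan_smiles_syntax(raw)
        mol = Chem.MolFromSmiles(raw, sanitize=False)
        if mol is None:
            raise TokenError(f"unparseable SMILES: {raw!r}")
        tagged = {
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetChiralTag()
            in (
                Chem.ChiralType.CHI_TETRAHEDRAL_CW,
                Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
            )
        }
        try:
            Chem.SanitizeMol(mol)
        except (
            Chem.AtomValenceException,
            Chem.KekulizeException,
        ) as exc:
            raise ValenceError(str(exc)) from exc
        except Exception as exc:
            raise TokenError(str(exc)) from exc
        if tagged:
            legal = chem.potential_stereocenters(mol)
            bogus = tagged - legal
            if bogus:
                raise ChiralityError(
                    f"chiral tags on non-stereocenters: {sorted(bogus)}"
                )
        return mol

    def canonical_components(self, raw: str) -> list[str]:
        mol = self._parse_checked(raw)
        mol = chem.canonical_mol(mol)
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        return sorted(Chem.MolToSmiles(f) for f in frags)

    def tokenize(self, raw: str) -> list[str]:
        return chem.atom_level_tokens(raw)


_REGISTRY: dict[str, Codec] = {}


def register_codec(codec: Codec) -> None:
    _REGISTRY[codec.name] = codec


def get_codec(name: str) -> Codec:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ConfigError(
            f"no codec registered for notation {name!r}; "
            f"available: {sorted(_REGISTRY)}"
        ) from None


def available_notations() -> list[str]:
    return sorted(_REGISTRY)


register_codec(FragSmilesCodec())
register_codec(SmilesCodec())
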