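"""Serialization of reduced graphs to fragSMILES token strings and back.

Grammar (chemical-word level; one word per token, words space-separated):

* fragment token  — canonical fragment word, optionally suffixed with one
  ``|<local index><R|S>`` block per stereocenter, e.g. ``C|0S`` or
  ``C1CCNCC1|2R|4S``;
* connector token — ``-<i>.<j>``: local atom ``i`` of the already-emitted
  (parent) fragment bonds to local atom ``j`` of the child fragment that
  follows;
* branch tokens   — the words ``(`` and ``)`` wrap every child subtree of a
  node except the last;
* separator token — the word ``.`` joins disconnected components.

Serialization is a deterministic depth-first preorder walk: the root of
each component is the node with the lexicographically smallest
``(fragment_word, degree)`` pair (ties broken by the smallest parent atom
rank, falling back to node id for hand-built graphs), and children are
visited in ascending ``(parent local index, child fragment_word)`` order.
Ring-closure digits never appear outside a fragment word, so the notation
has no ring-closure syntax of its own.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from . import chem
from .errors import (
    BranchError,
    ChiralityError,
    ConnectorBondError,
    TokenError,
    ValenceError,
)
from .fragmentation import (
    FragmentNode,
    ReducedGraph,
    ReducedGraphEdge,
    assign_fragment_chirality,
    fragment_molecule,
)

BRANCH_OPEN = "("
BRANCH_CLOSE = ")"
SEPARATOR = "."

_CONNECTOR_RE = re.compile(r"^-(\d+)\.(\d+)$")
_CHIRALITY_SUFFIX_RE = re.compile(r"^(\d+)(R|S)$")


@dataclass(frozen=True)
class Token:
    kind: str  # fragment | connector | branch_open | branch_close | molecule_separator
    word: str

    def __str__(self) -> str:
        return self.word


@dataclass
class TokenSequence:
    tokens: list[Token]
    source_id: str | None = None

    def __str__(self) -> str:
        return " ".join(t.word for t in self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def kinds(self) -> list[str]:
        return [t.kind for t in self.tokens]


def _fragment_token_word(node: FragmentNode) -> str:
    word = node.fragment_word
    for local, parity in sorted(node.chirality_labels):
        word += f"|{local}{parity}"
    return word


def _node_anchor(node: FragmentNode) -> int:
    if node.local_atoms:
        return min(node.local_atoms)
    return node.node_id


def serialize(graph: ReducedGraph) -> TokenSequence:
    """Emit the canonical token sequence of a reduced graph."""
    if not graph.is_forest():
        raise ValueError("reduced graph contains a cycle; cannot serialize")
    degree = Counter()
    for e in graph.edges:
        degree[e.node_a] += 1
        degree[e.node_b] += 1

    tokens: list[Token] = []

    def emit_fragment(node: FragmentNode) -> None:
        tokens.append(Token("fragment", _fragment_token_word(node)))

    def visit(node_id: int, came_from: int | None) -> None:
        node = graph.nodes[node_id]
        emit_fragment(node)
        children = []
        for edge, other in graph.neighbors(node_id):
            if other == came_from:
                continue
            if edge.node_a == node_id:
                pi, ci = edge.local_index_a, edge.local_index_b
            else:
                pi, ci = edge.local_index_b, edge.local_index_a
            child = graph.nodes[other]
            children.append(
                (pi, child.fragment_word, _node_anchor(child), ci, other)
            )
        children.sort()
        for pos, (pi, _, _, ci, other) in enumerate(children):
            last = pos == len(children) - 1
            if not last:
                tokens.append(Token("branch_open", BRANCH_OPEN))
            tokens.append(Token("connector", f"-{pi}.{ci}"))
            visit(other, node_id)
            if not last:
                tokens.append(Token("branch_close", BRANCH_CLOSE))

    comps = graph.components()
    rooted = []
    for comp in comps:
        root = min(
            comp,
            key=lambda nid: (
                graph.nodes[nid].fragment_word,
                degree[nid],
                _node_anchor(graph.nodes[nid]),
            ),
        )
        rooted.append((graph.nodes[root].fragment_word, _node_anchor(graph.nodes[root]), root))
    rooted.sort()
    for pos, (_, _, root) in enumerate(rooted):
        if pos:
            tokens.append(Token("molecule_separator", SEPARATOR))
        visit(root, None)
    return TokenSequence(tokens)


_WORD_CACHE: dict[str, int] = {}


def _fragment_word_atom_count(word: str) -> int:
    """Heavy-atom count of a fragment word (validates the word)."""
    if word not in _WORD_CACHE:
        mol = Chem.MolFromSmiles(word)
        if mol is None:
            raise TokenError(f"unknown fragment word: {word!r}")
        _WORD_CACHE[word] = mol.GetNumAtoms()
    return _WORD_CACHE[word]


def _classify_word(word: str) -> Token:
    if word == BRANCH_OPEN:
        return Token("branch_open", word)
    if word == BRANCH_CLOSE:
        return Token("branch_close", word)
    if word == SEPARATOR:
        return Token("molecule_separator", word)
    if word.startswith("-"):
        if not _CONNECTOR_RE.match(word):
            raise TokenError(f"malformed connector token: {word!r}")
        return Token("connector", word)
    return Token("fragment", word)


def tokenize(raw: str) -> TokenSequence:
    """Split a raw fragSMILES string into classified tokens."""
    words = raw.split()
    if not words:
        raise TokenError("empty token sequence")
    return TokenSequence([_classify_word(w) for w in words])


def _parse_fragment_word(word: str) -> tuple[str, int, list[tuple[int, str]]]:
    parts = word.split("|")
    frag = parts[0]
    if not frag:
        raise TokenError(f"empty fragment word in token {word!r}")
    n_atoms = _fragment_word_atom_count(frag)
    labels: list[tuple[int, str]] = []
    seen: set[int] = set()
    for suffix in parts[1:]:
        m = _CHIRALITY_SUFFIX_RE.match(suffix)
        if not m:
            raise TokenError(f"malformed chirality suffix in token {word!r}")
        local, parity = int(m.group(1)), m.group(2)
        if local >= n_atoms:
            raise ChiralityError(
                f"chirality label on atom {local} of {frag!r} "
                f"({n_atoms} atoms)"
            )
        if local in seen:
            raise ChiralityError(
                f"duplicate chirality label on atom {local} of {frag!r}"
            )
        seen.add(local)
        labels.append((local, parity))
    return frag, n_atoms, sorted(labels)


def parse(sequence: "TokenSequence | str") -> ReducedGraph:
    """Parse a token sequence (or raw whitespace-separated string) back to a
    reduced graph, with taxonomy-classified failures."""
    seq = tokenize(sequence) if isinstance(sequence, str) else sequence
    nodes: list[FragmentNode] = []
    edges: list[ReducedGraphEdge] = []
    roots: list[int] = []

    current: int | None = None
    pending: tuple[int, int] | None = None
    stack: list[int | None] = []

    for token in seq.tokens:
        if token.kind == "branch_open":
            if current is None:
                raise BranchError("branch opened before any fragment")
            stack.append(current)
        elif token.kind == "branch_close":
            if pending is not None:
                raise ConnectorBondError(
                    "connector token with no following fragment"
                )
            if not stack:
                raise BranchError("unbalanced branch close")
            current = stack.pop()
        elif token.kind == "molecule_separator":
            if current is None:
                raise TokenError("separator cannot open a sequence")
            if pending is not None:
                raise ConnectorBondError(
                    "connector token with no following fragment"
                )
            if stack:
                raise BranchError("separator inside an open branch")
            current = None
        elif token.kind == "connector":
            if current is None:
                raise ConnectorBondError(
                    "connector token with no preceding fragment"
                )
            if pending is not None:
                raise ConnectorBondError("two consecutive connector tokens")
            m = _CONNECTOR_RE.match(token.word)
            pending = (int(m.group(1)), int(m.group(2)))
        else:  # fragment
            frag, n_atoms, labels = _parse_fragment_word(token.word)
            node = FragmentNode(
                node_id=len(nodes),
                fragment_word=frag,
                n_atoms=n_atoms,
                chirality_labels=labels,
            )
            nodes.append(node)
            if current is None:
                if pending is not None:  # unreachable by grammar, guard anyway
                    raise ConnectorBondError("dangling connector")
                roots.append(node.node_id)
            else:
                if pending is None:
                    raise ConnectorBondError(
                        f"fragment {frag!r} has no connector to the "
                        "preceding fragment"
                    )
                pi, ci = pending
                parent = nodes[current]
                if pi >= parent.n_atoms:
                    raise ConnectorBondError(
                        f"connector index {pi} out of range for parent "
                        f"{parent.fragment_word!r} ({parent.n_atoms} atoms)"
                    )
                if ci >= n_atoms:
                    raise ConnectorBondError(
                        f"connector index {ci} out of range for child "
                        f"{frag!r} ({n_atoms} atoms)"
                    )
                edges.append(
                    ReducedGraphEdge(
                        node_a=current,
                        local_index_a=pi,
                        node_b=node.node_id,
                        local_index_b=ci,
                    )
                )
                pending = None
            current = node.node_id

    if pending is not None:
        raise ConnectorBondError("trailing connector token")
    if stack:
        raise BranchError("unclosed branch at end of sequence")
    if current is None and nodes:
        raise TokenError("separator cannot close a sequence")
    if not nodes:
        raise TokenError("empty token sequence")
    graph = ReducedGraph(nodes=nodes, edges=edges, component_roots=roots)
    return graph


def decode(graph: ReducedGraph) -> Chem.Mol:
    """Reassemble the molecule: restore cleaved single bonds, consume one
    hydrogen cap per restored bond, and re-impose stored CIP parities."""
    em = Chem.RWMol()
    offsets: dict[int, int] = {}
    for node in graph.nodes:
        frag = Chem.MolFromSmiles(node.fragment_word)
        if frag is None:
            raise TokenError(f"unknown fragment word: {node.fragment_word!r}")
        offsets[node.node_id] = em.GetNumAtoms()
        for atom in frag.GetAtoms():
            em.AddAtom(atom)
        for bond in frag.GetBonds():
            em.AddBond(
                offsets[node.node_id] + bond.GetBeginAtomIdx(),
                offsets[node.node_id] + bond.GetEndAtomIdx(),
                bond.GetBondType(),
            )
            nb = em.GetBondBetweenAtoms(
                offsets[node.node_id] + bond.GetBeginAtomIdx(),
                offsets[node.node_id] + bond.GetEndAtomIdx(),
            )
            stereo = bond.GetStereo()
            if stereo != Chem.BondStereo.STEREONONE:
                sa = [offsets[node.node_id] + int(x) for x in bond.GetStereoAtoms()]
                nb.SetStereoAtoms(sa[0], sa[1])
                nb.SetStereo(stereo)

    for edge in graph.edges:
        ia = offsets[edge.node_a] + edge.local_index_a
        ib = offsets[edge.node_b] + edge.local_index_b
        if em.GetBondBetweenAtoms(ia, ib) is not None:
            raise ConnectorBondError(
                f"duplicate bond between atoms {ia} and {ib}"
            )
        em.AddBond(ia, ib, Chem.BondType.SINGLE)
        for idx in (ia, ib):
            atom = em.GetAtomWithIdx(idx)
            if atom.GetNumExplicitHs() > 0:
                atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)

    targets: dict[int, str] = {}
    for node in graph.nodes:
        for local, parity in node.chirality_labels:
            targets[offsets[node.node_id] + local] = parity
    try:
        mol = chem.impose_cip_labels(em, targets)
    except ChiralityError:
        raise
    except Exception as exc:  # sanitize failures -> valence taxonomy
        raise ValenceError(str(exc)) from exc
    return chem.canonical_mol(mol)


def encode(mol: "Chem.Mol | str") -> str:
    """Canonical fragSMILES string of a molecule (any input atom order)."""
    graph = fragment_molecule(mol)
    assign_fragment_chirality(getattr(graph, "parent_mol"), graph)
    return str(serialize(graph))


def decode_string(raw: str) -> Chem.Mol:
    """Convenience composition ``decode(parse(raw))``."""
    return decode(parse(raw))


def write_vocabulary(corpus: list["TokenSequence | str"], path: str) -> int:
    """Write the corpus vocabulary, one token per line, frequency-sorted,
    with the reserved grammar words first; returns the vocabulary size."""
    vocab = token_stats(corpus)["vocabulary"]
    reserved = [BRANCH_OPEN, BRANCH_CLOSE, SEPARATOR]
    with open(path, "w") as fh:
        for word in reserved:
            fh.write(word + "\n")
        for word, _ in vocab.most_common():
            if word not in reserved:
                fh.write(word + "\n")
    return len(set(vocab) | set(reserved))


def token_stats(corpus: list["TokenSequence | str"]) -> dict:
    """Vocabulary size, token-length quantiles and per-kind fractions."""
    if not corpus:
        raise ValueError("empty corpus")
    seqs = [tokenize(c) if isinstance(c, str) else c for c in corpus]
    vocab = Counter()
    kind_counts = Counter()
    lengths = []
    for seq in seqs:
        lengths.append(len(seq))
        for tok in seq.tokens:
            vocab[tok.word] += 1
            kind_counts[tok.kind] += 1
    lengths_arr = np.asarray(lengths, dtype=float)
    total = sum(kind_counts.values())
    return {
        "n_sequences": len(seqs),
        "vocabulary_size": len(vocab),
        "vocabulary": vocab,
        "length_quantiles": {
            "min": float(lengths_arr.min()),
            "q25": float(np.quantile(lengths_arr, 0.25)),
            "median": float(np.quantile(lengths_arr, 0.5)),
            "q75": float(np.quantile(lengths_arr, 0.75)),
            "max": float(lengths_arr.max()),
            "mean": float(lengths_arr.mean()),
        },
        "kind_fractions": {k: v / total for k, v in kind_counts.items()},
    }
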