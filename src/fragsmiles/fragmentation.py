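"""Molecule fragmentation by exocyclic single-bond cleavage.

Every single bond between two heavy atoms that is not part of a ring is
cleaved; the connected components that remain become the nodes of a
*reduced graph* and each cleaved bond becomes an edge that remembers the
attachment atom on either side.  Because only acyclic single bonds are cut,
every ring system stays inside one node and the reduced graph is a forest.

Fragment nodes are described by a context-free *fragment word*: the
canonical SMILES of the hydrogen-capped induced subgraph, computed without
any reference to where the fragment attaches elsewhere.  Tetrahedral
chirality is carried separately as ``(local index, CIP label)`` pairs,
where the label is perceived on the intact parent molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from . import chem
from .errors import UnsupportedStereoError


@dataclass
class FragmentNode:
    """One fragment of the reduced graph.

    ``local_atoms[i]`` is the parent-molecule atom index of the fragment's
    atom with local index ``i``; local numbering follows the canonical
    SMILES output order of the fragment in isolation, so connector indices
    are context-free.  ``local_atoms`` is ``None`` for graphs parsed from
    strings, where no parent molecule exists.
    """

    node_id: int
    fragment_word: str
    n_atoms: int
    local_atoms: list[int] | None = None
    chirality_labels: list[tuple[int, str]] = field(default_factory=list)


@dataclass(frozen=True)
class ReducedGraphEdge:
    """A cleaved single bond: ``local_index_a`` on node ``node_a`` bonds to
    ``local_index_b`` on node ``node_b``."""

    node_a: int
    local_index_a: int
    node_b: int
    local_index_b: int

    @property
    def order(self) -> str:
        return "single"


@dataclass
class ReducedGraph:
    nodes: list[FragmentNode]
    edges: list[ReducedGraphEdge]
    component_roots: list[int] = field(default_factory=list)

    def neighbors(self, node_id: int) -> list[tuple[ReducedGraphEdge, int]]:
        out = []
        for edge in self.edges:
            if edge.node_a == node_id:
                out.append((edge, edge.node_b))
            elif edge.node_b == node_id:
                out.append((edge, edge.node_a))
        return out

    def components(self) -> list[list[int]]:
        """Connected components as sorted node-id lists."""
        seen: set[int] = set()
        comps = []
        for node in self.nodes:
            if node.node_id in seen:
                continue
            stack, comp = [node.node_id], []
            seen.add(node.node_id)
            while stack:
                cur = stack.pop()
                comp.append(cur)
                for _, other in self.neighbors(cur):
                    if other not in seen:
                        seen.add(other)
                        stack.append(other)
            comps.append(sorted(comp))
        return comps

    def is_forest(self) -> bool:
        return len(self.edges) == len(self.nodes) - len(self.components())

    def dump(self) -> str:
        """Plain-text adjacency listing for golden-file tests."""
        lines = []
        for node in self.nodes:
            labels = ",".join(f"{i}{p}" for i, p in node.chirality_labels)
            lines.append(
                f"node {node.node_id}\t{node.fragment_word}\t[{labels}]"
            )
        for e in sorted(
            self.edges,
            key=lambda e: (e.node_a, e.local_index_a, e.node_b, e.local_index_b),
        ):
            lines.append(
                f"edge {e.node_a}.{e.local_index_a}-{e.node_b}.{e.local_index_b}"
            )
        return "\n".join(lines)


def find_cleavage_bonds(mol: Chem.Mol) -> set[int]:
    """Bond indices of all exocyclic single bonds between heavy atoms."""
    out = set()
    for bond in mol.GetBonds():
        if (
            bond.GetBondType() == Chem.BondType.SINGLE
            and not bond.IsInRing()
            and bond.GetBeginAtom().GetAtomicNum() > 1
            and bond.GetEndAtom().GetAtomicNum() > 1
        ):
            out.add(bond.GetIdx())
    return out


def _fragment_components(mol: Chem.Mol, cleave: set[int]) -> list[list[int]]:
    """Connected components of the atom graph after deleting ``cleave``."""
    adj: dict[int, list[int]] = {a.GetIdx(): [] for a in mol.GetAtoms()}
    for bond in mol.GetBonds():
        if bond.GetIdx() in cleave:
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i].append(j)
        adj[j].append(i)
    seen: set[int] = set()
    comps = []
    for start in sorted(adj):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        comps.append(sorted(comp))
    return comps


def _build_fragment(
    mol: Chem.Mol, atom_ids: list[int], cleaved_per_atom: dict[int, int]
) -> tuple[str, list[int]]:
    """Fragment word and local numbering for one induced subgraph.

    Severed bonds are replaced by hydrogens so the word is context-free;
    explicit-H caps are needed only for fixed-valence (noImplicit) atoms and
    aromatic non-carbons, where RDKit does not recompute implicit counts.
    Tetrahedral tags are not copied (chirality travels separately); bond
    stereo is kept when all four defining atoms lie inside the fragment.
    """
    em = Chem.RWMol()
    amap: dict[int, int] = {}
    for idx in atom_ids:
        atom = mol.GetAtomWithIdx(idx)
        na = Chem.Atom(atom.GetAtomicNum())
        na.SetFormalCharge(atom.GetFormalCharge())
        na.SetIsotope(atom.GetIsotope())
        na.SetIsAromatic(atom.GetIsAromatic())
        na.SetNoImplicit(atom.GetNoImplicit())
        nh = atom.GetNumExplicitHs()
        k = cleaved_per_atom.get(idx, 0)
        if k and (
            atom.GetNoImplicit()
            or (atom.GetIsAromatic() and atom.GetAtomicNum() != 6)
        ):
            nh += k
        na.SetNumExplicitHs(nh)
        amap[idx] = em.AddAtom(na)
    inside = set(atom_ids)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in inside and j in inside:
            em.AddBond(amap[i], amap[j], bond.GetBondType())
            stereo = bond.GetStereo()
            if stereo != Chem.BondStereo.STEREONONE:
                satoms = [int(x) for x in bond.GetStereoAtoms()]
                if all(s in inside for s in satoms):
                    nb = em.GetBondBetweenAtoms(amap[i], amap[j])
                    nb.SetStereoAtoms(amap[satoms[0]], amap[satoms[1]])
                    nb.SetStereo(stereo)
    frag = em.GetMol()
    Chem.SanitizeMol(frag)
    word = Chem.MolToSmiles(frag)
    order = chem.smiles_output_order(frag)
    inv = {sub: parent for parent, sub in amap.items()}
    local_atoms = [inv[sub] for sub in order]
    return word, local_atoms


def fragment_molecule(mol: "Chem.Mol | str") -> ReducedGraph:
    """Cleave exocyclic single bonds and build the reduced graph.

    The parent molecule is canonicalized first, so the result (and every
    serialization derived from it) is invariant under input atom reordering.
    """
    mol = chem.canonical_mol(mol)
    cleave = find_cleavage_bonds(mol)
    cleaved_per_atom: dict[int, int] = {}
    for bidx in cleave:
        bond = mol.GetBondWithIdx(bidx)
        for a in (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()):
            cleaved_per_atom[a] = cleaved_per_atom.get(a, 0) + 1
    comps = _fragment_components(mol, cleave)

    nodes: list[FragmentNode] = []
    atom_to_node: dict[int, int] = {}
    atom_to_local: dict[int, int] = {}
    for node_id, atom_ids in enumerate(comps):
        word, local_atoms = _build_fragment(mol, atom_ids, cleaved_per_atom)
        nodes.append(
            FragmentNode(
                node_id=node_id,
                fragment_word=word,
                n_atoms=len(local_atoms),
                local_atoms=local_atoms,
            )
        )
        for local, parent in enumerate(local_atoms):
            atom_to_node[parent] = node_id
            atom_to_local[parent] = local

    edges = []
    for bidx in sorted(cleave):
        bond = mol.GetBondWithIdx(bidx)
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append(
            ReducedGraphEdge(
                node_a=atom_to_node[i],
                local_index_a=atom_to_local[i],
                node_b=atom_to_node[j],
                local_index_b=atom_to_local[j],
            )
        )

    graph = ReducedGraph(nodes=nodes, edges=edges)
    graph.component_roots = [comp[0] for comp in graph.components()]
    graph.parent_mol = mol  # type: ignore[attr-defined]
    return graph


def assign_fragment_chirality(
    mol: "Chem.Mol | str", graph: ReducedGraph
) -> ReducedGraph:
    """Attach CIP parities (perceived on the intact molecule) to the owning
    fragment nodes, keyed by fragment-local atom index."""
    mol = chem.canonical_mol(mol)
    atom_to_node: dict[int, tuple[int, int]] = {}
    for node in graph.nodes:
        if node.local_atoms is None:
            raise ValueError("graph has no parent-atom bookkeeping")
        for local, parent in enumerate(node.local_atoms):
            atom_to_node[parent] = (node.node_id, local)
    # flag centers RDKit cannot label before silently losing them
    tagged = {
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetChiralTag()
        in (
            Chem.ChiralType.CHI_TETRAHEDRAL_CW,
            Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
        )
    }
    centers = chem.assigned_stereocenters(mol)
    labelled = {idx for idx, _ in centers}
    unsupported = tagged - labelled
    if unsupported:
        raise UnsupportedStereoError(
            f"stereocenters without a CIP label cannot be carried: "
            f"atoms {sorted(unsupported)}"
        )
    for node in graph.nodes:
        node.chirality_labels = []
    for idx, label in centers:
        node_id, local = atom_to_node[idx]
        graph.nodes[node_id].chirality_labels.append((local, label))
    for node in graph.nodes:
        node.chirality_labels.sort()
    return graph
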