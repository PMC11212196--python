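"""Molecular graph data model.

Molecules are stored as plain heavy-atom graphs: hydrogens are implicit
(folded into per-atom counts), bond orders are 1, 2, 3 or 1.5 (aromatic).
RDKit is used for parsing, sanitization and canonical serialization; all
template logic operates on these lightweight graphs.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import networkx as nx
from rdkit import Chem

# bond orders
SINGLE = 1.0
DOUBLE = 2.0
TRIPLE = 3.0
AROMATIC = 1.5

_ORDER_TO_RDKIT = {
    SINGLE: Chem.BondType.SINGLE,
    DOUBLE: Chem.BondType.DOUBLE,
    TRIPLE: Chem.BondType.TRIPLE,
    AROMATIC: Chem.BondType.AROMATIC,
}
_RDKIT_TO_ORDER = {v: k for k, v in _ORDER_TO_RDKIT.items()}

# tetrahedral chirality tags (RDKit convention, relative to stored bond order)
CHI_NONE = "none"
CHI_CW = "cw"
CHI_CCW = "ccw"

_CHI_TO_RDKIT = {
    CHI_NONE: Chem.ChiralType.CHI_UNSPECIFIED,
    CHI_CW: Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    CHI_CCW: Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
}
_RDKIT_TO_CHI = {v: k for k, v in _CHI_TO_RDKIT.items()}


@dataclass
class AtomNode:
    """A heavy atom (or a lone hydrogen in H-only molecules such as H2)."""

    element: str
    formal_charge: int = 0
    explicit_h: int = 0
    aromatic: bool = False
    map_num: int | None = None
    radical_electrons: int = 0
    chirality: str = CHI_NONE

    def copy(self) -> "AtomNode":
        return replace(self)


@dataclass
class BondEdge:
    """An undirected bond between two atom indices."""

    i: int
    j: int
    order: float = SINGLE
    # double-bond stereo: RDKit BondStereo name plus the two reference atoms
    stereo: str = "none"
    stereo_atoms: tuple[int, int] | None = None

    def copy(self) -> "BondEdge":
        return replace(self)

    def other(self, idx: int) -> int:
        return self.j if idx == self.i else self.i


class MoleculeGraph:
    """Mutable heavy-atom molecular graph.

    Atom indices are stable under bond edits; `split_fragments` enumerates
    connected components. Serialization round-trips through RDKit canonical
    SMILES.
    """

    def __init__(self, atoms: list[AtomNode] | None = None,
                 bonds: list[BondEdge] | None = None):
        self.atoms: list[AtomNode] = atoms or []
        self.bonds: list[BondEdge] = bonds or []

    # -- construction ----------------------------------------------------
    def add_atom(self, atom: AtomNode) -> int:
        self.atoms.append(atom)
        return len(self.atoms) - 1

    def add_bond(self, i: int, j: int, order: float = SINGLE) -> BondEdge:
        if i == j:
            raise ValueError("self-bond")
        if self.bond_between(i, j) is not None:
            raise ValueError(f"duplicate bond {i}-{j}")
        b = BondEdge(i, j, order)
        self.bonds.append(b)
        return b

    def remove_bond(self, i: int, j: int) -> None:
        b = self.bond_between(i, j)
        if b is None:
            raise ValueError(f"no bond {i}-{j}")
        self.bonds.remove(b)

    def copy(self) -> "MoleculeGraph":
        return MoleculeGraph([a.copy() for a in self.atoms],
                             [b.copy() for b in self.bonds])

    # -- queries ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    def bond_between(self, i: int, j: int) -> BondEdge | None:
        for b in self.bonds:
            if (b.i == i and b.j == j) or (b.i == j and b.j == i):
                return b
        return None

    def neighbors(self, idx: int) -> list[tuple[int, BondEdge]]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append((b.j, b))
            elif b.j == idx:
                out.append((b.i, b))
        return out

    def degree(self, idx: int) -> int:
        return len(self.neighbors(idx))

    def bond_order_sum(self, idx: int) -> float:
        return sum(b.order for _, b in self.neighbors(idx))

    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")

    def element_counter(self) -> Counter:
        """Heavy-atom element counts (hydrogens excluded)."""
        return Counter(a.element for a in self.atoms if a.element != "H")

    def map_nums(self) -> set[int]:
        return {a.map_num for a in self.atoms if a.map_num is not None}

    # -- structure -------------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for idx, a in enumerate(self.atoms):
            g.add_node(idx, element=a.element, charge=a.formal_charge,
                       explicit_h=a.explicit_h, aromatic=a.aromatic,
                       map_num=a.map_num, radical=a.radical_electrons)
        for b in self.bonds:
            g.add_edge(b.i, b.j, order=b.order)
        return g

    def subgraph(self, indices: list[int]) -> "MoleculeGraph":
        """Induced subgraph on `indices` (in the given order)."""
        remap = {old: new for new, old in enumerate(indices)}
        atoms = [self.atoms[i].copy() for i in indices]
        bonds = []
        for b in self.bonds:
            if b.i in remap and b.j in remap:
                nb = b.copy()
                nb.i, nb.j = remap[b.i], remap[b.j]
                if nb.stereo_atoms is not None:
                    sa = tuple(remap.get(x) for x in nb.stereo_atoms)
                    nb.stereo_atoms = None if None in sa else sa
                    if nb.stereo_atoms is None:
                        nb.stereo = "none"
                bonds.append(nb)
        return MoleculeGraph(atoms, bonds)

    def split_fragments(self) -> list[tuple["MoleculeGraph", list[int]]]:
        """Connected components as (subgraph, original atom indices)."""
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        out = []
        for comp in nx.connected_components(g):
            indices = sorted(comp)
            out.append((self.subgraph(indices), indices))
        return out

    # -- RDKit interop ---------------------------------------------------
    @classmethod
    def from_rdkit(cls, mol: Chem.Mol) -> "MoleculeGraph":
        g = cls()
        for a in mol.GetAtoms():
            g.add_atom(AtomNode(
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                explicit_h=a.GetTotalNumHs(),
                aromatic=a.GetIsAromatic(),
                map_num=a.GetAtomMapNum() or None,
                radical_electrons=a.GetNumRadicalElectrons(),
                chirality=_RDKIT_TO_CHI.get(a.GetChiralTag(), CHI_NONE),
            ))
        for b in mol.GetBonds():
            e = g.add_bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                           _RDKIT_TO_ORDER[b.GetBondType()])
            st = b.GetStereo()
            if st != Chem.BondStereo.STEREONONE:
                e.stereo = st.name
                sa = list(b.GetStereoAtoms())
                if len(sa) == 2:
                    e.stereo_atoms = (sa[0], sa[1])
        return g

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        m = Chem.RWMol()
        for a in self.atoms:
            ra = Chem.Atom(a.element)
            ra.SetFormalCharge(a.formal_charge)
            ra.SetNoImplicit(True)
            ra.SetNumExplicitHs(a.explicit_h)
            ra.SetIsAromatic(a.aromatic)
            ra.SetNumRadicalElectrons(a.radical_electrons)
            if a.map_num is not None:
                ra.SetAtomMapNum(a.map_num)
            ra.SetChiralTag(_CHI_TO_RDKIT[a.chirality])
            m.AddAtom(ra)
        for b in self.bonds:
            m.AddBond(b.i, b.j, _ORDER_TO_RDKIT[b.order])
        mol = m.GetMol()
        if sanitize:
            Chem.SanitizeMol(mol)
        else:
            mol.UpdatePropertyCache(strict=False)
        # bond stereo must be applied after sanitization
        had_stereo = False
        for b in self.bonds:
            if b.stereo != "none" and b.stereo_atoms is not None:
                rb = mol.GetBondBetweenAtoms(b.i, b.j)
                rb.SetStereoAtoms(*b.stereo_atoms)
                rb.SetStereo(getattr(Chem.BondStereo, b.stereo))
                had_stereo = True
        if had_stereo:
            Chem.SetDoubleBondNeighborDirections(mol)
        return mol

    def to_smiles(self, ignore_maps: bool = False,
                  ignore_stereo: bool = False) -> str:
        mol = self.to_rdkit(sanitize=True)
        if ignore_maps:
            for a in mol.GetAtoms():
                a.SetAtomMapNum(0)
        return Chem.MolToSmiles(mol, isomericSmiles=not ignore_stereo)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        try:
            return f"MoleculeGraph({self.to_smiles()!r})"
        except Exception:
            return f"MoleculeGraph(<{len(self.atoms)} atoms, unsanitizable>)"


def canonical_key(mol: MoleculeGraph, ignore_maps: bool = True,
                  ignore_stereo: bool = False) -> str:
    """Deterministic canonical serialization of a molecule graph.

    Two graphs isomorphic under element / charge / H-count / bond-order
    labels yield identical keys (RDKit canonical SMILES; ties in the
    canonical ranking are broken by RDKit's documented invariant-based
    Morgan-style algorithm, stable across runs and platforms). With
    `ignore_maps`, atom-map numbers do not influence the key.
    """
    return mol.to_smiles(ignore_maps=ignore_maps, ignore_stereo=ignore_stereo)


def multiset_key(mols: list[MoleculeGraph], ignore_maps: bool = True,
                 ignore_stereo: bool = False) -> tuple[str, ...]:
    """Sorted tuple of canonical keys — canonical form of a molecule multiset."""
    return tuple(sorted(canonical_key(m, ignore_maps, ignore_stereo)
                        for m in mols))
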