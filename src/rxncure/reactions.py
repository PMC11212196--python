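"""Atom-mapped reactions: parsing, normalization, spectator handling, and
the condensed graph of reaction (CGR).

A reaction record is reaction SMILES in either the `reactants>agents>products`
or the `reactants>>products` dialect. Agents (middle field) are treated as
spectators and need not be mapped. On ingest, isotope labels are stripped
(they do not affect the transformation) and explicit hydrogens attached to
heavy atoms are folded into H counts; hydrogen-only molecules such as H2
keep their atoms.

The CGR superposes the reactant and product graphs: nodes are atoms paired
by map number, edges carry (order_before, order_after) labels with absent
bonds encoded as order 0. The changed-edge set is exactly the reaction
center bond set.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem
from rdkit.rdBase import BlockLogs

from .errors import (CgrIntegrityError, EmptyCoreError, ReactionParseError)
from .graphs import MoleculeGraph, multiset_key


@dataclass
class MappedReaction:
    """A parsed reaction with reactant/product graphs and spectators."""

    reactants: list[MoleculeGraph] = field(default_factory=list)
    products: list[MoleculeGraph] = field(default_factory=list)
    spectators: list[MoleculeGraph] = field(default_factory=list)
    source_id: str = ""

    def copy(self) -> "MappedReaction":
        return MappedReaction([m.copy() for m in self.reactants],
                              [m.copy() for m in self.products],
                              [m.copy() for m in self.spectators],
                              self.source_id)

    def product_map_nums(self) -> set[int]:
        out: set[int] = set()
        for m in self.products:
            out |= m.map_nums()
        return out

    def reactant_map_nums(self) -> set[int]:
        out: set[int] = set()
        for m in self.reactants:
            out |= m.map_nums()
        return out

    def to_smiles(self, include_spectators: bool = True) -> str:
        r = ".".join(m.to_smiles() for m in self.reactants)
        p = ".".join(m.to_smiles() for m in self.products)
        if include_spectators and self.spectators:
            s = ".".join(m.to_smiles() for m in self.spectators)
            return f"{r}>{s}>{p}"
        return f"{r}>>{p}"


def _normalize_rdkit_mol(mol: Chem.Mol) -> Chem.Mol:
    """Strip isotopes; fold heavy-atom-attached explicit hydrogens."""
    mol = Chem.RWMol(mol)
    for a in mol.GetAtoms():
        a.SetIsotope(0)
        # map numbers on hydrogens are dropped with the hydrogens
        if a.GetAtomicNum() == 1 and a.GetDegree() > 0:
            heavy = any(n.GetAtomicNum() != 1 for n in a.GetNeighbors())
            if heavy:
                a.SetAtomMapNum(0)
    mol = Chem.RemoveHs(mol.GetMol())
    Chem.SanitizeMol(mol)
    return mol


def _parse_side(text: str, record_id) -> list[MoleculeGraph]:
    if not text:
        return []
    with BlockLogs():
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ReactionParseError(record_id, f"unparsable molecule text {text!r}")
    mol = _normalize_rdkit_mol(mol)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return [MoleculeGraph.from_rdkit(f) for f in frags]


def parse_reaction(record: str, record_id: str = "") -> MappedReaction:
    """Parse one reaction-SMILES record into a normalized MappedReaction.

    Accepts both ``a>b>c`` and ``a>>c``; middle-field molecules become
    spectators. Unparsable molecule text raises :class:`ReactionParseError`
    carrying the record id (callers drop and log the record). Unmapped
    product atoms are permitted — they signal missing reactant information
    handled downstream.
    """
    fields = record.strip().split(">")
    if len(fields) == 2:
        r_text, a_text, p_text = fields[0], "", fields[1]
    elif len(fields) == 3:
        r_text, a_text, p_text = fields
    else:
        raise ReactionParseError(
            record_id, f"expected 2 or 3 '>'-delimited fields, got {len(fields)}")
    rxn = MappedReaction(
        reactants=_parse_side(r_text, record_id),
        products=_parse_side(p_text, record_id),
        spectators=_parse_side(a_text, record_id),
        source_id=record_id,
    )
    for side in (rxn.reactants, rxn.products):
        _check_unique_maps(side, record_id)
    return rxn


def _check_unique_maps(mols: list[MoleculeGraph], record_id) -> None:
    counts = Counter()
    for m in mols:
        for a in m.atoms:
            if a.map_num is not None:
                counts[a.map_num] += 1
    dup = [k for k, v in counts.items() if v > 1]
    if dup:
        raise ReactionParseError(
            record_id, f"duplicate map numbers on one side: {sorted(dup)}")


def remove_spectators(rxn: MappedReaction) -> MappedReaction:
    """Move reactant molecules contributing no mapped heavy atom to any
    product into the spectator list.

    Reversible via :func:`reinstate_spectators`. Raises
    :class:`EmptyCoreError` when every reactant is a spectator.
    """
    pmaps = rxn.product_map_nums()
    out = rxn.copy()
    core, spect = [], []
    for m in out.reactants:
        contributes = any(a.map_num in pmaps for a in m.atoms
                          if a.map_num is not None and a.element != "H")
        (core if contributes else spect).append(m)
    if not core:
        raise EmptyCoreError(
            f"record {rxn.source_id!r}: every reactant is a spectator")
    out.reactants = core
    out.spectators = out.spectators + spect
    return out


def reinstate_spectators(rxn: MappedReaction) -> MappedReaction:
    """Merge spectators back into the reactant list."""
    out = rxn.copy()
    out.reactants = out.reactants + out.spectators
    out.spectators = []
    return out


# ---------------------------------------------------------------------------
# Condensed graph of reaction
# ---------------------------------------------------------------------------

class CgrGraph:
    """Superposition of reactant and product graphs.

    Nodes are keyed by map number for atoms present on the product side;
    reactant-only atoms (unmapped, or carrying a map number absent from the
    product) get synthetic keys. Node labels: (element_before,
    element_after, h_delta, charge_delta); edge labels: (order_before,
    order_after), absent bonds encoded as 0.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph

    def changed_edges(self) -> list[tuple]:
        return [(u, v) for u, v, d in self.graph.edges(data=True)
                if d["before"] != d["after"]]

    def changed_map_nums(self) -> set[int]:
        """Mapped atoms whose bonding, H count, charge or element changes."""
        out: set[int] = set()
        for u, v in self.changed_edges():
            for n in (u, v):
                m = self.graph.nodes[n]["map_num"]
                if m is not None:
                    out.add(m)
        for n, d in self.graph.nodes(data=True):
            if d["map_num"] is None:
                continue
            if (d["h_delta"] != 0 or d["charge_delta"] != 0
                    or d["element_before"] != d["element_after"]):
                out.add(d["map_num"])
        return out

    def _label_multisets(self):
        nodes = sorted((d["element_before"] or "", d["element_after"] or "",
                        d["h_delta"], d["charge_delta"])
                       for _, d in self.graph.nodes(data=True))
        edges = sorted(
            (tuple(sorted((self.graph.nodes[u]["element_after"] or "",
                           self.graph.nodes[v]["element_after"] or ""))),
             d["before"], d["after"])
            for u, v, d in self.graph.edges(data=True))
        return nodes, edges

    def __eq__(self, other) -> bool:
        if not isinstance(other, CgrGraph):
            return NotImplemented
        return cgr_equal(self, other)

    def __ne__(self, other) -> bool:
        eq = self.__eq__(other)
        return NotImplemented if eq is NotImplemented else not eq


def build_cgr(rxn: MappedReaction) -> CgrGraph:
    """Build the CGR of a reaction (spectators excluded, hydrogen-only
    molecules contribute nothing — hydrogen is tracked via h_delta).

    Unmapped product atoms enter as product-only nodes; reactant atoms
    whose map number does not occur on the product side are treated as
    reactant-only (their bonds get order_after 0). Duplicate map numbers
    on one side raise :class:`CgrIntegrityError`.
    """
    pmaps: dict[int, tuple[int, int]] = {}   # map_num -> (mol_idx, atom_idx)
    for mi, m in enumerate(rxn.products):
        for ai, a in enumerate(m.atoms):
            if a.map_num is None or a.element == "H":
                continue
            if a.map_num in pmaps:
                raise CgrIntegrityError(
                    f"duplicate map {a.map_num} on product side")
            pmaps[a.map_num] = (mi, ai)
    rmaps: dict[int, tuple[int, int]] = {}
    for mi, m in enumerate(rxn.reactants):
        for ai, a in enumerate(m.atoms):
            if a.map_num is None or a.element == "H":
                continue
            if a.map_num in rmaps:
                raise CgrIntegrityError(
                    f"duplicate map {a.map_num} on reactant side")
            rmaps[a.map_num] = (mi, ai)

    g = nx.Graph()
    key_of_reactant_atom: dict[tuple[int, int], object] = {}
    key_of_product_atom: dict[tuple[int, int], object] = {}

    # paired + reactant-only nodes
    for mi, m in enumerate(rxn.reactants):
        for ai, a in enumerate(m.atoms):
            if a.element == "H":
                continue
            paired = a.map_num is not None and a.map_num in pmaps
            key = a.map_num if paired else ("r", mi, ai)
            key_of_reactant_atom[(mi, ai)] = key
            if paired:
                pa = rxn.products[pmaps[a.map_num][0]].atoms[pmaps[a.map_num][1]]
                g.add_node(key, map_num=a.map_num,
                           element_before=a.element, element_after=pa.element,
                           h_delta=pa.explicit_h - a.explicit_h,
                           charge_delta=pa.formal_charge - a.formal_charge)
            else:
                g.add_node(key, map_num=None,
                           element_before=a.element, element_after=None,
                           h_delta=-a.explicit_h,
                           charge_delta=-a.formal_charge)
    # product-only nodes
    for mi, m in enumerate(rxn.products):
        for ai, a in enumerate(m.atoms):
            if a.element == "H":
                continue
            if a.map_num is not None and a.map_num in rmaps:
                key_of_product_atom[(mi, ai)] = a.map_num
                continue
            key = a.map_num if a.map_num is not None else ("p", mi, ai)
            key_of_product_atom[(mi, ai)] = key
            g.add_node(key, map_num=a.map_num,
                       element_before=None, element_after=a.element,
                       h_delta=a.explicit_h, charge_delta=a.formal_charge)

    def _add_side(mols, key_of, attr):
        for mi, m in enumerate(mols):
            for b in m.bonds:
                ki = key_of.get((mi, b.i))
                kj = key_of.get((mi, b.j))
                if ki is None or kj is None:   # hydrogen endpoints
                    continue
                if g.has_edge(ki, kj):
                    g[ki][kj][attr] = b.order
                else:
                    g.add_edge(ki, kj, **{"before": 0, "after": 0, attr: b.order})

    _add_side(rxn.reactants, key_of_reactant_atom, "before")
    _add_side(rxn.products, key_of_product_atom, "after")
    return CgrGraph(g)


def cgr_equal(a: CgrGraph, b: CgrGraph) -> bool:
    """Equality of two CGRs as labeled graphs.

    Two CGRs are equal when an isomorphism exists preserving node labels
    (element before/after, h_delta, charge_delta) and edge labels
    (order_before, order_after); map numbers themselves are not compared,
    so renumbered-but-consistent mappings of the same transformation
    compare equal while any transposition of two non-equivalent atoms
    does not.
    """
    if a.graph.number_of_nodes() != b.graph.number_of_nodes():
        return False
    if a.graph.number_of_edges() != b.graph.number_of_edges():
        return False
    if a._label_multisets() != b._label_multisets():
        return False
    nm = nx.algorithms.isomorphism.categorical_node_match(
        ["element_before", "element_after", "h_delta", "charge_delta"],
        [None, None, 0, 0])
    em = nx.algorithms.isomorphism.categorical_edge_match(
        ["before", "after"], [0, 0])
    return nx.is_isomorphic(a.graph, b.graph, node_match=nm, edge_match=em)


def reaction_key(rxn: MappedReaction, ignore_maps: bool = True) -> str:
    """Mapping-agnostic canonical key of a reaction (spectators excluded)."""
    r = ".".join(multiset_key(rxn.reactants, ignore_maps=ignore_maps))
    p = ".".join(multiset_key(rxn.products, ignore_maps=ignore_maps))
    return f"{r}>>{p}"
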