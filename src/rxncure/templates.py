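"""Generic retro-template extraction, canonicalization and filtering.

A generic template is a radius-0 retrosynthetic transformation pattern: its
product side contains only the reaction-center atoms (element + map number,
bond orders among them), its reactant side the same atoms plus any
leaving-group atoms, written in a SMARTS dialect with atomic-number
primitives (``[#6:1]-[#6:2]-[#8:3]>>Br-[#6:1].[#6:2]=[#8:3]``). Atom
aromaticity, degree, chirality, hydrogen counts and charges are discarded,
with two exceptions: hydrogen counts are kept on center atoms of radical
reactions and formal charges on center atoms of charge-transfer reactions.
When the reaction centers are disconnected within one product molecule the
shortest connecting path (unweighted Dijkstra) is added, so ring-opening
transformations stay single-fragment.

Templates representing the same transformation are merged by graph
isomorphism of their two sides; following the principle of minimum chemical
distance, the representative with the fewest bond changes is kept, so
map-error-induced variants (which show spurious extra bond changes) are
discarded. Rare templates (frequency <= threshold, default 5) are removed.
"""
from __future__ import annotations

import ast
import itertools
import json
import re
from dataclasses import dataclass, field, replace

import networkx as nx
from rdkit import Chem

from .errors import NullTransformationError, RxncureError
from .graphs import (AROMATIC, DOUBLE, SINGLE, TRIPLE, MoleculeGraph)
from .reactions import MappedReaction, build_cgr, reaction_key, remove_spectators

_PERIODIC = Chem.GetPeriodicTable()

_BOND_SYMBOL = {SINGLE: "-", DOUBLE: "=", TRIPLE: "#", AROMATIC: ":"}
_SYMBOL_BOND = {v: k for k, v in _BOND_SYMBOL.items()}

# elements safe to write as bare symbols (cannot be aromatic)
_BARE_SYMBOLS = {9: "F", 17: "Cl", 35: "Br", 53: "I"}


class TemplateExtractionError(RxncureError):
    """The reaction does not admit a well-formed generic template."""


@dataclass
class AtomPattern:
    """An atom of a generic template.

    ``map_num`` is ``None`` for leaving-group atoms. ``h_count`` and
    ``charge`` are ``None`` unless the radical / charge-transfer special
    case applies (mapped atoms) or a leaving-group atom carries a nonzero
    formal charge.
    """

    atomic_num: int
    map_num: int | None = None
    h_count: int | None = None
    charge: int | None = None

    def copy(self) -> "AtomPattern":
        return replace(self)


class PatternGraph:
    """One side of a generic template: pattern atoms plus ordered bonds."""

    def __init__(self, atoms: list[AtomPattern] | None = None,
                 bonds: list[tuple[int, int, float]] | None = None):
        self.atoms = atoms or []
        self.bonds = bonds or []

    def add_atom(self, ap: AtomPattern) -> int:
        self.atoms.append(ap)
        return len(self.atoms) - 1

    def add_bond(self, i: int, j: int, order: float) -> None:
        self.bonds.append((i, j, order))

    def copy(self) -> "PatternGraph":
        return PatternGraph([a.copy() for a in self.atoms], list(self.bonds))

    def map_to_index(self) -> dict[int, int]:
        return {a.map_num: i for i, a in enumerate(self.atoms)
                if a.map_num is not None}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, a in enumerate(self.atoms):
            g.add_node(i, anum=a.atomic_num, h=a.h_count, charge=a.charge,
                       map_num=a.map_num)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g

    def fragments(self) -> list[list[int]]:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((i, j) for i, j, _ in self.bonds)
        return [sorted(c) for c in nx.connected_components(g)]

    def __len__(self) -> int:
        return len(self.atoms)


# ---------------------------------------------------------------------------
# canonical ordering and SMARTS writing
# ---------------------------------------------------------------------------

def _canonical_order(pg: PatternGraph) -> list[int]:
    """Atom indices in RDKit canonical-SMILES output order.

    The ranking molecule encodes the pattern's match semantics — atomic
    number, bond orders, and (via an isotope tag) whether H count / charge
    are constrained — so isomorphic patterns yield consistent orders
    regardless of input atom order, and non-equivalent specifications never
    collide.
    """
    m = Chem.RWMol()
    any_aromatic_bond = {i for i, j, o in pg.bonds if o == AROMATIC} | \
                        {j for i, j, o in pg.bonds if o == AROMATIC}
    for idx, a in enumerate(pg.atoms):
        ra = Chem.Atom(a.atomic_num)
        ra.SetNoImplicit(True)
        ra.SetNumExplicitHs(a.h_count or 0)
        ra.SetFormalCharge(a.charge or 0)
        ra.SetIsotope((0 if a.h_count is None else a.h_count + 1) * 10
                      + (0 if a.charge is None else 5))
        if idx in any_aromatic_bond:
            ra.SetIsAromatic(True)
        m.AddAtom(ra)
    for i, j, order in pg.bonds:
        m.AddBond(i, j, {SINGLE: Chem.BondType.SINGLE,
                         DOUBLE: Chem.BondType.DOUBLE,
                         TRIPLE: Chem.BondType.TRIPLE,
                         AROMATIC: Chem.BondType.AROMATIC}[order])
    mol = m.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.MolToSmiles(mol)
    return list(ast.literal_eval(mol.GetProp("_smilesAtomOutputOrder")))


def _atom_token(a: AtomPattern, include_map: bool = True) -> str:
    if (a.map_num is None or not include_map) and a.h_count is None \
            and not a.charge and a.atomic_num in _BARE_SYMBOLS:
        return _BARE_SYMBOLS[a.atomic_num]
    parts = [f"#{a.atomic_num}"]
    if a.h_count is not None:
        parts.append(f"H{a.h_count}")
    if a.charge is not None:
        parts.append(f"{'+' if a.charge >= 0 else '-'}{abs(a.charge)}")
    body = ";".join(parts)
    if include_map and a.map_num is not None:
        return f"[{body}:{a.map_num}]"
    return f"[{body}]"


def pattern_to_smarts(pg: PatternGraph, include_maps: bool = True) -> str:
    """Write a pattern graph in the atomic-number SMARTS dialect.

    The traversal follows the canonical atom order, so isomorphic patterns
    produce identical strings (maps aside); fragments are ordered by their
    first canonical atom.
    """
    if not pg.atoms:
        return ""
    pos = {idx: p for p, idx in enumerate(_canonical_order(pg))}
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(pg.atoms))}
    for i, j, order in pg.bonds:
        adj[i].append((j, order))
        adj[j].append((i, order))
    for lst in adj.values():
        lst.sort(key=lambda t: pos[t[0]])

    visited: set[int] = set()
    ring_digit = itertools.count(1)
    # ring-closure bookkeeping: atom -> list of (digit, order)
    closures: dict[int, list[tuple[int, float]]] = {}

    def _emit(u: int, via_order: float | None) -> str:
        visited.add(u)
        s = ""
        if via_order is not None:
            s += _BOND_SYMBOL[via_order]
        s += _atom_token(pg.atoms[u], include_maps)
        for d, order in closures.get(u, []):
            digit = str(d) if d < 10 else f"%{d:02d}"
            s += _BOND_SYMBOL[order] + digit
        branches = []
        for v, order in adj[u]:
            if v in visited:
                continue
            if (min(u, v), max(u, v)) not in _tree_edges:
                continue
            branches.append(_emit(v, order))
        if not branches:
            return s
        for b in branches[:-1]:
            s += f"({b})"
        return s + branches[-1]

    frag_strings = []
    for comp in pg.fragments():
        # leaving-group atoms are written first (field convention for retro
        # templates, e.g. "Br-[#6:1]"); ties by canonical position
        unmapped = [i for i in comp if pg.atoms[i].map_num is None]
        start = min(unmapped or comp, key=lambda i: pos[i])
        # spanning tree following canonical order; non-tree edges -> closures
        _tree_edges: set[tuple[int, int]] = set()
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, _ in reversed(adj[u]):
                if v not in seen:
                    seen.add(v)
                    _tree_edges.add((min(u, v), max(u, v)))
                    stack.append(v)
        for i, j, order in pg.bonds:
            if i in seen and (min(i, j), max(i, j)) not in _tree_edges:
                d = next(ring_digit)
                closures.setdefault(i, []).append((d, order))
                closures.setdefault(j, []).append((d, order))
        frag_strings.append(_emit(start, None))
    return ".".join(sorted(frag_strings))


# ---------------------------------------------------------------------------
# GenericTemplate
# ---------------------------------------------------------------------------

@dataclass
class GenericTemplate:
    """A canonicalized generic retro template."""

    product_pattern: PatternGraph
    reactant_pattern: PatternGraph
    bond_changes: int
    frequency: int = 1
    example_ids: list[str] = field(default_factory=list)
    smarts: str = ""
    signature: tuple[str, str] = ("", "")

    @property
    def reactant_patterns(self) -> list[PatternGraph]:
        """Reactant-side fragments as separate graphs."""
        out = []
        for comp in self.reactant_pattern.fragments():
            remap = {old: new for new, old in enumerate(comp)}
            atoms = [self.reactant_pattern.atoms[i].copy() for i in comp]
            bonds = [(remap[i], remap[j], o)
                     for i, j, o in self.reactant_pattern.bonds
                     if i in remap and j in remap]
            out.append(PatternGraph(atoms, bonds))
        return out


def count_bond_changes(t: GenericTemplate) -> int:
    """Number of atom pairs whose bond order differs between the product
    and reactant patterns.

    Formation, breakage and order change each count 1. Pairs are keyed by
    map number; each bond between a mapped atom and a leaving-group atom is
    a change (the bond does not exist on the product side); bonds among
    leaving-group atoms are internal to the leaving group and do not count.
    H-count and charge specifications never count.
    """
    def _bond_dict(pg: PatternGraph) -> dict[frozenset, float]:
        out = {}
        for i, j, order in pg.bonds:
            mi, mj = pg.atoms[i].map_num, pg.atoms[j].map_num
            if mi is not None and mj is not None:
                out[frozenset((mi, mj))] = order
        return out

    prod = _bond_dict(t.product_pattern)
    react = _bond_dict(t.reactant_pattern)
    changes = 0
    for key in set(prod) | set(react):
        if prod.get(key, 0) != react.get(key, 0):
            changes += 1
    # mapped-to-leaving bonds (reactant side only by construction)
    for i, j, order in t.reactant_pattern.bonds:
        mi = t.reactant_pattern.atoms[i].map_num
        mj = t.reactant_pattern.atoms[j].map_num
        if (mi is None) != (mj is None):
            changes += 1
    return changes


def make_generic_template(product_pattern: PatternGraph,
                          reactant_pattern: PatternGraph,
                          example_ids: list[str] | None = None,
                          frequency: int = 1) -> GenericTemplate:
    """Canonicalize map numbering, compute bond changes, signatures and the
    SMARTS string for a raw template pattern pair."""
    prod = product_pattern.copy()
    react = reactant_pattern.copy()
    # renumber maps 1..k in canonical product-side order
    renum: dict[int, int] = {}
    for idx in _canonical_order(prod):
        m = prod.atoms[idx].map_num
        if m is not None and m not in renum:
            renum[m] = len(renum) + 1
    for pg in (prod, react):
        for a in pg.atoms:
            if a.map_num is not None:
                a.map_num = renum.get(a.map_num)
    t = GenericTemplate(prod, react, 0, frequency, list(example_ids or []))
    t.bond_changes = count_bond_changes(t)
    t.smarts = (pattern_to_smarts(prod) + ">>" + pattern_to_smarts(react))
    t.signature = (pattern_to_smarts(prod, include_maps=False),
                   pattern_to_smarts(react, include_maps=False))
    return t


# ---------------------------------------------------------------------------
# extraction from mapped reactions
# ---------------------------------------------------------------------------

@dataclass
class ExtractionConfig:
    """Settings for generic template extraction."""

    bridge_disjoint: bool = True   # connect separate centers in one product


def find_reaction_center(rxn: MappedReaction) -> set[int]:
    """Map numbers of atoms whose bonding, hydrogen count, formal charge
    or element changes between the two sides.

    Raises :class:`NullTransformationError` when nothing changes.
    """
    centers = build_cgr(rxn).changed_map_nums()
    if not centers:
        raise NullTransformationError(
            f"record {rxn.source_id!r}: reactants and products are identical")
    return centers


def detect_radical_case(rxn: MappedReaction,
                        centers: set[int] | None = None) -> bool:
    """True iff any center atom carries unpaired electrons on either side."""
    if centers is None:
        centers = find_reaction_center(rxn)
    for side in (rxn.reactants, rxn.products):
        for m in side:
            for a in m.atoms:
                if a.map_num in centers and a.radical_electrons > 0:
                    return True
    return False


def detect_charge_transfer(rxn: MappedReaction,
                           centers: set[int] | None = None) -> bool:
    """True iff any mapped center atom changes formal charge between sides."""
    if centers is None:
        centers = find_reaction_center(rxn)
    charge: dict[int, int] = {}
    for m in rxn.reactants:
        for a in m.atoms:
            if a.map_num in centers:
                charge[a.map_num] = a.formal_charge
    for m in rxn.products:
        for a in m.atoms:
            if a.map_num in centers and a.map_num in charge:
                if a.formal_charge != charge[a.map_num]:
                    return True
    return False


def connect_disjoint_centers(product: MoleculeGraph,
                             centers: set[int]) -> set[int]:
    """Add the atoms on shortest paths connecting separate reaction centers
    within one product molecule.

    Paths run through mapped atoms only and are unweighted; among equally
    short paths one is chosen deterministically (smallest endpoint map
    pair, then smallest path map sequence), so no redundant atoms are ever
    included. Center map numbers not present in this molecule (or centers
    in different molecules) are returned unchanged.
    """
    m2i = {a.map_num: i for i, a in enumerate(product.atoms)
           if a.map_num is not None}
    local = {m for m in centers if m in m2i}
    if len(local) < 2:
        return set(centers)
    g = nx.Graph()
    g.add_nodes_from(m2i.values())
    for b in product.bonds:
        if (product.atoms[b.i].map_num is not None
                and product.atoms[b.j].map_num is not None):
            g.add_edge(b.i, b.j)
    result = set(centers)
    idx_local = {m2i[m] for m in local}

    def _components(nodes: set[int]) -> list[set[int]]:
        return [set(c) for c in
                nx.connected_components(g.subgraph(nodes))]

    comps = _components(idx_local)
    while len(comps) > 1:
        best = None
        paths = dict(nx.all_pairs_shortest_path(g))
        for ca, cb in itertools.combinations(range(len(comps)), 2):
            for u in comps[ca]:
                for v in comps[cb]:
                    p = paths.get(u, {}).get(v)
                    if p is None:
                        continue
                    maps = tuple(product.atoms[x].map_num for x in p)
                    key = (len(p), tuple(sorted((maps[0], maps[-1]))), maps)
                    if best is None or key < best[0]:
                        best = (key, p)
        if best is None:      # centers in disconnected pieces: leave as is
            break
        for x in best[1]:
            result.add(product.atoms[x].map_num)
            idx_local.add(x)
        comps = _components(idx_local)
    return result


def extract_generic_template(rxn: MappedReaction,
                             cfg: ExtractionConfig | None = None
                             ) -> GenericTemplate:
    """Extract the generic retro template of one mapped reaction.

    Spectators are removed first; the reaction center is read off the CGR;
    the radical and charge-transfer special cases switch on H-count /
    charge specification for center atoms; disjoint centers within one
    product molecule are bridged by the shortest connecting path.
    """
    cfg = cfg or ExtractionConfig()
    core = remove_spectators(rxn)
    centers = find_reaction_center(core)

    radical = detect_radical_case(core, centers)
    charge_transfer = detect_charge_transfer(core, centers)

    if cfg.bridge_disjoint:
        for pm in core.products:
            centers = connect_disjoint_centers(pm, centers)

    pmaps = core.product_map_nums()
    rmaps = core.reactant_map_nums()
    missing = {m for m in centers if m in pmaps and m not in rmaps}
    if missing:
        raise TemplateExtractionError(
            f"record {rxn.source_id!r}: product center atoms "
            f"{sorted(missing)} have no reactant-side counterpart")

    def _mk_atom(a, mapped: bool) -> AtomPattern:
        return AtomPattern(
            atomic_num=_PERIODIC.GetAtomicNumber(a.element),
            map_num=a.map_num if mapped else None,
            h_count=a.explicit_h if (mapped and radical) else None,
            charge=(a.formal_charge if (mapped and charge_transfer)
                    else (a.formal_charge if not mapped and a.formal_charge
                          else None)),
        )

    # product side: induced subgraph on center atoms
    prod = PatternGraph()
    for pm in core.products:
        sel = [i for i, a in enumerate(pm.atoms) if a.map_num in centers]
        remap = {}
        for i in sel:
            remap[i] = prod.add_atom(_mk_atom(pm.atoms[i], mapped=True))
        for b in pm.bonds:
            if b.i in remap and b.j in remap:
                prod.add_bond(remap[b.i], remap[b.j], b.order)

    # reactant side: center atoms plus adjacent leaving-group components
    react = PatternGraph()
    for rm in core.reactants:
        present = [i for i, a in enumerate(rm.atoms)
                   if a.map_num is not None and a.map_num in pmaps]
        kept = {i for i in present if rm.atoms[i].map_num in centers}
        absent = [i for i in range(len(rm.atoms)) if i not in set(present)
                  and rm.atoms[i].element != "H"]
        if absent:
            sub = nx.Graph()
            sub.add_nodes_from(absent)
            sub.add_edges_from((b.i, b.j) for b in rm.bonds
                               if b.i in set(absent) and b.j in set(absent))
            for comp in nx.connected_components(sub):
                touches_center = any(
                    n in kept
                    for x in comp for n, _ in rm.neighbors(x))
                if touches_center:
                    kept |= set(comp)
        if not kept:
            continue
        sel = sorted(kept)
        remap = {}
        for i in sel:
            a = rm.atoms[i]
            mapped = a.map_num is not None and a.map_num in pmaps
            remap[i] = react.add_atom(_mk_atom(a, mapped=mapped))
        for b in rm.bonds:
            if b.i in remap and b.j in remap:
                react.add_bond(remap[b.i], remap[b.j], b.order)

    return make_generic_template(prod, react, example_ids=[rxn.source_id])


# ---------------------------------------------------------------------------
# reduction of a detailed (RDChiral-style) template
# ---------------------------------------------------------------------------

_H_RE = re.compile(r"^H(\d*)$")
_CHG_RE = re.compile(r"^([+-])(\d*)$")


def _parse_smarts_side(text: str):
    """Parse one side of a detailed template into atom records and bonds."""
    mol = Chem.MolFromSmarts(text)
    if mol is None:
        raise RxncureError(f"unparsable SMARTS {text!r}")
    atoms = []
    for a in mol.GetAtoms():
        token = a.GetSmarts()
        h = charge = None
        body = token[1:-1] if token.startswith("[") else token
        body = body.split(":")[0]
        for piece in body.replace(";", "&").split("&"):
            m = _H_RE.match(piece)
            if m:
                h = int(m.group(1) or 1)
                continue
            m = _CHG_RE.match(piece)
            if m and not piece[1:].isalpha():
                charge = int(m.group(1) + (m.group(2) or "1"))
        atoms.append({"anum": a.GetAtomicNum(),
                      "map": a.GetAtomMapNum() or None,
                      "h": h, "charge": charge,
                      "aromatic": a.GetIsAromatic()})
    bonds = []
    for b in mol.GetBonds():
        sym = b.GetSmarts()
        if sym in _SYMBOL_BOND:
            order = _SYMBOL_BOND[sym]
        elif b.GetBondType() in (Chem.BondType.AROMATIC,):
            order = AROMATIC
        elif b.GetBondType() == Chem.BondType.DOUBLE:
            order = DOUBLE
        elif b.GetBondType() == Chem.BondType.TRIPLE:
            order = TRIPLE
        elif (atoms[b.GetBeginAtomIdx()]["aromatic"]
              and atoms[b.GetEndAtomIdx()]["aromatic"]):
            order = AROMATIC
        else:
            order = SINGLE
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return atoms, bonds


def reduce_detailed_template(smarts: str,
                             cfg: ExtractionConfig | None = None
                             ) -> GenericTemplate:
    """Reduce a detailed retro template (RDChiral dialect, product>>reactants)
    to its generic form.

    Center atoms are those whose bonding (including bonds to unmapped
    leaving-group atoms), specified H count, or specified charge differ
    between the two sides; every other mapped atom is environment and is
    dropped, and all atom-level constraints except element and map number
    are discarded.
    """
    cfg = cfg or ExtractionConfig()
    left, right = smarts.split(">>")
    p_atoms, p_bonds = _parse_smarts_side(left)
    r_atoms, r_bonds = _parse_smarts_side(right)

    def _env(atoms, bonds):
        env: dict[int, dict] = {}
        for idx, a in enumerate(atoms):
            if a["map"] is not None:
                env[a["map"]] = {"bonds": {}, "unmapped": 0,
                                 "h": a["h"], "charge": a["charge"]}
        for i, j, order in bonds:
            mi, mj = atoms[i]["map"], atoms[j]["map"]
            if mi is not None and mj is not None:
                env[mi]["bonds"][mj] = order
                env[mj]["bonds"][mi] = order
            elif mi is not None:
                env[mi]["unmapped"] += 1
            elif mj is not None:
                env[mj]["unmapped"] += 1
        return env

    p_env, r_env = _env(p_atoms, p_bonds), _env(r_atoms, r_bonds)
    centers: set[int] = set()
    for m in set(p_env) | set(r_env):
        pe, re_ = p_env.get(m), r_env.get(m)
        if pe is None or re_ is None:
            centers.add(m)
            continue
        if pe["bonds"] != re_["bonds"] or pe["unmapped"] != re_["unmapped"]:
            centers.add(m)
        elif (pe["h"] is not None and re_["h"] is not None
              and pe["h"] != re_["h"]):
            centers.add(m)
        elif (pe["charge"] is not None and re_["charge"] is not None
              and pe["charge"] != re_["charge"]):
            centers.add(m)

    if not centers:
        raise NullTransformationError("template encodes no transformation")

    if cfg.bridge_disjoint:
        # bridge within the product (left) side using a molecule-graph view
        mg = MoleculeGraph()
        for a in p_atoms:
            mg.add_atom(_pattern_atom_node(a))
        for i, j, order in p_bonds:
            mg.add_bond(i, j, order)
        centers = connect_disjoint_centers(mg, centers)

    prod = PatternGraph()
    remap = {}
    for idx, a in enumerate(p_atoms):
        if a["map"] in centers:
            remap[idx] = prod.add_atom(AtomPattern(a["anum"], a["map"]))
    for i, j, order in p_bonds:
        if i in remap and j in remap:
            prod.add_bond(remap[i], remap[j], order)

    react = PatternGraph()
    rmap = {}
    kept_mapped = {idx for idx, a in enumerate(r_atoms) if a["map"] in centers}
    unmapped = [idx for idx, a in enumerate(r_atoms) if a["map"] is None]
    keep_unmapped: set[int] = set()
    if unmapped:
        sub = nx.Graph()
        sub.add_nodes_from(unmapped)
        sub.add_edges_from((i, j) for i, j, _ in r_bonds
                           if i in set(unmapped) and j in set(unmapped))
        adj: dict[int, set[int]] = {i: set() for i in range(len(r_atoms))}
        for i, j, _ in r_bonds:
            adj[i].add(j)
            adj[j].add(i)
        for comp in nx.connected_components(sub):
            if any(n in kept_mapped for x in comp for n in adj[x]):
                keep_unmapped |= set(comp)
    for idx in sorted(kept_mapped | keep_unmapped):
        a = r_atoms[idx]
        mapped = a["map"] in centers
        charge = a["charge"] if (not mapped and a["charge"]) else None
        rmap[idx] = react.add_atom(AtomPattern(
            a["anum"], a["map"] if mapped else None, charge=charge))
    for i, j, order in r_bonds:
        if i in rmap and j in rmap:
            react.add_bond(rmap[i], rmap[j], order)

    return make_generic_template(prod, react)


def _pattern_atom_node(a: dict):
    from .graphs import AtomNode
    return AtomNode(element=_PERIODIC.GetElementSymbol(a["anum"]),
                    map_num=a["map"], aromatic=a["aromatic"])


# ---------------------------------------------------------------------------
# library: merging, filtering, serialization
# ---------------------------------------------------------------------------

@dataclass
class TemplateLibrary:
    """Canonicalized, frequency-filtered template set."""

    templates: list[GenericTemplate] = field(default_factory=list)
    min_frequency: int = 0

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.templates:
                fh.write(json.dumps({
                    "template": t.smarts,
                    "frequency": t.frequency,
                    "bond_changes": t.bond_changes,
                    "example_ids": t.example_ids,
                }) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "TemplateLibrary":
        templates = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                t = parse_template_smarts(rec["template"])
                t.frequency = rec.get("frequency", 1)
                t.example_ids = rec.get("example_ids", [])
                templates.append(t)
        return cls(templates=_sorted_templates(templates))


def parse_template_smarts(text: str) -> GenericTemplate:
    """Parse a generic template written in the atomic-number SMARTS dialect."""
    left, right = text.split(">>")

    def _side(s: str) -> PatternGraph:
        atoms, bonds = _parse_smarts_side(s)
        pg = PatternGraph()
        for a in atoms:
            pg.add_atom(AtomPattern(a["anum"], a["map"], h_count=a["h"],
                                    charge=a["charge"]))
        for i, j, order in bonds:
            pg.add_bond(i, j, order)
        return pg

    return make_generic_template(_side(left), _side(right))


def _sorted_templates(ts: list[GenericTemplate]) -> list[GenericTemplate]:
    return sorted(ts, key=lambda t: (-t.frequency, t.smarts))


def merge_isomorphic_templates(ts: list[GenericTemplate]) -> TemplateLibrary:
    """Merge templates whose product-side and reactant-side pattern graphs
    are both isomorphic (map numbering ignored).

    The representative is the member with the fewest bond changes (principle
    of minimum chemical distance); ties break on the lexicographically
    smallest canonical SMARTS, so merging is associative and
    order-independent. Frequencies are summed.
    """
    groups: dict[tuple[str, str], list[GenericTemplate]] = {}
    for t in ts:
        groups.setdefault(t.signature, []).append(t)
    merged = []
    for members in groups.values():
        rep = min(members, key=lambda t: (t.bond_changes, t.smarts))
        total = sum(t.frequency for t in members)
        ids: list[str] = []
        for t in sorted(members, key=lambda t: (t.bond_changes, t.smarts)):
            for eid in t.example_ids:
                if eid not in ids:
                    ids.append(eid)
        merged.append(replace(rep, frequency=total, example_ids=ids[:10]))
    return TemplateLibrary(templates=_sorted_templates(merged),
                           min_frequency=0)


def filter_rare_templates(lib: TemplateLibrary,
                          min_frequency: int = 5) -> TemplateLibrary:
    """Retain exactly the templates with frequency > min_frequency
    (default 5: a template seen 5 times or fewer is removed)."""
    kept = [t for t in lib.templates if t.frequency > min_frequency]
    return TemplateLibrary(templates=_sorted_templates(kept),
                           min_frequency=min_frequency)


def extract_template_library(rxns: list[MappedReaction],
                             min_frequency: int = 5,
                             cfg: ExtractionConfig | None = None,
                             dedupe: bool = True):
    """Extract, merge and frequency-filter templates for a reaction list.

    Duplicate reactions (identical mapping-agnostic canonical reaction
    keys) count once toward template frequency. Returns
    ``(library, per_record_errors)`` where the second element maps record
    ids to the reason extraction was skipped.
    """
    seen: set[str] = set()
    raw: list[GenericTemplate] = []
    errors: dict[str, str] = {}
    for rxn in rxns:
        if dedupe:
            try:
                key = reaction_key(rxn)
            except Exception as exc:    # unserializable molecule
                errors[rxn.source_id] = f"canonicalization failed: {exc}"
                continue
            if key in seen:
                continue
            seen.add(key)
        try:
            raw.append(extract_generic_template(rxn, cfg))
        except RxncureError as exc:
            errors[rxn.source_id] = str(exc)
    lib = merge_isomorphic_templates(raw) if raw else TemplateLibrary()
    return filter_rare_templates(lib, min_frequency), errors
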