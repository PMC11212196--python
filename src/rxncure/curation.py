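"""Template-guided reaction curation.

Each reaction's products are rewritten retro-synthetically with every
library template, in descending order of template frequency. A candidate
reactant set is accepted when the original reactants form a subset of it
(mapping- and stereo-agnostic multiset comparison); the first accepting
template wins, the candidate replaces the original reactants (restoring
missing reactants and rewriting atom maps consistently), stereochemistry is
transferred back from the original molecules, and the record is marked
validated or repaired. Records no template accepts are removed.

Hydrogen completion: template-written atoms have underspecified hydrogen
counts; every valence-consistent assignment is enumerated from the valence
table (e.g. a neutral one-bond sulfur acquires either one or five
hydrogens), except where the template explicitly specifies the count.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem
from rdkit.rdBase import BlockLogs

from .errors import EmptyCoreError, ValenceLookupError
from .graphs import (AROMATIC, AtomNode, CHI_NONE, MoleculeGraph,
                     canonical_key, multiset_key)
from .reactions import (MappedReaction, build_cgr, cgr_equal,
                        remove_spectators, reinstate_spectators)
from .templates import GenericTemplate, TemplateLibrary

_PERIODIC = Chem.GetPeriodicTable()


class ValenceTable:
    """Allowed bond-order sums per (element, formal charge).

    Defaults cover the organic set (B 3; C 4; N 3, N+ 4; O 2, O- 1; halogens
    1; P 3 or 5; S 2 or 6; Si 4). Lookups for unknown element/charge pairs
    fail loudly.
    """

    DEFAULTS: dict[tuple[str, int], tuple[int, ...]] = {
        ("H", 0): (1,),
        ("B", 0): (3,),
        ("C", 0): (4,),
        ("N", 0): (3,), ("N", 1): (4,), ("N", -1): (2,),
        ("O", 0): (2,), ("O", -1): (1,), ("O", 1): (3,),
        ("F", 0): (1,), ("F", -1): (0,),
        ("Cl", 0): (1,), ("Cl", -1): (0,),
        ("Br", 0): (1,), ("Br", -1): (0,),
        ("I", 0): (1,), ("I", -1): (0,),
        ("P", 0): (3, 5),
        ("S", 0): (2, 6), ("S", -1): (1,),
        ("Si", 0): (4,),
    }

    def __init__(self, overrides: dict[tuple[str, int], tuple[int, ...]] | None = None):
        self.table = dict(self.DEFAULTS)
        if overrides:
            self.table.update(overrides)

    def valences(self, element: str, charge: int = 0) -> tuple[int, ...]:
        try:
            return self.table[(element, charge)]
        except KeyError:
            raise ValenceLookupError(
                f"no valence entry for element {element!r} with charge {charge}")


def allowed_h_counts(atom: AtomNode, bond_order_sum: float,
                     vt: ValenceTable) -> list[int]:
    """Valence-consistent hydrogen counts for an atom with the given
    heavy-bond order sum (aromatic bonds count 1.5, the total is floored)."""
    consumed = math.floor(bond_order_sum) + atom.radical_electrons
    out = []
    for v in vt.valences(atom.element, atom.formal_charge):
        h = v - consumed
        if h >= 0:
            out.append(h)
    return sorted(set(out))


def complete_hydrogens(fragment: MoleculeGraph, vt: ValenceTable,
                       unspecified: set[int] | None = None,
                       h_specs: dict[int, int] | None = None,
                       max_variants: int = 32) -> list[MoleculeGraph]:
    """Enumerate every valence-consistent hydrogen assignment of a fragment.

    ``unspecified`` marks the atoms whose H counts are unknown (default:
    all); ``h_specs`` gives template-specified counts used verbatim.
    Returns the list of completed variants (empty when no assignment is
    valid), ordered by ascending H counts.
    """
    h_specs = h_specs or {}
    if unspecified is None:
        unspecified = set(range(len(fragment.atoms))) - set(h_specs)
    choices: list[list[tuple[int, int]]] = []
    for idx in sorted(unspecified):
        atom = fragment.atoms[idx]
        if atom.element == "H":
            continue
        opts = allowed_h_counts(atom, fragment.bond_order_sum(idx), vt)
        if not opts:
            return []
        choices.append([(idx, h) for h in opts])
    for idx, h in h_specs.items():
        fragment.atoms[idx].explicit_h = h
    variants = []
    for combo in itertools.product(*choices):
        g = fragment.copy()
        for idx, h in combo:
            g.atoms[idx].explicit_h = h
        variants.append(g)
        if len(variants) >= max_variants:
            break
    return variants


def _sanitizes(mol: MoleculeGraph) -> bool:
    try:
        with BlockLogs():
            mol.to_rdkit(sanitize=True)
        return True
    except Exception:
        return False


# ---------------------------------------------------------------------------
# retro template application
# ---------------------------------------------------------------------------

def _products_networkx(products: list[MoleculeGraph]) -> nx.Graph:
    g = nx.Graph()
    for mi, m in enumerate(products):
        for ai, a in enumerate(m.atoms):
            g.add_node((mi, ai), anum=_PERIODIC.GetAtomicNumber(a.element),
                       h=a.explicit_h, charge=a.formal_charge)
        for b in m.bonds:
            g.add_edge((mi, b.i), (mi, b.j), order=b.order)
    return g


def _pattern_networkx(t: GenericTemplate) -> nx.Graph:
    g = nx.Graph()
    for i, a in enumerate(t.product_pattern.atoms):
        g.add_node(i, anum=a.atomic_num, h=a.h_count, charge=a.charge)
    for i, j, order in t.product_pattern.bonds:
        g.add_edge(i, j, order=order)
    return g


def _node_match(gattrs: dict, pattrs: dict) -> bool:
    if gattrs["anum"] != pattrs["anum"]:
        return False
    if pattrs["h"] is not None and gattrs["h"] != pattrs["h"]:
        return False
    if pattrs["charge"] is not None and gattrs["charge"] != pattrs["charge"]:
        return False
    return True


def _edge_match(gattrs: dict, pattrs: dict) -> bool:
    return gattrs["order"] == pattrs["order"]


def apply_retro_template(t: GenericTemplate, products: list[MoleculeGraph],
                         vt: ValenceTable | None = None,
                         max_embeddings: int = 64,
                         max_variants: int = 32) -> list[list[MoleculeGraph]]:
    """Apply a generic retro template to a product molecule set.

    Every embedding of the product pattern yields candidate reactant
    multisets: matched atoms are rewired per the reactant patterns (with
    leaving-group atoms attached), unmatched product atoms are copied
    through with their maps preserved, and underspecified hydrogen counts
    are enumerated from the valence table. Chemically invalid rewrites
    (valence overflow, unsanitizable fragments) are discarded, not fatal.
    Returns a deterministically ordered, deduplicated candidate list
    (empty when no embedding exists).
    """
    vt = vt or ValenceTable()
    G = _products_networkx(products)
    P = _pattern_networkx(t)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        G, P, node_match=_node_match, edge_match=_edge_match)
    embeddings = []
    seen_embeddings = set()
    for mapping in matcher.subgraph_monomorphisms_iter():
        key = frozenset(mapping.items())
        if key in seen_embeddings:
            continue
        seen_embeddings.add(key)
        embeddings.append({p: g for g, p in mapping.items()})
        if len(embeddings) >= max_embeddings:
            break

    pmap_to_pattern = t.product_pattern.map_to_index()
    react = t.reactant_pattern
    react_map_to_idx = react.map_to_index()

    candidates: list[tuple[tuple, list[MoleculeGraph]]] = []
    seen_keys = set()
    for emb in embeddings:   # emb: pattern product idx -> (mi, ai)
        new = MoleculeGraph()
        node_of: dict[tuple[int, int], int] = {}
        matched: dict[tuple[int, int], int] = {}   # product atom -> pattern idx
        for pidx, gnode in emb.items():
            matched[gnode] = pidx
        # copy all product atoms
        for mi, m in enumerate(products):
            for ai, a in enumerate(m.atoms):
                na = a.copy()
                if (mi, ai) in matched:
                    pat_prod = t.product_pattern.atoms[matched[(mi, ai)]]
                    ridx = react_map_to_idx.get(pat_prod.map_num)
                    rpat = react.atoms[ridx] if ridx is not None else None
                    na.chirality = CHI_NONE
                    if rpat is not None and rpat.charge is not None:
                        na.formal_charge = rpat.charge
                node_of[(mi, ai)] = new.add_atom(na)
        underspecified: set[int] = set()
        h_specs: dict[int, int] = {}
        for gnode, pidx in matched.items():
            pat_prod = t.product_pattern.atoms[pidx]
            ridx = react_map_to_idx.get(pat_prod.map_num)
            rpat = react.atoms[ridx] if ridx is not None else None
            tgt = node_of[gnode]
            if rpat is not None and rpat.h_count is not None:
                h_specs[tgt] = rpat.h_count
            else:
                underspecified.add(tgt)
        # bonds among product atoms
        pat_edge = {}
        for i, j, order in t.product_pattern.bonds:
            pat_edge[frozenset((i, j))] = order
        react_edge_mapped = {}
        for i, j, order in react.bonds:
            mi_, mj_ = react.atoms[i].map_num, react.atoms[j].map_num
            if mi_ is not None and mj_ is not None:
                react_edge_mapped[frozenset((mi_, mj_))] = order
        handled_pairs = set()
        for mi, m in enumerate(products):
            for b in m.bonds:
                u, v = (mi, b.i), (mi, b.j)
                if u in matched and v in matched:
                    pi, pj = matched[u], matched[v]
                    if frozenset((pi, pj)) in pat_edge:
                        # bond is part of the pattern: rewritten below
                        handled_pairs.add(frozenset((u, v)))
                        continue
                new.add_bond(node_of[u], node_of[v], b.order)
        # rewritten bonds among matched atoms, per reactant pattern
        inv_map = {t.product_pattern.atoms[p].map_num: g
                   for g, p in matched.items()}
        for pair, order in react_edge_mapped.items():
            m1, m2 = tuple(pair)
            u, v = inv_map[m1], inv_map[m2]
            existing = new.bond_between(node_of[u], node_of[v])
            if existing is not None:
                existing.order = order
            else:
                new.add_bond(node_of[u], node_of[v], order)
        # leaving-group atoms and their bonds
        leaving_of: dict[int, int] = {}
        for i, a in enumerate(react.atoms):
            if a.map_num is None:
                na = AtomNode(element=_PERIODIC.GetElementSymbol(a.atomic_num),
                              formal_charge=a.charge or 0)
                idx = new.add_atom(na)
                leaving_of[i] = idx
                if a.h_count is not None:
                    h_specs[idx] = a.h_count
                else:
                    underspecified.add(idx)
        for i, j, order in react.bonds:
            ni = leaving_of.get(i)
            nj = leaving_of.get(j)
            if ni is None and nj is None:
                continue
            if ni is None:
                ni = node_of[inv_map[react.atoms[i].map_num]]
            if nj is None:
                nj = node_of[inv_map[react.atoms[j].map_num]]
            if new.bond_between(ni, nj) is None:
                new.add_bond(ni, nj, order)
        # clear aromatic flags on rewritten atoms that left aromatic systems
        for idx in set(underspecified) | set(h_specs):
            a = new.atoms[idx]
            if a.aromatic:
                n_arom = sum(1 for _, b in new.neighbors(idx)
                             if b.order == AROMATIC)
                if n_arom < 2:
                    a.aromatic = False
        # hydrogen completion per fragment, then recombine
        frag_variants: list[list[MoleculeGraph]] = []
        ok = True
        for frag, indices in new.split_fragments():
            local = {indices.index(i) for i in underspecified if i in indices}
            specs = {indices.index(i): h for i, h in h_specs.items()
                     if i in indices}
            variants = complete_hydrogens(frag, vt, unspecified=local,
                                          h_specs=specs,
                                          max_variants=max_variants)
            variants = [v for v in variants if _sanitizes(v)]
            if not variants:
                ok = False
                break
            frag_variants.append(variants)
        if not ok:
            continue
        count = 1
        for fv in frag_variants:
            count *= len(fv)
        if count > max_variants:
            count = max_variants
        for n, combo in enumerate(itertools.product(*frag_variants)):
            if n >= max_variants:
                break
            cand = [g.copy() for g in combo]
            try:
                key = multiset_key(cand, ignore_maps=False)
            except Exception:
                continue
            if key in seen_keys:
                continue
            seen_keys.add(key)
            sort_key = (multiset_key(cand, ignore_maps=True,
                                     ignore_stereo=True), key)
            candidates.append((sort_key, cand))
    candidates.sort(key=lambda t: t[0])
    return [c for _, c in candidates]


# ---------------------------------------------------------------------------
# subset test and stereochemistry transfer
# ---------------------------------------------------------------------------

def is_reactant_subset(original: list[MoleculeGraph],
                       candidate: list[MoleculeGraph]) -> bool:
    """True iff the multiset of mapping- and stereo-agnostic canonical keys
    of `original` is contained in that of `candidate`."""
    from collections import Counter
    orig = Counter(canonical_key(m, ignore_maps=True, ignore_stereo=True)
                   for m in original)
    cand = Counter(canonical_key(m, ignore_maps=True, ignore_stereo=True)
                   for m in candidate)
    return all(cand[k] >= v for k, v in orig.items())


def _exact_correspondence(a: MoleculeGraph, b: MoleculeGraph) -> dict | None:
    """One-to-one atom correspondence between two stereo-agnostically
    identical molecules (exact graph matching on element/charge/H labels)."""
    ga, gb = a.to_networkx(), b.to_networkx()
    nm = nx.algorithms.isomorphism.categorical_node_match(
        ["element", "charge", "explicit_h"], [None, 0, 0])
    em = nx.algorithms.isomorphism.categorical_edge_match("order", 1.0)
    gm = nx.algorithms.isomorphism.GraphMatcher(ga, gb, node_match=nm,
                                                edge_match=em)
    for mapping in gm.isomorphisms_iter():
        return mapping          # first match; VF2 order is deterministic
    return None


def reattach_stereochemistry(original: list[MoleculeGraph],
                             curated: list[MoleculeGraph]
                             ) -> tuple[list[MoleculeGraph], list[str]]:
    """Transfer chirality and bond stereo from original reactants onto the
    corresponding curated molecules.

    A curated molecule that matches an original one (stereo- and
    map-agnostically) is replaced by a copy of the original carrying the
    curated map numbers, so every stereocenter and double-bond stereo tag
    survives exactly; newly added fragments stay stereo-free. Returns the
    new list plus warning notes for molecules where no exact correspondence
    was found. The transfer is idempotent.
    """
    remaining = list(range(len(original)))
    out: list[MoleculeGraph] = []
    notes: list[str] = []
    for cm in curated:
        ck = canonical_key(cm, ignore_maps=True, ignore_stereo=True)
        chosen = None
        for ri in remaining:
            if canonical_key(original[ri], ignore_maps=True,
                             ignore_stereo=True) == ck:
                chosen = ri
                break
        if chosen is None:
            out.append(cm)
            continue
        om = original[chosen]
        corr = _exact_correspondence(om, cm)
        if corr is None:
            out.append(cm)
            notes.append("no exact correspondence; stereo left off")
            continue
        remaining.remove(chosen)
        repl = om.copy()
        for oi, ci in corr.items():
            repl.atoms[oi].map_num = cm.atoms[ci].map_num
        out.append(repl)
    return out, notes


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

@dataclass
class CurationConfig:
    """Settings for template-guided curation."""

    add_byproducts: bool = False
    reinstate_spectators: bool = False
    max_embeddings: int = 64
    max_variants: int = 32


@dataclass
class CurationOutcome:
    """Per-reaction curation verdict."""

    record_id: str
    status: str                              # validated | repaired | removed
    matched_template: GenericTemplate | None = None
    curated_reaction: MappedReaction | None = None
    added_fragments: list[MoleculeGraph] = field(default_factory=list)
    mapping_changed: bool = False
    notes: str = ""


def _fresh_maps(mols: list[MoleculeGraph], start: int) -> None:
    nxt = start
    for m in mols:
        for a in m.atoms:
            if a.map_num is None and a.element != "H":
                a.map_num = nxt
                nxt += 1


def curate_reaction(rxn: MappedReaction, lib: TemplateLibrary,
                    vt: ValenceTable | None = None,
                    cfg: CurationConfig | None = None) -> CurationOutcome:
    """Validate, repair or remove one reaction using the template library.

    Templates are tried in descending frequency (ties by canonical SMARTS);
    among passing candidates of the winning template, the one adding the
    fewest heavy atoms is preferred (minimal repair). The curated reaction
    replaces the reactants with the accepted candidate — stereochemistry
    reattached, added fragments given fresh map numbers — and is marked
    repaired when fragments were added or the CGR changed, else validated.
    """
    vt = vt or ValenceTable()
    cfg = cfg or CurationConfig()
    try:
        core = remove_spectators(rxn)
    except EmptyCoreError as exc:
        return CurationOutcome(rxn.source_id, "removed", notes=str(exc))

    chosen = None
    chosen_template = None
    for t in lib:
        passing = []
        for cand in apply_retro_template(t, core.products, vt,
                                         max_embeddings=cfg.max_embeddings,
                                         max_variants=cfg.max_variants):
            if is_reactant_subset(core.reactants, cand):
                added = (sum(m.heavy_atom_count() for m in cand)
                         - sum(m.heavy_atom_count() for m in core.reactants))
                passing.append((added,
                                multiset_key(cand, ignore_maps=True,
                                             ignore_stereo=True), cand))
        if passing:
            passing.sort(key=lambda x: x[:2])
            chosen = passing[0][2]
            chosen_template = t
            break
    if chosen is None:
        return CurationOutcome(rxn.source_id, "removed",
                               notes="no template matched")

    reactants, notes = reattach_stereochemistry(core.reactants, chosen)
    max_map = 0
    for side in (reactants, core.products):
        for m in side:
            for a in m.atoms:
                if a.map_num:
                    max_map = max(max_map, a.map_num)
    _fresh_maps(reactants, max_map + 1)

    curated = MappedReaction(reactants=reactants,
                             products=[m.copy() for m in core.products],
                             spectators=[m.copy() for m in core.spectators],
                             source_id=rxn.source_id)
    if cfg.add_byproducts:
        curated = add_byproducts(curated)
    if cfg.reinstate_spectators:
        curated = reinstate_spectators(curated)

    mapping_changed = not cgr_equal(build_cgr(core), build_cgr(curated))

    from collections import Counter
    orig_keys = Counter(canonical_key(m, ignore_maps=True, ignore_stereo=True)
                        for m in core.reactants)
    added_fragments = []
    for m in reactants:
        k = canonical_key(m, ignore_maps=True, ignore_stereo=True)
        if orig_keys[k] > 0:
            orig_keys[k] -= 1
        else:
            added_fragments.append(m)

    status = ("repaired" if (added_fragments or mapping_changed)
              else "validated")
    return CurationOutcome(rxn.source_id, status,
                           matched_template=chosen_template,
                           curated_reaction=curated,
                           added_fragments=added_fragments,
                           mapping_changed=mapping_changed,
                           notes="; ".join(notes))


def add_byproducts(rxn: MappedReaction) -> MappedReaction:
    """Balance a curated reaction by appending electroneutral by-products.

    Reactant atoms absent from the product side are grouped into
    leaving-group fragments; each severed bond is capped with the matching
    number of hydrogens; neutral, sanitizable fragments are appended to the
    products so heavy atoms balance exactly. Fragments that cannot be
    neutralized by hydrogen addition alone are left out (noted in the
    returned reaction's products being short; callers may warn).
    """
    out = rxn.copy()
    pmaps = out.product_map_nums()
    for m in out.reactants:
        absent = [i for i, a in enumerate(m.atoms)
                  if a.element != "H"
                  and (a.map_num is None or a.map_num not in pmaps)]
        if not absent:
            continue
        absent_set = set(absent)
        sub = nx.Graph()
        sub.add_nodes_from(absent)
        sub.add_edges_from((b.i, b.j) for b in m.bonds
                           if b.i in absent_set and b.j in absent_set)
        for comp in nx.connected_components(sub):
            indices = sorted(comp)
            frag = m.subgraph(indices)
            # cap severed bonds with hydrogens
            for local, orig in enumerate(indices):
                severed = sum(int(round(b.order))
                              for n, b in m.neighbors(orig)
                              if n not in absent_set)
                frag.atoms[local].explicit_h += severed
                frag.atoms[local].map_num = None
            if sum(a.formal_charge for a in frag.atoms) != 0:
                continue
            if not _sanitizes(frag):
                continue
            out.products.append(frag)
    return out
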