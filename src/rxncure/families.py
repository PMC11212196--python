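"""Synthetic single-step reaction families for benchmarking.

Each family emulates one laboratory transformation (carbonyl arylation,
Williamson ether synthesis, reductive amination, amide coupling,
Diels-Alder cycloaddition) over pools of substituents, with controllable
leaving-group diversity so the competing-template effect can be exercised.
Reactions are built product-first: every product heavy atom receives a map
number, and the reactants are derived by an explicit hand-coded retro edit
with the atom correspondence tracked by construction — so the mapping is
correct by construction and independent of the template machinery under
test. Leaving-group atoms are unmapped, as an atom-mapping tool would
leave them.
"""
from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from rdkit import Chem

from .curation import ValenceTable
from .errors import GenerationError
from .graphs import AtomNode, DOUBLE, MoleculeGraph, SINGLE
from .reactions import MappedReaction

_VT = ValenceTable()

ALKYL_POOL = ("C", "CC", "CCC", "CCCC", "CC(C)C")
ARYL_POOL = ("c1ccccc1", "c1ccc(C)cc1", "c1ccc(CC)cc1", "c1cccc(C)c1",
             "c1ccc(CCC)cc1", "c1ccc(C(C)C)cc1")
RING_SUB_POOL = ("", "(C)", "(CC)")
SPECTATOR_POOL = ("CCO", "C1CCOC1", "CS(C)=O")


@dataclass
class FamilySpec:
    """Configuration of one reaction family.

    ``leaving_groups`` are element symbols for the leaving atom (or, for
    families without one, ignored); ``leaving_weights`` control the mix so
    one leaving group can dominate, giving its template a higher frequency.
    """

    name: str
    leaving_groups: tuple[str, ...] | None = None
    leaving_weights: tuple[float, ...] | None = None
    spectator_prob: float = 0.0


def _mol_from_smiles(smiles: str) -> MoleculeGraph:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GenerationError(f"invalid generated SMILES {smiles!r}")
    return MoleculeGraph.from_rdkit(mol)


def _anchor(smiles: str, smarts: str) -> tuple[MoleculeGraph, tuple[int, ...]]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GenerationError(f"invalid generated SMILES {smiles!r}")
    match = mol.GetSubstructMatch(Chem.MolFromSmarts(smarts))
    if not match:
        raise GenerationError(
            f"anchor {smarts!r} not found in generated product {smiles!r}")
    return MoleculeGraph.from_rdkit(mol), match


def _recompute_h(g: MoleculeGraph, idx: int) -> None:
    """Set the lowest valence-consistent hydrogen count after a bond edit."""
    a = g.atoms[idx]
    consumed = math.floor(g.bond_order_sum(idx)) + a.radical_electrons
    for v in _VT.valences(a.element, a.formal_charge):
        if v - consumed >= 0:
            a.explicit_h = v - consumed
            return
    raise GenerationError(
        f"no valid valence for {a.element} with {consumed} bonds")


def _assign_maps(g: MoleculeGraph) -> None:
    nxt = 1
    for a in g.atoms:
        if a.element != "H":
            a.map_num = nxt
            nxt += 1


def _pick_leaving(spec: FamilySpec, rng: random.Random,
                  default: tuple[str, ...]) -> str:
    groups = spec.leaving_groups or default
    weights = spec.leaving_weights or [1.0] * len(groups)
    return rng.choices(list(groups), weights=list(weights), k=1)[0]


def _finish(product: MoleculeGraph, reactant_graph: MoleculeGraph,
            spec: FamilySpec, rng: random.Random) -> MappedReaction:
    reactants = [frag for frag, _ in reactant_graph.split_fragments()]
    rxn = MappedReaction(reactants=reactants, products=[product])
    if spec.spectator_prob and rng.random() < spec.spectator_prob:
        rxn.reactants.append(_mol_from_smiles(rng.choice(SPECTATOR_POOL)))
    for side in (rxn.reactants, rxn.products):
        for m in side:
            try:
                m.to_rdkit(sanitize=True)
            except Exception as exc:
                raise GenerationError(f"invalid generated molecule: {exc}")
    return rxn


def _carbonyl_arylation(spec: FamilySpec, rng: random.Random) -> MappedReaction:
    """Aryl halide + aldehyde -> secondary benzylic alcohol (Grignard-like)."""
    alk = rng.choice(ALKYL_POOL)
    aryl = rng.choice(ARYL_POOL)
    product, (o, c, ipso) = _anchor(f"O[CH]({alk}){aryl}", "[OX2H1]-[CX4H1]-c")
    _assign_maps(product)
    r = product.copy()
    r.bond_between(o, c).order = DOUBLE
    r.remove_bond(c, ipso)
    x = r.add_atom(AtomNode(_pick_leaving(spec, rng, ("Br",))))
    r.add_bond(ipso, x, SINGLE)
    for idx in (o, c, ipso, x):
        _recompute_h(r, idx)
    return _finish(product, r, spec, rng)


def _ether_synthesis(spec: FamilySpec, rng: random.Random) -> MappedReaction:
    """Phenol + alkyl halide -> aryl alkyl ether (Williamson)."""
    alk = rng.choice(ALKYL_POOL)
    aryl = rng.choice(ARYL_POOL)
    product, (ipso, o, ch2) = _anchor(f"{aryl}OC{alk}", "c-[OX2]-[CX4H2]")
    _assign_maps(product)
    r = product.copy()
    r.remove_bond(o, ch2)
    x = r.add_atom(AtomNode(_pick_leaving(spec, rng, ("Br",))))
    r.add_bond(ch2, x, SINGLE)
    for idx in (o, ch2, x):
        _recompute_h(r, idx)
    return _finish(product, r, spec, rng)


def _reductive_amination(spec: FamilySpec, rng: random.Random) -> MappedReaction:
    """Aldehyde + arylamine -> secondary amine; the carbonyl oxygen leaves."""
    alk = rng.choice(ALKYL_POOL)
    aryl = rng.choice(ARYL_POOL)
    product, (ch2, n, _) = _anchor(f"{alk}CN{aryl}", "[CX4H2]-[NX3H1]-c")
    _assign_maps(product)
    r = product.copy()
    r.remove_bond(ch2, n)
    o = r.add_atom(AtomNode("O"))
    r.add_bond(ch2, o, DOUBLE)
    for idx in (ch2, n, o):
        _recompute_h(r, idx)
    return _finish(product, r, spec, rng)


def _amide_coupling(spec: FamilySpec, rng: random.Random) -> MappedReaction:
    """Carboxylic acid (or acyl chloride) + arylamine -> anilide."""
    alk = rng.choice(ALKYL_POOL)
    aryl = rng.choice(ARYL_POOL)
    product, (c, _odbl, n, _) = _anchor(f"{alk}C(=O)N{aryl}",
                                        "[CX3](=[OX1])-[NX3H1]-c")
    _assign_maps(product)
    r = product.copy()
    r.remove_bond(c, n)
    x = r.add_atom(AtomNode(_pick_leaving(spec, rng, ("O",))))
    r.add_bond(c, x, SINGLE)
    for idx in (c, n, x):
        _recompute_h(r, idx)
    return _finish(product, r, spec, rng)


def _diels_alder(spec: FamilySpec, rng: random.Random) -> MappedReaction:
    """Diene + dienophile -> substituted cyclohexene; no leaving group."""
    subs = [rng.choice(RING_SUB_POOL) for _ in range(5)]
    smiles = (f"C1=C{subs[0]}C{subs[1]}C{subs[2]}C{subs[3]}C1{subs[4]}")
    product, match = _anchor(
        smiles, "[CX3]1=[CX3]-[CX4]-[CX4]-[CX4]-[CX4]1")
    d2, d3, d4, e1, e2, d1 = match
    _assign_maps(product)
    r = product.copy()
    r.bond_between(d1, d2).order = DOUBLE
    r.bond_between(d2, d3).order = SINGLE
    r.bond_between(d3, d4).order = DOUBLE
    r.remove_bond(d4, e1)
    r.bond_between(e1, e2).order = DOUBLE
    r.remove_bond(e2, d1)
    for idx in (d1, d2, d3, d4, e1, e2):
        _recompute_h(r, idx)
    return _finish(product, r, spec, rng)


FAMILY_BUILDERS = {
    "carbonyl_arylation": _carbonyl_arylation,
    "ether_synthesis": _ether_synthesis,
    "reductive_amination": _reductive_amination,
    "amide_coupling": _amide_coupling,
    "diels_alder": _diels_alder,
}

#: families with a unique leaving group each — one template per family
UNIQUE_LG_FAMILIES = (
    FamilySpec("carbonyl_arylation", leaving_groups=("Br",)),
    FamilySpec("reductive_amination"),
    FamilySpec("diels_alder"),
)

#: the same transformations with two competing leaving groups per family
#: (the minority group's records get repaired with the majority group,
#: depressing exact missing-reactant recovery)
COMPETING_LG_FAMILIES = (
    FamilySpec("carbonyl_arylation", leaving_groups=("Br", "F"),
               leaving_weights=(0.65, 0.35)),
    FamilySpec("ether_synthesis", leaving_groups=("Br", "Cl"),
               leaving_weights=(0.65, 0.35)),
    FamilySpec("amide_coupling", leaving_groups=("O", "Cl"),
               leaving_weights=(0.65, 0.35)),
)


def generate_fixture_dataset(families: list[FamilySpec] | tuple,
                             n_per_family: int,
                             seed: int = 0) -> list[MappedReaction]:
    """Generate correctly mapped single-step reactions for each family.

    Identical seeds produce byte-identical datasets. Each family yields one
    generic template per leaving group when extracted.
    """
    rng = random.Random(seed)
    out: list[MappedReaction] = []
    for spec in families:
        try:
            builder = FAMILY_BUILDERS[spec.name]
        except KeyError:
            raise GenerationError(f"unknown family {spec.name!r}")
        for i in range(n_per_family):
            rxn = builder(spec, rng)
            rxn.source_id = f"{spec.name}-{i:04d}"
            out.append(rxn)
    return out
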