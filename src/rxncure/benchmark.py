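"""Noise injection and curation scoring.

Three error types emulate the defects found in mined reaction datasets:
removal of one reactant molecule, a small structural modification of the
product (adding a C or O atom, or substituting a C by O or N), and the
transposition of two atom-map numbers in the product. A configured fraction
of records receives exactly one error; ground-truth labels retain the
pristine reaction so curation success can be scored exactly:

* missing-reactant success — curated reactant multiset equals the pristine
  one (mapping-agnostic);
* structural-error detection — the modified record was removed;
* map-curation success — the curated CGR equals the pristine CGR;
* residual proportion — fraction of records surviving curation.
"""
from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from itertools import combinations

from .errors import RxncureError
from .graphs import AROMATIC, AtomNode, MoleculeGraph, SINGLE, multiset_key
from .reactions import (MappedReaction, build_cgr, cgr_equal,
                        remove_spectators)
from .curation import CurationOutcome

ERROR_TYPES = ("missing_reactant", "structural_mod", "map_swap")


@dataclass
class NoiseConfig:
    """Noise-injection settings.

    ``noise_ratio`` is the corrupted fraction (the study conditions use
    0.09, 0.15, 0.30, 0.45 and 0.60); ``type_probs`` the distribution over
    the three error types (default uniform); each corrupted record gets
    exactly one error.
    """

    noise_ratio: float = 0.15
    type_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.noise_ratio <= 1.0:
            raise ValueError("noise_ratio must be in [0, 1]")
        if len(self.type_probs) != 3 or abs(sum(self.type_probs) - 1) > 1e-9:
            raise ValueError("type_probs must be 3 probabilities summing to 1")


@dataclass
class GroundTruthLabel:
    """Per-record ground truth for scoring."""

    record_id: str
    error_type: str                    # one of ERROR_TYPES or "clean"
    pristine_reaction: MappedReaction


# ---------------------------------------------------------------------------
# corruption operators
# ---------------------------------------------------------------------------

def _corrupt_missing_reactant(rxn: MappedReaction,
                              rng: random.Random) -> MappedReaction | None:
    if len(rxn.reactants) < 2:
        return None
    out = rxn.copy()
    out.reactants.pop(rng.randrange(len(out.reactants)))
    return out


def _structural_edit_sites(mol: MoleculeGraph, edit: str) -> list[int]:
    sites = []
    for i, a in enumerate(mol.atoms):
        if a.element == "H":
            continue
        if edit in ("add_C", "add_O"):
            if a.explicit_h >= 1:
                sites.append(i)
        elif edit == "sub_C_to_O":
            if (a.element == "C" and not a.aromatic and a.formal_charge == 0
                    and a.radical_electrons == 0 and a.chirality == "none"
                    and math.floor(mol.bond_order_sum(i)) <= 2):
                sites.append(i)
        elif edit == "sub_C_to_N":
            if (a.element == "C" and not a.aromatic and a.formal_charge == 0
                    and a.radical_electrons == 0 and a.chirality == "none"
                    and math.floor(mol.bond_order_sum(i)) <= 3):
                sites.append(i)
    return sites


def _corrupt_structural(rxn: MappedReaction,
                        rng: random.Random) -> MappedReaction | None:
    out = rxn.copy()
    mi = rng.randrange(len(out.products))
    mol = out.products[mi]
    edits = ["add_C", "add_O", "sub_C_to_O", "sub_C_to_N"]
    rng.shuffle(edits)
    chosen = None
    for edit in [edits[rng.randrange(len(edits))]] + edits:
        sites = _structural_edit_sites(mol, edit)
        if sites:
            chosen = (edit, sites[rng.randrange(len(sites))])
            break
    if chosen is None:
        return None
    edit, site = chosen
    a = mol.atoms[site]
    if edit == "add_C":
        a.explicit_h -= 1
        idx = mol.add_atom(AtomNode("C", explicit_h=3))
        mol.add_bond(site, idx, SINGLE)
    elif edit == "add_O":
        a.explicit_h -= 1
        idx = mol.add_atom(AtomNode("O", explicit_h=1))
        mol.add_bond(site, idx, SINGLE)
    elif edit == "sub_C_to_O":
        a.element = "O"
        a.explicit_h = 2 - math.floor(mol.bond_order_sum(site))
    else:
        a.element = "N"
        a.explicit_h = 3 - math.floor(mol.bond_order_sum(site))
    try:
        mol.to_rdkit(sanitize=True)
    except Exception:
        return None
    return out


def _corrupt_map_swap(rxn: MappedReaction,
                      rng: random.Random) -> MappedReaction | None:
    """Transpose the map numbers of two non-equivalent product atoms.

    Only same-element pairs whose transposition changes the CGR are used:
    swapping topologically equivalent atoms is a no-op that would poison
    the labels, and cross-element swaps are structural data errors rather
    than mapping errors.
    """
    pristine_cgr = build_cgr(rxn)
    out = rxn.copy()
    atoms = [(mi, ai)
             for mi, m in enumerate(out.products)
             for ai, a in enumerate(m.atoms)
             if a.map_num is not None and a.element != "H"]
    pairs = [(u, v) for u, v in combinations(atoms, 2)
             if (out.products[u[0]].atoms[u[1]].element
                 == out.products[v[0]].atoms[v[1]].element)]
    rng.shuffle(pairs)
    for (mi, ai), (mj, aj) in pairs:
        a, b = out.products[mi].atoms[ai], out.products[mj].atoms[aj]
        a.map_num, b.map_num = b.map_num, a.map_num
        if not cgr_equal(build_cgr(out), pristine_cgr):
            return out
        a.map_num, b.map_num = b.map_num, a.map_num
    return None


_CORRUPTORS = {
    "missing_reactant": _corrupt_missing_reactant,
    "structural_mod": _corrupt_structural,
    "map_swap": _corrupt_map_swap,
}


def inject_noise(data: list[MappedReaction], cfg: NoiseConfig
                 ) -> tuple[list[MappedReaction], list[GroundTruthLabel]]:
    """Corrupt ``floor(noise_ratio * n)`` records, one error each.

    Records are selected without replacement; the error type is drawn from
    ``type_probs``, falling back to the remaining types when a record
    cannot take the drawn one (e.g. a single-reactant record cannot lose a
    reactant). Identical seeds give byte-identical outputs.
    """
    rng = random.Random(cfg.seed)
    n_corrupt = math.floor(cfg.noise_ratio * len(data))
    chosen = set(rng.sample(range(len(data)), n_corrupt))
    corrupted: list[MappedReaction] = []
    labels: list[GroundTruthLabel] = []
    for i, rxn in enumerate(data):
        if i not in chosen:
            corrupted.append(rxn.copy())
            labels.append(GroundTruthLabel(rxn.source_id, "clean", rxn.copy()))
            continue
        order = rng.choices(range(3), weights=cfg.type_probs, k=1) + \
            rng.sample(range(3), 3)
        applied = None
        for ti in dict.fromkeys(order):
            etype = ERROR_TYPES[ti]
            result = _CORRUPTORS[etype](rxn, rng)
            if result is not None:
                applied = (etype, result)
                break
        if applied is None:
            corrupted.append(rxn.copy())
            labels.append(GroundTruthLabel(rxn.source_id, "clean", rxn.copy()))
            continue
        etype, result = applied
        corrupted.append(result)
        labels.append(GroundTruthLabel(rxn.source_id, etype, rxn.copy()))
    return corrupted, labels


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Curation success rates, in percent."""

    success_missing_reactants: float | None
    success_structural_detection: float | None
    success_map_curation: float | None
    residual_proportion: float
    per_type_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "success_missing_reactants": self.success_missing_reactants,
            "success_structural_detection": self.success_structural_detection,
            "success_map_curation": self.success_map_curation,
            "residual_proportion": self.residual_proportion,
            "per_type_counts": self.per_type_counts,
        }


def _core_reactant_key(rxn: MappedReaction):
    try:
        core = remove_spectators(rxn)
    except RxncureError:
        core = rxn
    return multiset_key(core.reactants, ignore_maps=True, ignore_stereo=True)


def evaluate_curation(outcomes: list[CurationOutcome],
                      labels: list[GroundTruthLabel]) -> EvaluationReport:
    """Score curation outcomes against ground truth.

    Raises on unmatched record ids. Rates are None when no record of that
    error type exists.
    """
    by_id = {o.record_id: o for o in outcomes}
    missing_ids = [l.record_id for l in labels if l.record_id not in by_id]
    if missing_ids or len(outcomes) != len(labels):
        raise RxncureError(
            f"outcome/label mismatch (unmatched ids: {missing_ids[:5]})")

    counts = {t: {"total": 0, "success": 0}
              for t in ERROR_TYPES + ("clean",)}
    survivors = 0
    for label in labels:
        out = by_id[label.record_id]
        if out.status != "removed":
            survivors += 1
        c = counts[label.error_type]
        c["total"] += 1
        if label.error_type == "missing_reactant":
            if (out.status != "removed"
                    and _core_reactant_key(out.curated_reaction)
                    == _core_reactant_key(label.pristine_reaction)):
                c["success"] += 1
        elif label.error_type == "structural_mod":
            if out.status == "removed":
                c["success"] += 1
        elif label.error_type == "map_swap":
            if out.status != "removed" and cgr_equal(
                    build_cgr(out.curated_reaction),
                    build_cgr(remove_spectators(label.pristine_reaction))):
                c["success"] += 1
        else:                                   # clean records survive
            if out.status != "removed":
                c["success"] += 1

    def _rate(t):
        n = counts[t]["total"]
        return None if n == 0 else 100.0 * counts[t]["success"] / n

    return EvaluationReport(
        success_missing_reactants=_rate("missing_reactant"),
        success_structural_detection=_rate("structural_mod"),
        success_map_curation=_rate("map_swap"),
        residual_proportion=100.0 * survivors / len(labels),
        per_type_counts=counts,
    )
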