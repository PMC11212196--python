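"""Template extraction, reduction, canonicalization and filtering."""
import random
import re

import pytest
from hypothesis import given, settings, strategies as st

from rxncure import (count_bond_changes, extract_generic_template,
                     extract_template_library, filter_rare_templates,
                     find_reaction_center, merge_isomorphic_templates,
                     parse_reaction, parse_template_smarts,
                     reduce_detailed_template)
from rxncure.errors import NullTransformationError
from rxncure.templates import (TemplateLibrary, connect_disjoint_centers,
                               detect_charge_transfer, detect_radical_case)
from tests.conftest import GRIGNARD_DETAILED, GRIGNARD_GENERIC

DA_SMILES = ("[CH2:1]=[CH:2][CH:3]=[CH2:4].[CH2:5]=[CH2:6]"
             ">>[CH2:1]1[CH:2]=[CH:3][CH2:4][CH2:5][CH2:6]1")
DA_BAD_SMILES = ("[CH2:1]=[CH:2][CH:3]=[CH2:4].[CH2:5]=[CH2:6]"
                 ">>[CH2:1]1[CH:2]=[CH:3][CH2:5][CH2:4][CH2:6]1")


class TestReactionCenter:
    def test_identity_reaction_is_null_transformation(self):
        rxn = parse_reaction("[CH3:1][OH:2]>>[CH3:1][OH:2]")
        with pytest.raises(NullTransformationError):
            find_reaction_center(rxn)

    def test_hydrogenation_centers_are_both_carbons(self):
        rxn = parse_reaction("[CH2:1]=[CH2:2].[H][H]>>[CH3:1][CH3:2]")
        assert find_reaction_center(rxn) == {1, 2}

    def test_grignard_centers(self, grignard_rxn):
        # halide-bearing carbon, carbonyl carbon, carbonyl oxygen
        assert find_reaction_center(grignard_rxn) == {1, 7, 8}


class TestSpecialCases:
    def test_closed_shell_reaction_is_not_radical(self, grignard_rxn):
        assert detect_radical_case(grignard_rxn) is False

    def test_radical_reaction_detected_and_h_specified(self):
        rxn = parse_reaction("[CH4:1].[Cl:2]>>[CH3:1].[Cl:2][H]")
        assert detect_radical_case(rxn) is True
        t = extract_generic_template(rxn)
        assert t.smarts == "[#17;H1:1].[#6;H3:2]>>[#17;H0:1].[#6;H4:2]"

    def test_radical_flag_matches_exhaustive_scan(self):
        rxn = parse_reaction("[CH4:1].[Cl:2]>>[CH3:1].[Cl:2][H]")
        centers = find_reaction_center(rxn)
        brute = any(
            a.radical_electrons > 0
            for side in (rxn.reactants, rxn.products)
            for m in side for a in m.atoms if a.map_num in centers)
        assert detect_radical_case(rxn) is brute

    def test_neutral_reaction_is_not_charge_transfer(self, grignard_rxn):
        assert detect_charge_transfer(grignard_rxn) is False

    def test_protonation_keeps_charges_in_template(self):
        rxn = parse_reaction("[CH3:1][NH2:2].Br>>[CH3:1][NH3+:2].[Br-]")
        assert detect_charge_transfer(rxn) is True
        t = extract_generic_template(rxn)
        assert t.smarts == "[#7;+1:1]>>[#7;+0:1]"

    def test_charge_flag_agrees_with_cgr_deltas(self):
        from rxncure import build_cgr
        rxn = parse_reaction("[CH3:1][NH2:2].Br>>[CH3:1][NH3+:2].[Br-]")
        cgr = build_cgr(rxn)
        brute = any(d["charge_delta"] != 0 and d["map_num"] is not None
                    for _, d in cgr.graph.nodes(data=True))
        assert detect_charge_transfer(rxn) is brute


class TestBridging:
    def test_connected_centers_returned_unchanged(self, grignard_rxn):
        prod = grignard_rxn.products[0]
        assert connect_disjoint_centers(prod, {1, 7, 8}) == {1, 7, 8}

    def test_ring_opening_bridges_through_shortest_path(self):
        rxn = parse_reaction(
            "[CH2:1]1[CH2:2][CH2:3][CH2:4][CH2:5]1.BrBr"
            ">>Br[CH2:1][CH2:2][CH2:3][CH2:4][CH2:5]Br")
        prod = rxn.products[0]
        assert connect_disjoint_centers(prod, {1, 5}) == {1, 2, 3, 4, 5}
        t = extract_generic_template(rxn)
        assert set(re.findall(r":(\d)", t.smarts.split(">>")[0])) == \
            {"1", "2", "3", "4", "5"}

    def test_bridge_matches_exhaustive_path_enumeration(self):
        import itertools
        import networkx as nx
        rxn = parse_reaction(
            "[CH2:1]1[CH2:2][CH2:3][CH2:4][CH2:5]1.BrBr"
            ">>Br[CH2:1][CH2:2][CH2:3][CH2:4][CH2:5]Br")
        prod = rxn.products[0]
        g = nx.Graph((b.i, b.j) for b in prod.bonds)
        m2i = {a.map_num: i for i, a in enumerate(prod.atoms) if a.map_num}
        shortest = min(
            (p for p in nx.all_simple_paths(g, m2i[1], m2i[5])), key=len)
        expected = {1, 5} | {prod.atoms[i].map_num for i in shortest}
        assert connect_disjoint_centers(prod, {1, 5}) == expected

    def test_centers_in_different_molecules_unchanged(self):
        rxn = parse_reaction("[CH4:1].[OH2:2]>>[CH3:1]O.[OH:2]C")
        prod0 = rxn.products[0]
        assert connect_disjoint_centers(prod0, {1, 2}) == {1, 2}


class TestReduction:
    def test_printed_grignard_reduces_exactly(self):
        t = reduce_detailed_template(GRIGNARD_DETAILED)
        assert t.smarts == GRIGNARD_GENERIC

    def test_reduction_agrees_with_extraction(self, grignard_rxn):
        assert (extract_generic_template(grignard_rxn).smarts
                == reduce_detailed_template(GRIGNARD_DETAILED).smarts)

    def test_generic_templates_carry_no_query_decorations(self,
                                                          unique_lg_library):
        # aromatic atom primitives, degree, chirality and cis/trans
        # constraints never appear in generic templates
        for t in unique_lg_library:
            for forbidden in ("D", "@", "/", "\\", "c", "n", "o", "s"):
                assert forbidden not in t.smarts


class TestBondChanges:
    def test_grignard_template_has_three_changes(self):
        t = reduce_detailed_template(GRIGNARD_DETAILED)
        assert count_bond_changes(t) == 3

    def test_diels_alder_has_six_changes(self):
        t = extract_generic_template(parse_reaction(DA_SMILES))
        assert count_bond_changes(t) == 6
        assert t.bond_changes == 6


class TestMerging:
    def test_map_error_variant_is_discarded(self):
        good = extract_generic_template(parse_reaction(DA_SMILES))
        bad = extract_generic_template(parse_reaction(DA_BAD_SMILES))
        assert good.signature == bad.signature
        assert bad.bond_changes > good.bond_changes
        lib = merge_isomorphic_templates([bad, good])
        assert len(lib) == 1
        assert lib.templates[0].bond_changes == good.bond_changes
        assert lib.templates[0].frequency == 2

    def test_singleton_input_unchanged(self, grignard_rxn):
        t = extract_generic_template(grignard_rxn)
        lib = merge_isomorphic_templates([t])
        assert len(lib) == 1 and lib.templates[0].frequency == 1

    def test_merge_is_order_independent(self, unique_lg_dataset):
        ts = [extract_generic_template(r) for r in unique_lg_dataset[:60]]
        a = merge_isomorphic_templates(ts)
        shuffled = ts[:]
        random.Random(4).shuffle(shuffled)
        b = merge_isomorphic_templates(shuffled)
        assert ([(t.smarts, t.frequency) for t in a]
                == [(t.smarts, t.frequency) for t in b])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.permutations(range(40)), st.integers(0, 8))
    def test_merge_then_filter_invariants_hold_for_any_order(
            self, unique_lg_dataset, perm, threshold):
        """For any presentation order and threshold: merging is
        order-independent, frequency mass is conserved, and filtering keeps
        exactly the templates above threshold."""
        ts = [extract_generic_template(unique_lg_dataset[i]) for i in perm]
        lib = merge_isomorphic_templates(ts)
        assert sum(t.frequency for t in lib) == len(ts)
        kept = filter_rare_templates(lib, threshold)
        assert {t.smarts for t in kept} == {
            t.smarts for t in lib if t.frequency > threshold}
        assert all(t.frequency > threshold for t in kept)

    def test_representative_minimizes_bond_changes(self):
        good = extract_generic_template(parse_reaction(DA_SMILES))
        bad = extract_generic_template(parse_reaction(DA_BAD_SMILES))
        lib = merge_isomorphic_templates([bad, bad, good])
        assert all(lib.templates[0].bond_changes <= t.bond_changes
                   for t in (good, bad))


class TestFiltering:
    def test_threshold_five_removes_five_keeps_six(self):
        good = extract_generic_template(parse_reaction(DA_SMILES))
        t5 = merge_isomorphic_templates([good] * 5).templates[0]
        t6 = merge_isomorphic_templates([good] * 6).templates[0]
        assert len(filter_rare_templates(
            TemplateLibrary([t5]), 5).templates) == 0
        assert len(filter_rare_templates(
            TemplateLibrary([t6]), 5).templates) == 1

    def test_zero_threshold_is_identity(self, unique_lg_library):
        out = filter_rare_templates(unique_lg_library, 0)
        assert [t.smarts for t in out] == [t.smarts for t in unique_lg_library]

    def test_frequency_mass_is_conserved(self, unique_lg_dataset):
        ts = [extract_generic_template(r) for r in unique_lg_dataset]
        lib = merge_isomorphic_templates(ts)
        kept = filter_rare_templates(lib, 5)
        removed_mass = sum(t.frequency for t in lib
                           if t.frequency <= 5)
        assert (sum(t.frequency for t in kept) + removed_mass
                == sum(t.frequency for t in lib) == len(ts))


class TestStabilityAndSerialization:
    def test_family_members_share_one_canonical_template(self,
                                                         unique_lg_dataset):
        by_family = {}
        for rxn in unique_lg_dataset:
            fam = rxn.source_id.rsplit("-", 1)[0]
            by_family.setdefault(fam, set()).add(
                extract_generic_template(rxn).smarts)
        assert all(len(s) == 1 for s in by_family.values()), by_family

    def test_jsonl_round_trip(self, unique_lg_library, tmp_path):
        path = tmp_path / "lib.jsonl"
        unique_lg_library.to_jsonl(path)
        again = TemplateLibrary.from_jsonl(path)
        assert ([(t.smarts, t.frequency, t.bond_changes) for t in again]
                == [(t.smarts, t.frequency, t.bond_changes)
                    for t in unique_lg_library])

    def test_smarts_parse_round_trip(self):
        t = parse_template_smarts(GRIGNARD_GENERIC)
        assert t.smarts == GRIGNARD_GENERIC
        assert t.bond_changes == 3
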