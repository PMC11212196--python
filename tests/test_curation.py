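"""Retro template application, hydrogen completion, subset test,
stereochemistry transfer, curation verdicts and by-product balancing."""
from collections import Counter

import pytest
from rdkit import Chem

from rxncure import (apply_retro_template, build_cgr, canonical_key,
                     cgr_equal, complete_hydrogens, curate_reaction,
                     add_byproducts, is_reactant_subset, parse_reaction,
                     reattach_stereochemistry)
from rxncure.curation import allowed_h_counts
from rxncure.errors import ValenceLookupError
from rxncure.graphs import AtomNode, MoleculeGraph, SINGLE
from rxncure.templates import parse_template_smarts


def graph(smiles):
    return MoleculeGraph.from_rdkit(Chem.MolFromSmiles(smiles))


class TestHydrogenCompletion:
    def test_neutral_one_bond_sulfur_gets_one_or_five(self, vt):
        g = MoleculeGraph()
        s = g.add_atom(AtomNode("S"))
        c = g.add_atom(AtomNode("C", explicit_h=3))
        g.add_bond(s, c, SINGLE)
        variants = complete_hydrogens(g, vt, unspecified={s})
        assert [v.atoms[s].explicit_h for v in variants] == [1, 5]

    def test_saturated_carbon_has_single_zero_h_variant(self, vt):
        g = graph("C(C)(C)(C)C")
        center = next(i for i, a in enumerate(g.atoms)
                      if g.degree(i) == 4)
        variants = complete_hydrogens(g, vt, unspecified={center})
        assert len(variants) == 1
        assert variants[0].atoms[center].explicit_h == 0

    def test_enumeration_equals_valence_arithmetic(self, vt):
        # brute force over the valence table entries minus the bond sum
        for elem, bonds in [("S", 1), ("P", 1), ("N", 2), ("O", 1)]:
            a = AtomNode(elem)
            expected = sorted({v - bonds for v in vt.valences(elem, 0)
                               if v - bonds >= 0})
            assert allowed_h_counts(a, bonds, vt) == expected

    def test_template_specified_count_is_verbatim(self, vt):
        g = MoleculeGraph()
        s = g.add_atom(AtomNode("S"))
        c = g.add_atom(AtomNode("C", explicit_h=3))
        g.add_bond(s, c, SINGLE)
        variants = complete_hydrogens(g, vt, unspecified=set(),
                                      h_specs={s: 1})
        assert len(variants) == 1 and variants[0].atoms[s].explicit_h == 1

    def test_unknown_element_fails_loudly(self, vt):
        with pytest.raises(ValenceLookupError):
            vt.valences("Xx", 0)


class TestTemplateApplication:
    def test_grignard_regenerates_aryl_bromide_and_aldehyde(
            self, grignard_rxn, grignard_library, vt):
        t = grignard_library.templates[0]
        cands = apply_retro_template(t, grignard_rxn.products, vt)
        keys = [sorted(canonical_key(m) for m in c) for c in cands]
        assert sorted(["CC=O", "Brc1ccccc1"]) in keys

    def test_absent_pattern_gives_empty_list(self, grignard_library, vt):
        t = grignard_library.templates[0]
        assert apply_retro_template(t, [graph("CCCC")], vt) == []

    def test_candidate_count_matches_embedding_count_on_symmetric_substrate(
            self, vt):
        # C-O bond cleavage pattern on a symmetric diether: two distinct
        # embeddings per C-O bond, but symmetric ones collapse
        t = parse_template_smarts("[#8:1]-[#6:2]>>[#8:1].Br-[#6:2]")
        prod = graph("COC")   # two equivalent C-O bonds
        cands = apply_retro_template(t, [prod], vt)
        # embeddings: (O,C_left) and (O,C_right) -> identical candidates
        assert len(cands) == 1
        prod2 = graph("COCC")  # now the two C-O bonds differ
        assert len(apply_retro_template(t, [prod2], vt)) == 2

    def test_valence_overflow_candidates_are_discarded(self, vt):
        # forcing a double bond onto an aryl ether oxygen is invalid
        t = parse_template_smarts("[#6:1]-[#6:2]-[#8:3]>>Br-[#6:1].[#6:2]=[#8:3]")
        cands = apply_retro_template(t, [graph("c1ccccc1OCC")], vt)
        for cand in cands:
            for m in cand:
                m.to_rdkit(sanitize=True)   # every candidate sanitizes


class TestReactantSubset:
    def test_missing_amine_case(self):
        orig = [graph("CC=O")]
        cand = [graph("CC=O"), graph("Nc1ccccc1")]
        assert is_reactant_subset(orig, cand)

    def test_reflexive(self, grignard_rxn):
        assert is_reactant_subset(grignard_rxn.reactants,
                                  grignard_rxn.reactants)

    def test_extra_original_molecule_fails(self):
        orig = [graph("CC=O"), graph("CCO")]
        cand = [graph("CC=O"), graph("Nc1ccccc1")]
        assert not is_reactant_subset(orig, cand)

    def test_multiset_semantics(self):
        orig = [graph("O"), graph("O")]
        assert not is_reactant_subset(orig, [graph("O")])
        assert is_reactant_subset(orig, [graph("O"), graph("O")])

    def test_subset_monotonic_under_candidate_growth(self):
        orig = [graph("CC=O")]
        cand = [graph("CC=O")]
        bigger = cand + [graph("CCN")]
        assert is_reactant_subset(orig, cand)
        assert is_reactant_subset(orig, bigger)


class TestStereoReattachment:
    def test_chirality_transfers_to_identical_skeleton(self):
        orig = [graph("C[C@H](N)C(=O)O")]
        curated = [graph("CC(N)C(=O)O")]
        out, notes = reattach_stereochemistry(orig, curated)
        assert not notes
        assert canonical_key(out[0]) == canonical_key(orig[0])
        assert "@" in out[0].to_smiles(ignore_maps=True)

    def test_added_fragment_stays_stereo_free(self):
        orig = [graph("CC=O")]
        curated = [graph("CC=O"), graph("OP(O)OC")]   # new phosphite-like
        out, _ = reattach_stereochemistry(orig, curated)
        assert "@" not in out[1].to_smiles()

    def test_transfer_is_idempotent(self):
        orig = [graph("C[C@H](N)C(=O)O"), graph("C/C=C/C")]
        curated = [graph("CC(N)C(=O)O"), graph("CC=CC")]
        once, _ = reattach_stereochemistry(orig, curated)
        twice, _ = reattach_stereochemistry(orig, once)
        assert ([m.to_smiles() for m in once]
                == [m.to_smiles() for m in twice])

    def test_map_numbers_follow_the_curated_molecule(self):
        orig = [graph("C[C@H](N)C(=O)O")]
        curated = [parse_reaction("C[CH:3]([NH2:4])C(=O)O>>C").reactants[0]]
        out, _ = reattach_stereochemistry(orig, curated)
        assert out[0].map_nums() == {3, 4}


class TestCuration:
    def test_correct_reaction_is_validated(self, grignard_rxn,
                                           grignard_library, vt):
        out = curate_reaction(grignard_rxn, grignard_library, vt)
        assert out.status == "validated"
        assert not out.mapping_changed and not out.added_fragments

    def test_missing_reactant_is_restored(self, grignard_library, vt):
        rxn = parse_reaction(
            "Br[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1"
            ">>[OH:8][CH:7]([CH3:9])[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1")
        out = curate_reaction(rxn, grignard_library, vt)
        assert out.status == "repaired"
        assert [canonical_key(m) for m in out.added_fragments] == ["CC=O"]

    def test_map_swap_is_corrected(self, grignard_rxn, grignard_library, vt):
        swapped = parse_reaction(
            "Br[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1.[O:8]=[CH:7][CH3:9]"
            ">>[OH:8][CH:9]([CH3:7])[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1")
        out = curate_reaction(swapped, grignard_library, vt)
        assert out.status == "repaired" and out.mapping_changed
        assert cgr_equal(build_cgr(out.curated_reaction),
                         build_cgr(grignard_rxn))

    def test_element_mismatch_reaction_is_removed(self, grignard_library, vt):
        # C in the product where the reactants have O at the mapped position
        rxn = parse_reaction(
            "Br[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1.[O:8]=[CH:7][CH3:9]"
            ">>[CH3:8][CH:7]([CH3:9])[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1")
        out = curate_reaction(rxn, grignard_library, vt)
        assert out.status == "removed"
        assert out.curated_reaction is None

    def test_curation_is_idempotent(self, grignard_library, vt):
        rxn = parse_reaction(
            "Br[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1"
            ">>[OH:8][CH:7]([CH3:9])[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1")
        first = curate_reaction(rxn, grignard_library, vt)
        second = curate_reaction(first.curated_reaction, grignard_library, vt)
        assert second.status == "validated"
        assert not second.mapping_changed and not second.added_fragments

    def test_soundness_never_removes_family_members(self, unique_lg_dataset,
                                                    unique_lg_library, vt):
        for rxn in unique_lg_dataset[::7]:
            out = curate_reaction(rxn, unique_lg_library, vt)
            assert out.status != "removed", rxn.source_id

    def test_every_mapped_product_atom_has_same_element_preimage(
            self, unique_lg_dataset, unique_lg_library, vt):
        for rxn in unique_lg_dataset[::13]:
            out = curate_reaction(rxn, unique_lg_library, vt)
            cur = out.curated_reaction
            relem = {a.map_num: a.element for m in cur.reactants
                     for a in m.atoms if a.map_num}
            for m in cur.products:
                for a in m.atoms:
                    if a.map_num and a.element != "H":
                        assert relem.get(a.map_num) == a.element


class TestByproducts:
    def test_hbr_is_appended(self, grignard_rxn, grignard_library, vt):
        out = curate_reaction(grignard_rxn, grignard_library, vt)
        balanced = add_byproducts(out.curated_reaction)
        keys = [canonical_key(m) for m in balanced.products]
        assert "Br" in keys          # canonical SMILES of H-Br

    def test_already_balanced_reaction_is_unchanged(self):
        rxn = parse_reaction("[CH3:1][OH:2]>>[CH3:1][O:2](C)")
        out = add_byproducts(rxn)
        assert len(out.products) == len(rxn.products)

    def test_heavy_atoms_balance_after_addition(self, unique_lg_dataset,
                                                unique_lg_library, vt):
        for rxn in unique_lg_dataset[::11]:
            out = curate_reaction(rxn, unique_lg_library, vt)
            balanced = add_byproducts(out.curated_reaction)
            left, right = Counter(), Counter()
            for m in balanced.reactants:
                left += m.element_counter()
            for m in balanced.products:
                right += m.element_counter()
            assert left == right, rxn.source_id
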