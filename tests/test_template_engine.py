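"""Changed-atom detection, template extraction, application, correction."""

import re
from dataclasses import replace

import pytest
from rdkit import Chem

from retrofict.errors import NoReactionError
from retrofict.reaction_model import Molecule, parse_reaction, strip_maps
from retrofict.template_engine import (
    apply_forward,
    apply_retro,
    correct_templates,
    detect_changed_atoms,
    extract_template,
    match_products,
    template_hash,
)

ESTER = "[CH3:1][C:2](=[O:3])[OH:4].[CH3:5][OH:6]>>[CH3:1][C:2](=[O:3])[O:6][CH3:5]"
AMIDE = "[C:1](=[O:2])[OH:3].[NH2:4][CH3:5]>>[C:1](=[O:2])[NH:4][CH3:5]"


def brute_force_changed(rxn):
    """Independent per-map comparison of sorted bond lists, charge, H."""

    def atom_table(mols):
        table = {}
        for mol in mols:
            for a in mol.GetAtoms():
                if not a.GetAtomMapNum():
                    continue
                bonds = sorted(
                    (
                        n.GetAtomMapNum(),
                        str(
                            mol.GetBondBetweenAtoms(
                                a.GetIdx(), n.GetIdx()
                            ).GetBondType()
                        ),
                    )
                    for n in a.GetNeighbors()
                )
                table[a.GetAtomMapNum()] = (
                    bonds,
                    a.GetFormalCharge(),
                    a.GetTotalNumHs(),
                )
        return table

    left = atom_table([m.to_mol() for m in rxn.starting_materials])
    right = atom_table([rxn.product.to_mol()])
    r_changed, p_changed = set(), set()
    for mn in set(left) | set(right):
        if mn not in right:
            r_changed.add(mn)
        elif mn not in left:
            p_changed.add(mn)
        elif left[mn] != right[mn]:
            r_changed.add(mn)
            p_changed.add(mn)
    return r_changed, p_changed


class TestDetectChangedAtoms:
    @pytest.mark.parametrize(
        "line, want_r, want_p",
        [
            (ESTER, {2, 4, 6}, {2, 6}),
            (AMIDE, {1, 3, 4}, {1, 4}),
        ],
    )
    def test_hand_examples(self, line, want_r, want_p):
        rxn = parse_reaction(line)
        changed = detect_changed_atoms(rxn)
        assert set(changed.reactant_side) == want_r
        assert set(changed.product_side) == want_p

    def test_agrees_with_brute_force_on_fixtures(self, toy_pairs):
        for rxn, _ in toy_pairs:
            changed = detect_changed_atoms(rxn)
            want_r, want_p = brute_force_changed(rxn)
            assert set(changed.reactant_side) == want_r
            assert set(changed.product_side) == want_p

    def test_identity_reaction_has_empty_change_set(self):
        rxn = parse_reaction(
            "[CH3:1][OH:2].[CH3:3][CH3:4]>>[CH3:1][OH:2]"
        )
        changed = detect_changed_atoms(rxn)
        assert not changed.product_side
        with pytest.raises(NoReactionError):
            extract_template(rxn, "r0")


class TestExtractTemplate:
    def test_r0_ester_self_consistency(self):
        rxn = parse_reaction(ESTER)
        t = extract_template(rxn, "r0")
        assert t.n_tags == 2
        sets = apply_retro(t, strip_maps(rxn.product))
        assert rxn.sm_plain_set() in [
            tuple(sorted(m.plain for m in s)) for s in sets
        ]

    def test_r1_pattern_includes_first_shell(self):
        rxn = parse_reaction(ESTER)
        t0 = extract_template(rxn, "r0")
        t1 = extract_template(rxn, "r1")
        # r1 mentions the carbonyl oxygen and alkyl carbons beyond r0
        assert len(re.findall(r"\[", t1.product_pattern)) > len(
            re.findall(r"\[", t0.product_pattern)
        )
        assert "#8;A;D1" in t1.product_pattern  # the carbonyl oxygen shell atom

    def test_n_tags_matches_detection(self, toy_pairs):
        for rxn, truth in toy_pairs[::7]:
            for radius in ("r0", "r1"):
                t = extract_template(rxn, radius, verify=False)
                assert t.n_tags == len(truth.changed_product)

    def test_monotone_specificity_r1_matches_imply_r0(self, toy_pairs, pool):
        for rxn, _ in toy_pairs[::17]:
            t0 = extract_template(rxn, "r0", verify=False)
            t1 = extract_template(rxn, "r1", verify=False)
            r1_matches = {m.plain for m in match_products(t1, pool)}
            r0_matches = {m.plain for m in match_products(t0, pool)}
            assert r1_matches <= r0_matches


class TestTemplateHash:
    def test_invariant_to_map_renumbering(self):
        a = parse_reaction(ESTER)
        renumbered = (
            "[CH3:11][C:12](=[O:13])[OH:14].[CH3:15][OH:16]"
            ">>[CH3:11][C:12](=[O:13])[O:16][CH3:15]"
        )
        b = parse_reaction(renumbered)
        for radius in ("r0", "r1"):
            ta = extract_template(a, radius)
            tb = extract_template(b, radius)
            assert ta.hash == tb.hash
            assert ta.product_pattern == tb.product_pattern

    def test_invariant_to_atom_reordering(self):
        a = parse_reaction(ESTER)
        reordered = (
            "[OH:4][C:2]([CH3:1])=[O:3].[OH:6][CH3:5]"
            ">>[CH3:5][O:6][C:2]([CH3:1])=[O:3]"
        )
        b = parse_reaction(reordered)
        assert extract_template(a, "r1").hash == extract_template(b, "r1").hash

    def test_r0_r1_and_families_differ(self):
        ester = parse_reaction(ESTER)
        amide = parse_reaction(AMIDE)
        e0 = extract_template(ester, "r0")
        e1 = extract_template(ester, "r1")
        a0 = extract_template(amide, "r0")
        assert len({e0.hash, e1.hash, a0.hash}) == 3
        assert template_hash(e0) == e0.hash


class TestApplyRetro:
    def test_single_site(self, world):
        t = world.template_for("esterification", "r0")
        sets = apply_retro(t, Molecule.from_smiles("COC(C)=O"))
        assert [tuple(sorted(m.plain for m in s)) for s in sets] == [
            ("CC(=O)O", "CO")
        ]

    def test_diester_has_two_sites(self, world):
        t = world.template_for("esterification", "r0")
        # asymmetric diester: each ester site yields a distinct SM-set
        sets = apply_retro(t, Molecule.from_smiles("CCOC(=O)CC(=O)OC"))
        assert len(sets) == 2

    def test_symmetric_sites_deduplicated(self, world):
        t = world.template_for("esterification", "r0")
        sets = apply_retro(t, Molecule.from_smiles("COC(=O)CCC(=O)OC"))
        assert len(sets) == 1

    def test_non_matching_molecule_empty(self, world):
        t = world.template_for("esterification", "r0")
        assert apply_retro(t, Molecule.from_smiles("c1ccccc1")) == []

    def test_output_is_map_annotated(self, world):
        t = world.template_for("esterification", "r0")
        (sm_set,) = apply_retro(t, Molecule.from_smiles("COC(C)=O"))
        maps = set().union(*(m.maps for m in sm_set))
        assert maps >= t.changed_reactant_maps


class TestApplyForward:
    def test_roundtrip(self, world):
        t = world.template_for("esterification", "r0")
        sm = [Molecule.from_smiles("CC(=O)O"), Molecule.from_smiles("CO")]
        assert apply_forward(t, sm).plain == "COC(C)=O"

    def test_order_independent(self, world):
        t = world.template_for("esterification", "r0")
        sm = [Molecule.from_smiles("CO"), Molecule.from_smiles("CC(=O)O")]
        assert apply_forward(t, sm).plain == "COC(C)=O"

    def test_non_matching_sm_none(self, world):
        t = world.template_for("esterification", "r0")
        sm = [Molecule.from_smiles("c1ccccc1"), Molecule.from_smiles("CO")]
        assert apply_forward(t, sm) is None

    def test_retro_then_forward_on_fixtures(self, toy_pairs):
        for rxn, truth in toy_pairs[::11]:
            t = extract_template(rxn, "r1", verify=False)
            for sm_set in apply_retro(t, strip_maps(rxn.product)):
                if tuple(sorted(m.plain for m in sm_set)) == truth.sm_plain:
                    product = apply_forward(t, list(sm_set))
                    assert product is not None
                    assert product.plain == truth.product_plain
                    break
            else:  # pragma: no cover
                pytest.fail(f"recorded SM-set not regenerated: {truth}")


class TestMatchProducts:
    def test_pool_order_preserved(self, world):
        t = world.template_for("esterification", "r0")
        pool = [
            Molecule.from_smiles(s)
            for s in ["CCOC(C)=O", "c1ccccc1", "COC(=O)c1ccccc1"]
        ]
        hits = match_products(t, pool)
        assert [m.plain for m in hits] == ["CCOC(C)=O", "COC(=O)c1ccccc1"]

    def test_empty_pool(self, world):
        t = world.template_for("esterification", "r0")
        assert match_products(t, []) == []


class TestCorrectTemplates:
    def _ester_examples(self):
        lines = [
            ESTER,
            "[CH3:1][CH2:7][C:2](=[O:3])[OH:4].[CH3:5][OH:6]"
            ">>[CH3:1][CH2:7][C:2](=[O:3])[O:6][CH3:5]",
        ]
        return [parse_reaction(s, source_id=str(i)) for i, s in enumerate(lines)]

    def test_generalized_variant_merges(self):
        rxns = self._ester_examples()
        t = extract_template(rxns[0], "r1")
        # a syntactic variant: drop the degree constraint on one shell atom
        looser = replace(
            t,
            template_id="variant",
            product_pattern=t.product_pattern.replace(";D1;+0:4]", ";+0:4]", 1),
            hash="variant-hash",
        )
        merged = correct_templates(
            [t, looser],
            {t.template_id: [rxns[0]], "variant": [rxns[0]]},
        )
        assert len(merged) == 1
        assert merged[0].n_examples == 2
        # representative is the most general pattern (fewest primitives)
        assert merged[0].specificity == looser.specificity

    def test_different_r0_parents_never_compared(self):
        ester = extract_template(parse_reaction(ESTER), "r1")
        amide = extract_template(parse_reaction(AMIDE), "r1")
        merged = correct_templates(
            [ester, amide],
            {ester.template_id: [], amide.template_id: []},
        )
        assert len(merged) == 2

    def test_group_of_one_unchanged(self):
        t = extract_template(parse_reaction(ESTER), "r1")
        assert correct_templates([t], {t.template_id: []}) == [t]

    def test_non_equivalent_same_parent_pass_through(self):
        rxns = self._ester_examples()
        t_methyl = extract_template(rxns[0], "r1")
        t_ethyl = extract_template(rxns[1], "r1")
        assert t_methyl.parent_r0_hash == t_ethyl.parent_r0_hash
        merged = correct_templates(
            [t_methyl, t_ethyl],
            {
                t_methyl.template_id: [rxns[0]],
                t_ethyl.template_id: [rxns[1]],
            },
        )
        assert len(merged) == 2
        # coverage of (template, example) pairs is preserved
        assert sum(t.n_examples for t in merged) == 2
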