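import numpy as np
import pytest
from rdkit import Chem

from hydrolyze.molgraph import parse_molecule
from hydrolyze.templates import (
    UnsupportedConditionError,
    apply_hydrolysis_template,
    assemble_reaction,
    detect_functional_groups,
    enumerate_hydrolysis,
    hydroxylate,
    load_template_catalog,
    protonate,
)


def element_counts(mols):
    out = {}
    for m in mols:
        for el, n in m.element_counts().items():
            out[el] = out.get(el, 0) + n
    return out


def side_charge(mols):
    return sum(m.total_charge for m in mols)


class TestCatalog:
    def test_thirteen_groups(self, catalog):
        assert len(catalog) >= 13
        ids = [t.fg_id for t in catalog]
        for expected in ("carboxylic acid ester", "lactone", "nitrile",
                         "lactam", "imide", "nitrogen–sulfur cleavage",
                         "enamine", "amide", "cyclic carbonate",
                         "aliphatic fluoride", "carbamate", "urea", "epoxide"):
            assert expected in ids

    def test_smarts_compile(self, catalog):
        for t in catalog:
            assert t.pattern() is not None

    def test_urea_three_products(self, catalog):
        urea = next(t for t in catalog if t.fg_id == "urea")
        assert urea.expected_products == 3

    def test_stable_order(self, catalog):
        assert [t.fg_id for t in catalog] == \
            [t.fg_id for t in load_template_catalog()]

    def test_product_count_range(self, catalog):
        assert all(t.expected_products in (1, 2, 3) for t in catalog)


class TestDetection:
    def test_methyl_acetate_single_ester(self):
        matches = detect_functional_groups(parse_molecule("CC(=O)OC"))
        assert len(matches) == 1
        assert matches[0].fg_id == "carboxylic acid ester"

    def test_methane_empty(self):
        assert detect_functional_groups(parse_molecule("C")) == []

    def test_ethyl_cyanoacetate_two_groups(self):
        matches = detect_functional_groups(parse_molecule("N#CCC(=O)OCC"))
        assert sorted(m.fg_id for m in matches) == \
            ["carboxylic acid ester", "nitrile"]

    def test_symmetric_urea_deduplicated(self):
        matches = detect_functional_groups(parse_molecule("CNC(=O)NC"))
        assert len([m for m in matches if m.fg_id == "urea"]) == 1


class TestNeutralProducts:
    @pytest.mark.parametrize("smiles, expected_products", [
        ("CC(=O)OC", {"CC(=O)O", "CO"}),          # ester -> acid + alcohol
        ("CC(N)=O", {"CC(=O)O", "N"}),            # amide -> acid + ammonia
        ("CCF", {"CCO", "F"}),                    # fluoride -> alcohol + HF
    ])
    def test_worked_examples(self, smiles, expected_products):
        mol = parse_molecule(smiles)
        match = detect_functional_groups(mol)[0]
        rxn = apply_hydrolysis_template(mol, match)
        got = {Chem.CanonSmiles(p.smiles) for p in rxn.products}
        assert got == {Chem.CanonSmiles(s) for s in expected_products}

    @pytest.mark.parametrize("smiles, fg, n_products", [
        ("CNC(=O)OC", "carbamate", 3),
        ("NC(N)=O", "urea", 3),
        ("O=C1OCCO1", "cyclic carbonate", 2),
        ("C1CO1", "epoxide", 1),
        ("O=C1CCO1", "lactone", 1),
        ("O=C1CCN1", "lactam", 1),
        ("C=CN(C)C", "enamine", 2),
        ("CS(=O)(=O)NC", "nitrogen–sulfur cleavage", 2),
    ])
    def test_product_counts(self, smiles, fg, n_products):
        mol = parse_molecule(smiles)
        rxns = [r for r in enumerate_hydrolysis(mol, "neutral")
                if r.fg_id == fg]
        assert rxns and len(rxns[0].products) == n_products

    def test_conservation(self):
        for smiles in ("CC(=O)OC", "CC#N", "NC(N)=O", "C1CO1", "C=CN(C)C"):
            mol = parse_molecule(smiles)
            for rxn in enumerate_hydrolysis(mol, "neutral"):
                assert element_counts(rxn.reactants) == \
                    element_counts(rxn.products)


class TestEnumeration:
    def test_nitrile_cascade(self):
        rxns = enumerate_hydrolysis(parse_molecule("CC#N"), "neutral")
        assert len(rxns) == 2
        first = {Chem.CanonSmiles(p.smiles) for p in rxns[0].products}
        second = {Chem.CanonSmiles(p.smiles) for p in rxns[1].products}
        assert first == {"CC(N)=O"}              # nitrile -> acetamide
        assert second == {"CC(=O)O", "N"}        # acetamide -> acid + ammonia

    def test_methane_any_condition(self):
        for cond in ("neutral", "acidic", "basic"):
            assert enumerate_hydrolysis(parse_molecule("C"), cond) == []

    def test_diester_two_reactions(self):
        rxns = enumerate_hydrolysis(parse_molecule("COC(=O)CCC(=O)OC"),
                                    "neutral")
        assert len(rxns) == 2
        assert all(r.fg_id == "carboxylic acid ester" for r in rxns)

    def test_enumeration_is_reproducible(self):
        mol = parse_molecule("N#CCC(=O)OCC")
        a = [r.canonical_key() for r in enumerate_hydrolysis(mol, "neutral")]
        b = [r.canonical_key() for r in enumerate_hydrolysis(mol, "neutral")]
        assert a == b and len(a) == len(set(a))

    def test_non_nitrile_single_reaction_per_match(self):
        for smiles in ("CC(=O)OC", "C1CO1", "NC(N)=O"):
            mol = parse_molecule(smiles)
            n_matches = len(detect_functional_groups(mol))
            assert len(enumerate_hydrolysis(mol, "neutral")) == n_matches


class TestProtonationHydroxylation:
    def test_protonate_ester_on_carbonyl_oxygen(self):
        mol = parse_molecule("CC(=O)OC")
        match = detect_functional_groups(mol)[0]
        p = protonate(mol, match)
        assert p.total_charge == mol.total_charge + 1
        charged = [a for a in p.atoms if a.formal_charge == 1]
        assert len(charged) == 1 and charged[0].element == "O"

    def test_protonate_nitrile_on_nitrogen(self):
        mol = parse_molecule("CC#N")
        match = detect_functional_groups(mol)[0]
        p = protonate(mol, match)
        charged = [a for a in p.atoms if a.formal_charge == 1]
        assert charged[0].element == "N"
        assert p.total_charge == 1

    @pytest.mark.parametrize("smiles", ["CC(=O)OC", "C1CO1", "CC#N"])
    def test_hydroxylate_charge_delta(self, smiles):
        mol = parse_molecule(smiles)
        match = detect_functional_groups(mol)[0]
        h = hydroxylate(mol, match)
        assert h.total_charge == mol.total_charge - 1
        assert h.n_atoms == mol.n_atoms + 2

    def test_unsupported_condition(self):
        mol = parse_molecule("CCF")
        match = detect_functional_groups(mol)[0]
        with pytest.raises(UnsupportedConditionError):
            hydroxylate(mol, match)


class TestConditionSchemes:
    def test_acidic_stoichiometry(self):
        mol = parse_molecule("CC(=O)OC")
        match = detect_functional_groups(mol)[0]
        rxn = assemble_reaction(mol, match, "acidic")
        waters = [m for m in rxn.reactants if m.smiles == "O"]
        assert len(waters) == 2 and rxn.n_water == 2
        assert any(p.smiles == "[OH3+]" for p in rxn.products)
        assert side_charge(rxn.reactants) == 1
        assert side_charge(rxn.products) == 1

    def test_basic_stoichiometry(self):
        mol = parse_molecule("CC(=O)OC")
        match = detect_functional_groups(mol)[0]
        rxn = assemble_reaction(mol, match, "basic")
        assert len([m for m in rxn.reactants if m.smiles == "O"]) == 1
        assert any(p.smiles == "[OH-]" for p in rxn.products)
        assert side_charge(rxn.reactants) == -1
        assert side_charge(rxn.products) == -1

    def test_neutral_products_recovered_in_charged_schemes(self):
        mol = parse_molecule("CC(=O)OC")
        match = detect_functional_groups(mol)[0]
        neutral = {Chem.CanonSmiles(p.smiles) for p in
                   assemble_reaction(mol, match, "neutral").products}
        acidic = {Chem.CanonSmiles(p.smiles) for p in
                  assemble_reaction(mol, match, "acidic").products}
        assert neutral < acidic  # plus hydronium

    def test_atom_maps_total_and_bijective(self):
        mol = parse_molecule("CC#N")
        for cond in ("neutral", "acidic", "basic"):
            for rxn in enumerate_hydrolysis(mol, cond):
                rmaps = sorted(n for m in rxn.reactants
                               for n in m.map_numbers())
                pmaps = sorted(n for m in rxn.products
                               for n in m.map_numbers())
                assert rmaps == pmaps
                assert rmaps == list(range(1, len(rmaps) + 1))


def test_fixture_enumeration_conserves(mixed_fixture_reactions):
    _, reactions = mixed_fixture_reactions
    for rxn in reactions:
        assert element_counts(rxn.reactants) == element_counts(rxn.products)
        assert side_charge(rxn.reactants) == side_charge(rxn.products)
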