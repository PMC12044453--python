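import random

import pytest
from rdkit import Chem

from fragcompare.chem_io import MoleculeRecord
from fragcompare.recap import (
    RECAP_RULES,
    RULE_NAMES,
    _break_bonds,
    find_cleavable_bonds,
    find_cleavage_sites,
    fragment_library,
    recap_decompose,
    recap_smiles,
)
from fragcompare.standardize import check_elements

from conftest import mol

# One hand-built molecule per rule: (smiles, expected rule tags of the
# first-level cleavable bonds, expected leaf fragment SMILES).
RULE_FIXTURES = {
    "amide": ("CC(=O)Nc1ccccc1", ["amide"], {"CC=O", "Nc1ccccc1"}),
    "ester": ("CC(=O)Oc1ccccc1", ["ester"], {"CC=O", "Oc1ccccc1"}),
    "amine": (
        "CCN(CC)Cc1ccccc1",
        ["amine", "amine", "amine"],
        {"CC", "N", "Cc1ccccc1"},
    ),
    "urea": (
        "O=C(Nc1ccccc1)Nc1ccccc1",
        ["urea", "urea"],
        {"C=O", "Nc1ccccc1"},
    ),
    "ether": ("COc1ccccc1", ["ether"], {"C", "Oc1ccccc1"}),
    "olefin": ("C/C=C/C", ["olefin"], {"CC"}),
    "aromatic_N_aliphatic_C": ("Cn1cccc1", ["aromatic_N_aliphatic_C"], {"C", "c1cc[nH]c1"}),
    "lactam_N_aliphatic_C": (
        "O=C1CCCCCN1Cc1ccccc1",
        ["lactam_N_aliphatic_C"],
        {"Cc1ccccc1", "O=C1CCCCCN1"},
    ),
    "aromatic_C_aromatic_C": (
        "c1ccc(-c2ccccc2)cc1",
        ["aromatic_C_aromatic_C"],
        {"c1ccccc1"},
    ),
    "quaternary_N": (
        "C[N+](C)(C)Cc1ccccc1",
        ["quaternary_N"] * 4,
        {"C", "[NH4+]", "Cc1ccccc1"},
    ),
    "sulfonamide": (
        "CN(C)S(=O)(=O)c1ccccc1",
        ["sulfonamide"],
        {"C", "N", "O=[SH](=O)c1ccccc1"},
    ),
}


class TestRuleSet:
    def test_exactly_eleven_rules(self):
        assert len(RECAP_RULES) == 11
        assert set(RULE_NAMES) == {
            "amine", "amide", "ester", "urea", "olefin", "ether",
            "aromatic_N_aliphatic_C", "lactam_N_aliphatic_C",
            "aromatic_C_aromatic_C", "quaternary_N", "sulfonamide",
        }

    @pytest.mark.parametrize("rule_name", sorted(RULE_FIXTURES))
    def test_rule_fixture_bonds(self, rule_name):
        smiles, expected_tags, _ = RULE_FIXTURES[rule_name]
        bonds = find_cleavable_bonds(mol(smiles))
        assert sorted(tag for _, tag in bonds) == sorted(expected_tags)

    @pytest.mark.parametrize("rule_name", sorted(RULE_FIXTURES))
    def test_rule_fixture_leaves(self, rule_name):
        smiles, _, expected_leaves = RULE_FIXTURES[rule_name]
        assert recap_smiles(mol(smiles)) == expected_leaves

    def test_no_ring_bond_ever_cleaved(self, np_like_records, synthetic_like_records):
        for record in (np_like_records + synthetic_like_records)[:100]:
            m = mol(record.raw_smiles)
            for bond_idx, _ in find_cleavable_bonds(m):
                assert not m.GetBondWithIdx(bond_idx).IsInRing()


class TestDecompose:
    def test_benzene_nothing_cleavable(self):
        assert find_cleavable_bonds(mol("c1ccccc1")) == []
        assert recap_smiles(mol("c1ccccc1")) == set()

    def test_cyclohexane_no_fragments(self):
        assert recap_smiles(mol("C1CCCCC1")) == set()

    def test_acetanilide_two_leaves(self):
        leaves = recap_decompose(mol("CC(=O)Nc1ccccc1"))
        assert len(leaves) == 2

    def test_deterministic_across_atom_orderings(self):
        base = mol("CC(=O)Oc1ccc(-c2ccccn2)cc1")
        expected = recap_smiles(base)
        for seed in range(5):
            rng = random.Random(seed)
            order = list(range(base.GetNumAtoms()))
            rng.shuffle(order)
            renumbered = Chem.RenumberAtoms(base, order)
            assert recap_smiles(renumbered) == expected

    @pytest.mark.parametrize(
        "smiles",
        [f[0] for f in RULE_FIXTURES.values()]
        + ["CC(=O)Oc1ccc(-c2ccccn2)cc1", "O=C(OCC1CCOC1)c1ccc(OC)cc1"],
    )
    def test_order_independence_against_sequential_oracle(self, smiles):
        """Applying cleavage sites one at a time in random order must give
        the same leaf multiset as the all-at-once decomposition."""

        def sequential_leaves(m, rng):
            sites = find_cleavage_sites(m)
            if not sites:
                return [Chem.MolToSmiles(m)]
            _, bond_idxs = rng.choice(sites)
            broken = _break_bonds(m, list(bond_idxs))
            out = []
            for piece in Chem.GetMolFrags(broken, asMols=True):
                out.extend(sequential_leaves(piece, rng))
            return out

        m = mol(smiles)
        expected = sorted(Chem.MolToSmiles(x) for x in recap_decompose(m)) or [
            Chem.MolToSmiles(m)
        ]
        for seed in range(6):
            got = sorted(sequential_leaves(Chem.Mol(m), random.Random(seed)))
            assert got == expected

    @pytest.mark.parametrize("smiles", [f[0] for f in RULE_FIXTURES.values()])
    def test_atom_conservation(self, smiles):
        m = mol(smiles)
        leaves = recap_decompose(m)
        assert sum(leaf.GetNumHeavyAtoms() for leaf in leaves) == m.GetNumHeavyAtoms()

    def test_rings_stay_intact(self):
        from rdkit.Chem import rdMolDescriptors

        m = mol("O=C(OCC1CCOC1)c1ccc(OC)cc1")
        leaves = recap_decompose(m)
        assert sum(
            rdMolDescriptors.CalcNumRings(leaf) for leaf in leaves
        ) == rdMolDescriptors.CalcNumRings(m)

    def test_fragments_pass_element_check(self, np_like_records):
        for record in np_like_records[:40]:
            for leaf in recap_decompose(mol(record.raw_smiles)):
                assert check_elements(leaf)

    def test_boundary_rules_attributed(self):
        leaves = recap_decompose(mol("CC(=O)Nc1ccccc1"), return_rules=True)
        assert all(rules == {"amide"} for _, rules in leaves)


class TestFragmentLibrary:
    def standardized(self, smiles, source_id):
        record = MoleculeRecord(source_id=source_id, raw_smiles=smiles)
        return record.standardized(Chem.MolToSmiles(mol(smiles)))

    def test_biphenyl_single_fragment(self):
        records = [self.standardized("c1ccc(-c2ccccc2)cc1", "p1")]
        fragments, stats = fragment_library(records, 1000.0)
        assert len(fragments) == 1
        assert fragments[0].canonical_smiles == "c1ccccc1"
        assert fragments[0].occurrence == 1
        assert fragments[0].parents == {"p1"}
        assert fragments[0].rules_applied == {"aromatic_C_aromatic_C"}

    def test_heavy_parent_skipped(self):
        heavy = "C" * 90  # n-C90 alkane, MW ~1264
        records = [self.standardized(heavy, "big")]
        fragments, stats = fragment_library(records, 1000.0)
        assert fragments == []
        assert stats.n_skipped_mw == 1

    def test_mw_cutoff_strictly_less_than(self):
        heavy = "C" * 90
        fragments, stats = fragment_library(
            [self.standardized(heavy, "big")], mw_cutoff=1e6
        )
        assert stats.n_skipped_mw == 0

    def test_occurrence_counts_parent_once(self):
        # two anisole-like ethers on one parent give the methane fragment
        # at two sites but occurrence 1
        records = [self.standardized("COc1ccc(OC)cc1", "p1")]
        fragments, _ = fragment_library(records, 1000.0)
        methane = next(f for f in fragments if f.canonical_smiles == "C")
        assert methane.occurrence == 1
        assert methane.site_count == 2

    def test_site_multiplicity_switch(self):
        records = [self.standardized("COc1ccc(OC)cc1", "p1")]
        fragments, _ = fragment_library(records, 1000.0, count_sites=True)
        methane = next(f for f in fragments if f.canonical_smiles == "C")
        assert methane.occurrence == 2

    def test_occurrence_aggregates_across_parents(self):
        records = [
            self.standardized("c1ccc(-c2ccccc2)cc1", "p1"),
            self.standardized("COc1ccccc1", "p2"),
            self.standardized("CC(=O)Oc1ccccc1", "p3"),
        ]
        fragments, _ = fragment_library(records, 1000.0)
        by_smiles = {f.canonical_smiles: f for f in fragments}
        # phenol from the ether and the ester parents
        assert by_smiles["Oc1ccccc1"].occurrence == 2
        assert by_smiles["Oc1ccccc1"].parents == {"p2", "p3"}
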