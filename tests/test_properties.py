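import pytest

from fragcompare.properties import (
    RO3_DEFAULTS,
    descriptor_profile,
    filter_ro3,
    library_descriptor_summary,
    ro3_profile,
)
from fragcompare.recap import FragmentRecord

from conftest import mol


class TestRo3Profile:
    def test_benzene_passes(self):
        profile = ro3_profile(mol("c1ccccc1"))
        assert profile.passes
        assert profile.hba == 0
        assert profile.hbd == 0
        assert profile.rb == 0

    def test_c25_alkane_fails_on_weight(self):
        profile = ro3_profile(mol("C" * 25))
        assert profile.mw > 300
        assert not profile.passes

    def test_hbd_boundary(self):
        # cyclic triamine: hbd = hba = 3, TPSA 36, no rotatable bonds
        triamine = ro3_profile(mol("C1NCNCN1"))
        assert triamine.hbd == 3
        assert triamine.passes
        tetraol = ro3_profile(mol("OCC(O)C(O)CO"))
        assert tetraol.hbd == 4
        assert not tetraol.passes

    def test_rotatable_bond_boundary(self):
        hexane = ro3_profile(mol("CCCCCC"))
        assert hexane.rb == 3
        assert hexane.passes
        heptane = ro3_profile(mol("CCCCCCC"))
        assert heptane.rb == 4
        assert heptane.mw <= 300 and heptane.logp <= 3  # fails only on rb
        assert not heptane.passes

    def test_tpsa_boundary(self):
        below = ro3_profile(mol("COCC(O)CO"))  # 2xOH + ether: 49.7
        assert below.tpsa <= 60
        assert below.passes
        glycerol = ro3_profile(mol("OCC(O)CO"))  # 3xOH: 60.69
        assert 60 < glycerol.tpsa < 61
        assert glycerol.hbd == 3 and glycerol.mw <= 300 and glycerol.rb <= 3
        assert not glycerol.passes  # fails only on TPSA

    def test_hba_boundary(self):
        three = ro3_profile(mol("COc1ccc(OC)cn1"))  # 2 OMe + ring N
        assert three.hba == 3
        assert three.passes
        four = ro3_profile(mol("COc1cc(OC)nc(OC)c1"))  # 3 OMe + ring N
        assert four.hba == 4
        assert four.rb == 3 and four.mw <= 300
        assert not four.passes  # fails only on HBA

    def test_thresholds_inclusive(self):
        profile = ro3_profile(mol("CCCCCC"))
        at = ro3_profile(mol("CCCCCC"), {"mw": profile.mw})
        assert at.passes
        just_below = ro3_profile(mol("CCCCCC"), {"mw": profile.mw - 0.01})
        assert not just_below.passes
        at_logp = ro3_profile(mol("CCCCCC"), {"logp": profile.logp})
        assert at_logp.passes
        below_logp = ro3_profile(mol("CCCCCC"), {"logp": profile.logp - 1e-9})
        assert not below_logp.passes

    def test_default_thresholds_match_study_values(self):
        assert RO3_DEFAULTS == {
            "mw": 300.0, "rb": 3, "tpsa": 60.0, "logp": 3.0, "hba": 3, "hbd": 3,
        }


class TestFilterRo3:
    def fragments(self, smiles_list):
        return [FragmentRecord(canonical_smiles=s, occurrence=1) for s in smiles_list]

    def test_subset_and_idempotent(self):
        frags = self.fragments(["c1ccccc1", "C" * 25, "CCO"])
        passing, rate = filter_ro3(frags)
        assert {f.canonical_smiles for f in passing} == {"c1ccccc1", "CCO"}
        again, rate2 = filter_ro3(passing)
        assert [f.canonical_smiles for f in again] == [f.canonical_smiles for f in passing]
        assert rate2 == 100.0

    def test_empty_input_rate_not_applicable(self):
        passing, rate = filter_ro3([])
        assert passing == []
        assert rate is None

    def test_all_benzene_rate(self):
        passing, rate = filter_ro3(self.fragments(["c1ccccc1"] * 5))
        assert len(passing) == 5
        assert rate == 100.0

    def test_occurrence_preserved(self):
        frag = FragmentRecord(canonical_smiles="c1ccccc1", occurrence=7)
        passing, _ = filter_ro3([frag])
        assert passing[0].occurrence == 7


class TestDescriptorProfile:
    def test_benzene(self):
        profile = descriptor_profile(mol("c1ccccc1"))
        assert profile.n_rings == 1
        assert profile.n_aromatic_rings == 1
        assert profile.n_heterocycles == 0
        assert profile.frac_sp3_C == 0
        assert profile.n_spiro_atoms == 0
        assert profile.frac_C == 1.0

    def test_spiro_nonane(self):
        profile = descriptor_profile(mol("C1CCC2(C1)CCCC2"))
        assert profile.n_spiro_atoms == 1
        assert profile.n_rings == 2
        assert profile.n_aliphatic_rings == 2
        assert profile.n_aromatic_rings == 0

    def test_norbornane_bridgeheads(self):
        profile = descriptor_profile(mol("C1CC2CCC1C2"))
        assert profile.n_bridgehead_atoms == 2

    def test_chiral_fraction_counts_unassigned_centers(self):
        assigned = descriptor_profile(mol("C[C@H](O)CC"))
        unassigned = descriptor_profile(mol("CC(O)CC"))
        assert assigned.frac_chiral_C == unassigned.frac_chiral_C == 0.25

    @pytest.mark.parametrize(
        "smiles",
        ["c1ccccc1", "c1ccncc1", "C1CCOCC1", "O=C1CCCCCN1", "c1ccc2ccccc2c1",
         "C1CC2CCC1C2", "CC(=O)Nc1ccc(O)cc1", "OC1OC(CO)C(O)C(O)C1O"],
    )
    def test_ring_count_invariants(self, smiles):
        profile = descriptor_profile(mol(smiles))
        assert profile.n_aliphatic_rings + profile.n_aromatic_rings == profile.n_rings
        assert profile.n_aromatic_heterocycles <= profile.n_aromatic_rings
        assert profile.n_aliphatic_heterocycles <= profile.n_aliphatic_rings
        assert profile.n_heterocycles <= profile.n_rings
        assert 0 <= profile.frac_C + profile.frac_O + profile.frac_N <= 1

    def test_homologous_series_monotonic(self):
        previous = None
        for length in range(1, 8):
            profile = descriptor_profile(mol("C" * length))
            if previous is not None:
                assert profile.mw > previous.mw
                assert profile.n_heavy > previous.n_heavy
            previous = profile


class TestLibrarySummary:
    def test_single_benzene(self):
        summary = library_descriptor_summary([mol("c1ccccc1")])
        profile = descriptor_profile(mol("c1ccccc1"))
        for name in ("n_rings", "frac_sp3_C", "mw"):
            assert summary[name] == pytest.approx(getattr(profile, name))

    def test_benzene_cyclohexane_means(self):
        summary = library_descriptor_summary([mol("c1ccccc1"), mol("C1CCCCC1")])
        assert summary["n_rings"] == pytest.approx(1.0)
        assert summary["frac_sp3_C"] == pytest.approx(0.5)

    def test_empty_collection_errors(self):
        with pytest.raises(ValueError):
            library_descriptor_summary([])

    def test_generated_library_recovers_target(self, np_like_records):
        mols = [mol(r.raw_smiles) for r in np_like_records]
        summary = library_descriptor_summary(mols)
        assert summary["frac_O"] == pytest.approx(0.22, abs=0.03)
        assert summary["frac_N"] <= 0.03
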