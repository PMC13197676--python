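"""Library triage: descriptors, filters, warhead classification."""

import pytest
from hypothesis import given, strategies as st
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from covfrag.chemlib import (
    DescriptorSet,
    Structure,
    StructureParseError,
    apply_size_logp_filter,
    classify_warhead,
    compute_descriptors,
    rule_of_three_profile,
)
from covfrag.synthetic import fixture_library


def _desc(**overrides) -> DescriptorSet:
    base = dict(heavy_atoms=10, mol_weight=150.0, logp=1.0, hbd=1, hba=2, rotatable_bonds=1, psa=30.0)
    base.update(overrides)
    return DescriptorSet(**base)


class TestDescriptors:
    def test_benzene_counts(self):
        d = compute_descriptors(Structure("benzene", "c1ccccc1"))
        assert d.heavy_atoms == 6
        assert d.hbd == 0

    def test_acetamide_counts(self):
        d = compute_descriptors(Structure("acetamide", "CC(N)=O"))
        assert d.heavy_atoms == 4
        assert d.hbd == 1

    def test_parse_error_names_id(self):
        with pytest.raises(StructureParseError, match="bad-mol"):
            compute_descriptors(Structure("bad-mol", "not_a_smiles(("))

    @pytest.mark.parametrize(
        "smiles", ["c1ccccc1", "CC(N)=O", "Clc1ccnc(Cl)n1", "C=CC(N)=O", "CC1CO1", "OCC1CO1", "CS(=O)(=O)c1ncccn1", "C=CS(=O)(=O)c1ccccc1", "N#Cc1ccc(O)cc1", "CCOC(=O)C1CO1"],
    )
    def test_crippen_logp_matches_atom_contribution_sum(self, smiles):
        """The reported logP equals the sum of published Wildman-Crippen
        per-atom contributions (independent table-lookup route)."""
        mol = Chem.AddHs(Chem.MolFromSmiles(smiles))  # H contributions count too
        contribs = rdMolDescriptors._CalcCrippenContribs(mol)
        expected = sum(logp for logp, _mr in contribs)
        d = compute_descriptors(Structure("m", smiles))
        assert d.logp == pytest.approx(expected, abs=1e-6)


class TestSizeLogpFilter:
    @pytest.mark.parametrize(
        "ha,logp,size_ok,logp_ok",
        [
            (5, 1.0, False, True),  # below the six-heavy-atom floor
            (6, 1.0, True, True),
            (22, 2.0, True, True),  # both boundaries inclusive
            (23, 1.0, False, True),
            (10, 2.5, True, False),  # logP > 2 excluded
        ],
    )
    def test_window_boundaries(self, ha, logp, size_ok, logp_ok):
        dec = apply_size_logp_filter(_desc(heavy_atoms=ha, logp=logp))
        assert dec.pass_size is size_ok
        assert dec.pass_logp is logp_ok
        assert dec.pass_overall is (size_ok and logp_ok)

    @given(st.floats(-5, 5), st.floats(0, 5))
    def test_logp_filter_monotone(self, lo, delta):
        """Increasing logP can never flip a failing filter back to passing."""
        fail_first = not apply_size_logp_filter(_desc(logp=lo)).pass_logp
        if fail_first:
            assert not apply_size_logp_filter(_desc(logp=lo + delta)).pass_logp


class TestRuleOfThree:
    @pytest.mark.parametrize(
        "overrides,expected",
        [
            ({"mol_weight": 301.0}, {"MW"}),
            ({"hba": 4, "psa": 63.8}, {"HBA", "PSA"}),
            ({"heavy_atoms": 1, "mol_weight": 16.0, "logp": 0.6, "hbd": 0, "hba": 0, "rotatable_bonds": 0, "psa": 0.0}, set()),
            ({"hbd": 4, "rotatable_bonds": 4}, {"HBD", "ROTB"}),
            ({"mol_weight": 300.0, "hba": 3, "psa": 60.0}, set()),  # thresholds inclusive
        ],
    )
    def test_violation_sets(self, overrides, expected):
        assert rule_of_three_profile(_desc(**overrides)) == frozenset(expected)


class TestWarheadClassification:
    @pytest.mark.parametrize(
        "smiles,family",
        [
            ("C=CC(N)=O", "AA"),
            ("Clc1ccnc(Cl)n1", "SN"),
            ("C=C(C#N)C(N)=O", "CA"),  # CA precedence over the AA submatch
            ("C=CS(=O)(=O)c1ccccc1", "VS"),
            ("CC1CO1", "EO"),
            ("c1ccccc1", "none"),
            ("Clc1ccccc1", "none"),  # halide on a carbocycle is not SNAr
        ],
    )
    def test_family_assignment(self, smiles, family):
        assert classify_warhead(Structure("m", smiles)).family == family

    def test_sn_ring_subtypes(self):
        assert classify_warhead(Structure("m", "Clc1ccnc(Cl)n1")).sn_ring == "six-membered"
        assert classify_warhead(Structure("m", "Clc1nccs1")).sn_ring == "five-membered"
        assert classify_warhead(Structure("m", "Clc1ncnc2ccccc12")).sn_ring == "bicyclic"

    def test_fixture_library_round_trip(self):
        """Every bundled fixture molecule classifies to its annotation,
        identically on repeated runs."""
        for structure, family, sn_ring in fixture_library():
            first = classify_warhead(structure)
            second = classify_warhead(structure)
            assert first == second
            assert first.family == family, structure.id
            if family == "SN":
                assert first.sn_ring == sn_ring, structure.id

    def test_oversized_fixture_fails_size_filter(self):
        big = next(s for s, _f, _r in fixture_library() if s.id == "neg-afatinib")
        dec = apply_size_logp_filter(compute_descriptors(big), id=big.id)
        assert not dec.pass_size
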