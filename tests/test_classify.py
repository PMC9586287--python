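"""Structure parsing, hazard flags and the Cramer decision tree."""

import pytest
from rdkit import Chem

from moescreen import cramer
from moescreen.classify import (
    SmilesParseError,
    classify_cramer,
    detect_ache_groups,
    detect_genotoxic_alerts,
    kroes_gate,
    molecular_weight,
    parse_structure,
    profile_chemical,
    volatility_flag,
)
from moescreen.records import ChemicalRecord, CramerClass


class TestParseStructure:
    def test_ethanol_graph_and_mw(self):
        mol = parse_structure("CCO")
        assert sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6) == 2
        assert sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 8) == 1
        # atomic-mass sum: 2*12.011 + 6*1.008 + 15.999
        assert molecular_weight(mol) == pytest.approx(46.069, abs=0.01)

    @pytest.mark.parametrize("bad", ["", "   ", "C1CC", "not_a_smiles(("])
    def test_unparsable_smiles_raise(self, bad):
        with pytest.raises(SmilesParseError) as exc:
            parse_structure(bad)
        assert bad.strip() in str(exc.value) or "empty" in str(exc.value)

    def test_salt_reduced_to_largest_organic_fragment(self):
        mol = parse_structure("CC(=O)[O-].[Na+]")
        assert all(a.GetAtomicNum() != 11 for a in mol.GetAtoms())
        assert any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


class TestAcheGroups:
    @pytest.mark.parametrize(
        "smiles,carbamate,organophosphate",
        [
            ("CCOP(=O)(OCC)OCC", False, True),  # triethyl phosphate
            ("CNC(=O)Oc1cccc2ccccc12", True, False),  # carbaryl
            ("CCO", False, False),  # ethanol: no N, no P
            ("CCOC(=O)CC(SP(=S)(OC)OC)C(=O)OCC", False, True),  # thiophosphate
            ("CNC(=O)ON=C(C)SC", True, False),  # oxime carbamate (methomyl)
        ],
    )
    def test_substructure_flags(self, smiles, carbamate, organophosphate):
        mol = parse_structure(smiles)
        assert detect_ache_groups(mol) == (carbamate, organophosphate)


class TestGenotoxicAlerts:
    @pytest.mark.parametrize(
        "smiles,expected_alert",
        [
            ("O=[N+]([O-])c1ccccc1", "aromatic nitro"),
            ("CN(C)N=O", "N-nitroso"),
            ("c1ccc(/N=N/c2ccccc2)cc1", "aromatic azo"),
            ("OCC1CO1", "epoxide"),
            ("COS(C)(=O)=O", "alkyl sulfonate or phosphonate ester"),
            ("C=CC=O", "alpha,beta-unsaturated carbonyl"),
        ],
    )
    def test_alert_names(self, smiles, expected_alert):
        flag, names = detect_genotoxic_alerts(parse_structure(smiles))
        assert flag and expected_alert in names

    @pytest.mark.parametrize(
        "clean", ["CCO", "c1ccncc1", "CNC(=O)Oc1cccc2ccccc12", "O=Cc1ccco1"]
    )
    def test_clean_structures_unflagged(self, clean):
        flag, names = detect_genotoxic_alerts(parse_structure(clean))
        assert not flag and names == []

    def test_phosphate_ester_is_not_phosphonate_alert(self):
        # phosphate (P bonded to O only) must not trip the P-C phosphonate alert
        flag, names = detect_genotoxic_alerts(parse_structure("CCOP(=O)(OCC)OCC"))
        assert not flag


class TestKroesGate:
    def test_plain_organic_inside_domain(self):
        assert kroes_gate(parse_structure("CCO")) == (False, None)

    def test_organometallic_excluded(self):
        excluded, reason = kroes_gate(parse_structure("C[As](C)C"))
        assert excluded and reason == "organometallic"

    def test_polyhalogenated_dibenzodioxin_core_excluded(self):
        tcdd = "O1c2cc(Cl)c(Cl)cc2Oc2cc(Cl)c(Cl)cc12"
        excluded, reason = kroes_gate(parse_structure(tcdd))
        assert excluded and "high-potency carcinogen" in reason

    def test_annotation_only_chemical_still_classified(self):
        profile = profile_chemical(
            ChemicalRecord(chem_id="x", smiles="C[As](C)C")
        )
        assert profile.kroes_excluded
        assert profile.cramer_class in set(CramerClass)


class TestCramer:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("CCO", CramerClass.I),  # simple aliphatic alcohol
            ("CC(C)O", CramerClass.I),
            ("c1ccc2ncccc2c1", CramerClass.III),  # fused heteroaromatic
            ("O=C1C=Cc2ccccc2O1", CramerClass.III),  # fused/unsaturated lactone
            ("c1ccncc1", CramerClass.II),  # monocyclic heteroaromatic
            ("CCCCCC", CramerClass.I),  # plain hydrocarbon
        ],
    )
    def test_known_classes(self, smiles, expected):
        cls, trace = classify_cramer(parse_structure(smiles))
        assert cls == expected
        assert len(trace) >= 1

    def test_every_structure_gets_exactly_one_class(self, panel_profiles):
        for _, (_, _, profile) in panel_profiles.items():
            assert profile.cramer_class in set(CramerClass)
            assert len(profile.cramer_trace) >= 1

    def test_trace_replay(self, panel_profiles):
        for smiles, (_, _, profile) in panel_profiles.items():
            mol = parse_structure(smiles)
            assert cramer.replay(mol, profile.cramer_trace)

    def test_classification_invariant_to_smiles_form(self):
        # same structure, different SMILES spellings -> same profile
        for a, b in [("CCO", "OCC"), ("Cc1ccccc1", "C1=CC=CC=C1C")]:
            pa = profile_chemical(ChemicalRecord(chem_id="a", smiles=a))
            pb = profile_chemical(ChemicalRecord(chem_id="b", smiles=b))
            assert pa.cramer_class == pb.cramer_class
            assert pa.genotoxic_alert == pb.genotoxic_alert
            assert pa.is_carbamate_ester == pb.is_carbamate_ester

    def test_all_33_questions_defined_and_wired(self):
        assert len(cramer.NODES) == 33
        reachable = set()
        stack = [cramer.ROOT]
        while stack:
            qid = stack.pop()
            if qid in reachable:
                continue
            reachable.add(qid)
            node = cramer.NODES[qid]
            for nxt in (node.yes, node.no):
                if not isinstance(nxt, CramerClass):
                    stack.append(nxt)
        assert reachable == set(cramer.NODES)


class TestVolatility:
    @pytest.mark.parametrize(
        "bp,vp,expected",
        [
            (100.0, None, True),  # below the 260 C boiling-point cutoff
            (300.0, 0.01, False),
            (None, 0.5, True),  # above the 0.1 mmHg vapor-pressure cutoff
            (None, None, None),
            (259.9, 0.0, True),
            (260.0, 0.1, False),  # both exactly at cutoffs: not volatile
        ],
    )
    def test_cutoffs(self, bp, vp, expected):
        assert volatility_flag(bp, vp) is expected

    def test_negative_vapor_pressure_rejected(self):
        with pytest.raises(ValueError):
            volatility_flag(None, -1.0)


def test_panel_flags_match_truth_labels(panel_profiles):
    """Every template-panel exemplar is classified exactly as labeled."""
    from moescreen.records import TTCCategory
    from moescreen.ttc import assign_category

    for smiles, (category, kroes, profile) in panel_profiles.items():
        assignment = assign_category(profile, apply_genotox_filter=True)
        assert assignment.category == category, smiles
        assert profile.kroes_excluded == kroes, smiles
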