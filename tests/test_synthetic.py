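"""Synthetic-data generators: determinism, distributions, ground truth."""

import numpy as np
import pandas as pd
import pytest

from moescreen.classify import profile_chemical
from moescreen.pod import filter_records, quantile_type2
from moescreen.records import ChemicalRecord, TTCCategory
from moescreen.synthetic import (
    DEFAULT_MIX,
    PANEL,
    generate_bioactivity,
    generate_bundle,
    generate_chemicals,
    generate_exposures,
    generate_noael_sets,
    generate_pk,
)
from moescreen.ttc import TTC_VALUES_UG_PER_KG_D, assign_category


class TestGenerateChemicals:
    def test_degenerate_mix_all_cramer_i(self):
        chems = generate_chemicals(10, {TTCCategory.CRAMER_I: 1.0}, seed=1)
        assert len(chems) == 10
        assert all(c.truth_category == TTCCategory.CRAMER_I for c in chems)

    def test_seeded_determinism(self):
        a = generate_chemicals(100, seed=7)
        b = generate_chemicals(100, seed=7)
        assert a == b

    def test_unique_ids_and_positive_mw(self):
        chems = generate_chemicals(50, seed=2)
        assert len({c.chem_id for c in chems}) == 50
        assert all(c.mw > 0 for c in chems)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_chemicals(0, seed=1)
        with pytest.raises(ValueError):
            generate_chemicals(5, {TTCCategory.CRAMER_I: 0.5}, seed=1)

    def test_truth_recovery_on_default_mix(self):
        """classify + assign-ttc recovers truth_category for 100% of chemicals."""
        chems = generate_chemicals(100, seed=3)
        for c in chems:
            profile = profile_chemical(
                ChemicalRecord(chem_id=c.chem_id, smiles=c.smiles)
            )
            assignment = assign_category(profile, apply_genotox_filter=True)
            assert assignment.category == c.truth_category, c.smiles
            assert profile.kroes_excluded == c.truth_kroes_excluded, c.smiles


class TestGenerateBioactivity:
    def chems(self, n=1):
        return generate_chemicals(n, {TTCCategory.CRAMER_I: 1.0}, seed=1)

    def test_zero_variance_single_assay(self):
        df = generate_bioactivity(
            self.chems(), n_assays_range=(1, 1), logmean=np.log(10), logsd=0.0, seed=1
        )
        assert len(df) == 1
        assert df.ac50_uM.iloc[0] == pytest.approx(10.0)

    def test_seeded_determinism(self):
        chems = self.chems(20)
        a = generate_bioactivity(chems, seed=9)
        b = generate_bioactivity(chems, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_lognormal_median_recovered(self):
        # median of a lognormal is exp(logmean); Monte Carlo at ~10^4 rows
        chems = self.chems(400)
        df = generate_bioactivity(
            chems, n_assays_range=(25, 25), logmean=np.log(1.0), logsd=1.0, seed=5
        )
        assert len(df) == 10_000
        assert np.median(df.ac50_uM) == pytest.approx(1.0, rel=0.10)

    def test_all_positive_and_errors(self):
        df = generate_bioactivity(self.chems(10), seed=0)
        assert (df.ac50_uM > 0).all()
        with pytest.raises(ValueError):
            generate_bioactivity([], seed=0)
        with pytest.raises(ValueError):
            generate_bioactivity(self.chems(), n_assays_range=(0, 5), seed=0)


class TestGeneratePK:
    def test_point_mass_at_zero_clint(self):
        chems = generate_chemicals(30, seed=4)
        df = generate_pk(chems, seed=1, zero_clint_fraction=1.0)
        assert (df.clint == 0).all()

    def test_fup_in_unit_interval(self):
        df = generate_pk(generate_chemicals(200, seed=4), seed=2)
        assert ((df.fup > 0) & (df.fup <= 1)).all()

    def test_seeded_determinism(self):
        chems = generate_chemicals(20, seed=4)
        pd.testing.assert_frame_equal(
            generate_pk(chems, seed=3), generate_pk(chems, seed=3)
        )


class TestGenerateNoael:
    def test_ttc_consistent_pins_generating_5th_percentile(self):
        # Cramer III truth: TTC 1.5 µg/kg-d -> generating p5 must be 0.15 mg/kg-d
        chems = generate_chemicals(200, {TTCCategory.CRAMER_III: 1.0}, seed=6)
        df = generate_noael_sets(
            chems, ttc_consistent=True, seed=8, n_range=(40, 40), decoy_fraction=0.0
        )
        empirical_p5 = quantile_type2(df.value.tolist(), 0.05)
        assert empirical_p5 == pytest.approx(0.15, rel=0.15)

    def test_no_decoys_all_rows_survive_filter(self):
        chems = generate_chemicals(20, seed=6)
        df = generate_noael_sets(chems, seed=1, decoy_fraction=0.0)
        assert len(filter_records(df)) == len(df)

    def test_decoys_are_removed_by_filter(self):
        chems = generate_chemicals(50, seed=6)
        df = generate_noael_sets(chems, seed=1, decoy_fraction=0.5, n_range=(10, 20))
        kept = filter_records(df)
        assert 0 < len(kept) < len(df)

    def test_all_values_positive_and_deterministic(self):
        chems = generate_chemicals(20, seed=6)
        a = generate_noael_sets(chems, seed=2)
        b = generate_noael_sets(chems, seed=2)
        pd.testing.assert_frame_equal(a, b)
        assert (a.value > 0).all()


class TestGenerateExposures:
    def chems(self):
        return generate_chemicals(50, seed=10)

    def test_upper95_factor_one_means_equal(self):
        df = generate_exposures(self.chems(), upper95_factor=1.0, seed=1)
        assert (df.upper95 == df["median"]).all()

    def test_zero_seem2_fraction(self):
        df = generate_exposures(self.chems(), seem2_fraction=0.0, seed=1)
        assert (df.source == "SEEM3").all()

    def test_seeded_determinism_and_one_row_per_chemical(self):
        chems = self.chems()
        a = generate_exposures(chems, seed=4)
        b = generate_exposures(chems, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == len(chems)
        assert (a.upper95 >= a["median"]).all()

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            generate_exposures(self.chems(), upper95_factor=0.5, seed=1)


def test_bundle_determinism_and_truth_sidecar(tmp_path):
    a = generate_bundle(25, seed=13)
    b = generate_bundle(25, seed=13)
    for name in ("chemicals", "bioactivity", "pk", "noael", "exposure"):
        pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
    assert a.truth == b.truth
    a.write(tmp_path / "x")
    b.write(tmp_path / "y")
    for f in sorted((tmp_path / "x").iterdir()):
        assert (tmp_path / "y" / f.name).read_bytes() == f.read_bytes()


def test_default_mix_sums_to_one():
    assert sum(DEFAULT_MIX.values()) == pytest.approx(1.0)
    assert set(DEFAULT_MIX) == set(PANEL)
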