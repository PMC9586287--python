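"""MoE computation, exposure selection, ranking, summaries and the pipeline."""

import filecmp
from pathlib import Path

import pandas as pd
import pytest

from moescreen.moe import (
    compute_moe,
    rank_by_moe,
    select_exposure,
    select_exposures,
    summarize_by_category,
    ttc_pod,
)
from moescreen.pipeline import RunConfig, run_pipeline
from moescreen.records import ExposureEstimate, PodType, PoDResult, TTCCategory


def exp(chem_id="c", source="SEEM3", median=0.001, upper95=0.01):
    return ExposureEstimate(chem_id, source, median, upper95)


def pod(value, chem_id="c", pod_type=PodType.TTC):
    return PoDResult(chem_id=chem_id, pod_type=pod_type, pod=value)


class TestSelectExposure:
    def test_seem3_preferred_over_seem2(self):
        chosen = select_exposure(exp(source="SEEM3"), exp(source="SEEM2"))
        assert chosen.source == "SEEM3"

    def test_seem2_fallback(self):
        chosen = select_exposure(None, exp(source="SEEM2"))
        assert chosen.source == "SEEM2"

    def test_neither_present_raises(self):
        with pytest.raises(ValueError):
            select_exposure(None, None)

    def test_bulk_selection_reports_missing(self):
        rows = [exp("a", "SEEM3"), exp("a", "SEEM2"), exp("b", "SEEM2")]
        selected, missing = select_exposures(rows)
        assert selected["a"].source == "SEEM3"
        assert selected["b"].source == "SEEM2"
        assert missing == []


class TestComputeMoE:
    def test_equality_boundary_not_flagged(self):
        # TTC 1.5 µg/kg-d -> PoD 0.0015 mg/kg-d; MoE exactly 1 is NOT lt1
        res = compute_moe(ttc_pod(1.5, "c"), exp(upper95=0.0015))
        assert res.moe == pytest.approx(1.0)
        assert not res.lt1

    def test_simple_ratio(self):
        res = compute_moe(ttc_pod(30.0, "c"), exp(upper95=0.003))
        assert res.moe == pytest.approx(10.0)

    def test_lt1_flag(self):
        res = compute_moe(pod(0.5), exp(upper95=5.0))
        assert res.moe == pytest.approx(0.1)
        assert res.lt1

    def test_ug_to_mg_conversion_happens_once(self):
        assert ttc_pod(1.5).pod == pytest.approx(0.0015)
        assert ttc_pod(30.0).pod == pytest.approx(0.030)

    def test_scale_invariance(self):
        a = compute_moe(pod(0.5), exp(upper95=5.0)).moe
        b = compute_moe(pod(0.5 * 7.3), exp(upper95=5.0 * 7.3)).moe
        assert a == pytest.approx(b)

    def test_monotonicity(self):
        base = compute_moe(pod(0.5), exp(upper95=5.0)).moe
        assert compute_moe(pod(1.0), exp(upper95=5.0)).moe > base
        assert compute_moe(pod(0.5), exp(upper95=10.0)).moe < base

    def test_nonpositive_exposure_is_state_error(self):
        with pytest.raises(RuntimeError):
            compute_moe(pod(0.5), exp(upper95=0.0))


class TestRanking:
    @staticmethod
    def results(moes: dict):
        return [
            compute_moe(pod(v, chem_id=k), exp(chem_id=k, upper95=1.0))
            for k, v in moes.items()
        ]

    def test_ascending_order_top_n(self):
        top = rank_by_moe(self.results({"A": 0.5, "B": 2.0, "C": 0.1}), top_n=2)
        assert [r.chem_id for r in top] == ["C", "A"]
        assert [r.rank for r in top] == [1, 2]

    def test_ties_broken_by_chem_id(self):
        top = rank_by_moe(self.results({"z": 1.0, "a": 1.0, "m": 1.0}), top_n=3)
        assert [r.chem_id for r in top] == ["a", "m", "z"]

    def test_top_n_exceeding_size_returns_all(self):
        top = rank_by_moe(self.results({"A": 0.5, "B": 2.0}), top_n=10)
        assert len(top) == 2

    def test_invalid_top_n(self):
        with pytest.raises(ValueError):
            rank_by_moe(self.results({"A": 1.0}), top_n=0)


class TestSummary:
    @staticmethod
    def result(chem_id, moe_value, category):
        r = compute_moe(
            pod(moe_value, chem_id=chem_id),
            exp(chem_id=chem_id, upper95=1.0),
            ttc_category=category,
        )
        return r

    def test_single_category_total_matches(self):
        rows = [self.result(f"c{i}", v, TTCCategory.CRAMER_I) for i, v in enumerate([2.0, 0.5])]
        df = summarize_by_category(rows)
        cat = df[df.category == "CRAMER_I"].iloc[0]
        tot = df[df.category == "Total"].iloc[0]
        assert cat.n == tot.n == 2
        assert cat.n_lt1 == tot.n_lt1 == 1
        assert cat.median_moe == tot.median_moe

    def test_counts_sum_to_total(self):
        rows = [
            self.result("a", 2.0, TTCCategory.CRAMER_I),
            self.result("b", 0.5, TTCCategory.CRAMER_III),
            self.result("c", 0.1, TTCCategory.GENOTOXIC),
        ]
        df = summarize_by_category(rows)
        assert df[df.category != "Total"].n.sum() == df[df.category == "Total"].n.iloc[0]

    def test_median_is_type2_mean_of_middle_pair(self):
        rows = [self.result(f"c{i}", v, TTCCategory.CRAMER_II) for i, v in enumerate([1, 2, 3, 4])]
        df = summarize_by_category(rows)
        assert df[df.category == "CRAMER_II"].median_moe.iloc[0] == pytest.approx(2.5)


@pytest.fixture()
def bundle_dir(tmp_path, small_bundle):
    d = tmp_path / "bundle"
    small_bundle.write(d)
    return d


def make_config(bundle_dir, out_dir, **overrides):
    kwargs = dict(
        chemicals=str(bundle_dir / "chemicals.csv"),
        exposure=str(bundle_dir / "exposure.csv"),
        bioactivity=str(bundle_dir / "bioactivity.csv"),
        pk=str(bundle_dir / "pk.csv"),
        noael=str(bundle_dir / "noael.csv"),
        out_dir=str(out_dir),
        seed=5,
        n_samples=200,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


class TestPipeline:
    def test_all_three_pod_types_produce_tables(self, bundle_dir, tmp_path):
        tables, report = run_pipeline(make_config(bundle_dir, tmp_path / "out"))
        for name in ("moe_ttc", "moe_oed", "moe_noael", "summary", "top_n"):
            assert name in tables and len(tables[name]) > 0
        counts = report["counts"]
        assert counts["n_input"] == counts["n_classified"] + counts["n_rejected"]

    def test_same_seed_byte_identical_outputs(self, bundle_dir, tmp_path):
        out1, out2 = tmp_path / "run1", tmp_path / "run2"
        run_pipeline(make_config(bundle_dir, out1))
        run_pipeline(make_config(bundle_dir, out2))
        for f in sorted(out1.glob("*.csv")):
            assert (out2 / f.name).read_bytes() == f.read_bytes(), f.name

    def test_genotox_toggle_only_changes_alert_chemicals(self, bundle_dir, tmp_path):
        t_on, _ = run_pipeline(
            make_config(bundle_dir, tmp_path / "on", pod_types=("TTC",), genotox_filter=True)
        )
        t_off, _ = run_pipeline(
            make_config(bundle_dir, tmp_path / "off", pod_types=("TTC",), genotox_filter=False)
        )
        profiles = t_on["profiles"].set_index("chem_id")
        on = t_on["moe_ttc"].set_index("chem_id")
        off = t_off["moe_ttc"].set_index("chem_id")
        for chem_id in on.index:
            changed = on.loc[chem_id, "moe"] != off.loc[chem_id, "moe"]
            if changed:
                assert profiles.loc[chem_id, "genotoxic_alert"], chem_id
            if not profiles.loc[chem_id, "genotoxic_alert"]:
                assert on.loc[chem_id, "moe"] == off.loc[chem_id, "moe"]

    def test_shared_denominator_across_pod_types(self, bundle_dir, tmp_path):
        tables, _ = run_pipeline(make_config(bundle_dir, tmp_path / "out"))
        merged = tables["moe_ttc"].merge(
            tables["moe_noael"], on="chem_id", suffixes=("_ttc", "_noael")
        )
        assert (
            merged.exposure_upper95_ttc == merged.exposure_upper95_noael
        ).all()

    def test_missing_table_for_requested_pod_type(self, bundle_dir, tmp_path):
        from moescreen.pipeline import ConfigurationError

        with pytest.raises(ConfigurationError, match="noael"):
            run_pipeline(
                make_config(bundle_dir, tmp_path / "out", noael=None, pod_types=("NOAEL",))
            )
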