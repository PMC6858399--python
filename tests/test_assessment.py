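"""End-to-end assessment assembly, screens, config, CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from critb import AssessmentConfig, RangeMetrics, restricted_screen, run_assessment
from critb.cli import main
from critb.io import read_assessment_json, write_assessment_report
from critb.landscape import generate_bundle
from critb.grid import GridSpec


class TestRestrictedScreen:
    @pytest.mark.parametrize(
        "eoo,aoo,expect_eoo,expect_aoo",
        [
            (396.0, 264.0, True, True),        # highly restricted species
            (121939.0, 73076.0, False, False),  # widespread species
            (20000.0, 100.0, False, True),      # boundary: strict "smaller than"
            (19999.9, 2000.0, True, False),
        ],
    )
    def test_strict_thresholds(self, eoo, aoo, expect_eoo, expect_aoo):
        s = restricted_screen(RangeMetrics(eoo, aoo), AssessmentConfig())
        assert s["eoo_restricted"] is expect_eoo
        assert s["aoo_restricted"] is expect_aoo


@pytest.fixture(scope="module")
def assessed(small_bundle):
    config = AssessmentConfig(n_replicates=4, seed=21)
    record = run_assessment(
        small_bundle.occurrences,
        small_bundle.env_layers,
        small_bundle.landuse,
        small_bundle.dem,
        small_bundle.villages,
        config=config,
        species_id="synthetic_sp",
    )
    return record, config, small_bundle


class TestRunAssessment:
    def test_deterministic_under_seed(self, assessed):
        record, config, bundle = assessed
        again = run_assessment(
            bundle.occurrences, bundle.env_layers, bundle.landuse, bundle.dem,
            bundle.villages, config=config, species_id="synthetic_sp",
        )
        assert again.range_metrics == record.range_metrics
        assert again.fragmentation.ra_lqh_percent == record.fragmentation.ra_lqh_percent
        assert again.locations.n_locations == record.locations.n_locations
        assert again.provenance["input_digests"] == record.provenance["input_digests"]

    def test_record_is_internally_consistent(self, assessed):
        record, config, _ = assessed
        assert record.range_metrics.eoo_km2 >= record.range_metrics.aoo_km2
        assert 0 <= record.fragmentation.ra_lqh_percent <= 100
        assert record.fragmentation.severely_fragmented == (
            record.fragmentation.ra_lqh_percent > config.lqh.severe_threshold_percent
        )
        assert record.screens == restricted_screen(record.range_metrics, config)
        assert 0 <= record.sdm_eval_train.auc <= 1

    def test_pristine_landscape_is_unfragmented(self):
        bundle = generate_bundle(
            spec=GridSpec(40, 40), n_env_layers=4, anthropogenic_fraction=0.0,
            n_occurrences=80, seed=31,
        )
        record = run_assessment(
            bundle.occurrences, bundle.env_layers, bundle.landuse, bundle.dem,
            bundle.villages, config=AssessmentConfig(n_replicates=3, seed=31),
        )
        assert record.fragmentation.ra_lqh_percent == 0.0
        assert not record.fragmentation.severely_fragmented

    def test_stage_errors_carry_stage_name(self, small_bundle):
        bad_occ = small_bundle.occurrences.subset(np.arange(3))  # too few records
        with pytest.raises(RuntimeError, match="fit_sdm"):
            run_assessment(
                bad_occ, small_bundle.env_layers, small_bundle.landuse,
                small_bundle.dem, small_bundle.villages,
                config=AssessmentConfig(n_replicates=2, seed=1),
            )


class TestReportRoundtrip:
    def test_json_and_csv_agree_with_record(self, assessed, tmp_path):
        record, config, _ = assessed
        json_path, csv_path = write_assessment_report(record, tmp_path)
        loaded = read_assessment_json(json_path)[0]
        assert loaded["species_id"] == "synthetic_sp"
        assert loaded["range_metrics"]["eoo_km2"] == record.range_metrics.eoo_km2
        df = pd.read_csv(csv_path)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["ra_lqh_percent"] == round(record.fragmentation.ra_lqh_percent, 2)
        # screens recomputed from the CSV match the stored booleans
        assert bool(row["eoo_restricted"]) == (row["eoo_km2"] < config.eoo_restricted_km2)
        assert bool(row["aoo_restricted"]) == (row["aoo_km2"] < config.aoo_restricted_km2)


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = AssessmentConfig(seed=77)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = AssessmentConfig.from_yaml(p)
        assert back == cfg

    def test_shipped_defaults_match_dataclass_defaults(self):
        import importlib.resources

        import yaml

        raw = yaml.safe_load(
            importlib.resources.files("critb").joinpath("data/default_config.yaml").read_text()
        )
        cfg = AssessmentConfig()
        assert raw["lqh"]["buffer_km"] == cfg.lqh.buffer_km == 2.0
        assert raw["lqh"]["severe_threshold_percent"] == cfg.lqh.severe_threshold_percent == 50.0
        assert set(raw["lqh"]["anthropogenic_codes"]) == set(cfg.lqh.anthropogenic_codes)
        assert raw["locations"]["min_population"] == cfg.locations.min_population == 100
        assert raw["locations"]["locality_radius_km"] == cfg.locations.locality_radius_km == 2.5
        assert raw["eoo_restricted_km2"] == cfg.eoo_restricted_km2 == 20000.0
        assert raw["aoo_restricted_km2"] == cfg.aoo_restricted_km2 == 2000.0
        assert raw["aoo_cell_km"] == cfg.aoo_cell_km == 2.0


def test_cli_simulate_assess_report(tmp_path):
    runner = CliRunner()
    bundle_dir = tmp_path / "bundle"
    r = runner.invoke(
        main,
        ["simulate", "--grid", "30x30", "--n-occurrences", "60", "--n-env-layers", "3",
         "--seed", "5", "--out", str(bundle_dir)],
    )
    assert r.exit_code == 0, r.output
    out_dir = tmp_path / "report"
    r = runner.invoke(
        main,
        ["assess",
         "--occurrences", str(bundle_dir / "occurrences.csv"),
         "--env-dir", str(bundle_dir),
         "--landuse", str(bundle_dir / "landuse.asc"),
         "--dem", str(bundle_dir / "dem.asc"),
         "--villages", str(bundle_dir / "villages.csv"),
         "--out", str(out_dir)],
    )
    assert r.exit_code == 0, r.output
    assert "RA_LQH" in r.output
    r = runner.invoke(main, ["report", "--in", str(out_dir), "--format", "csv"])
    assert r.exit_code == 0
    assert "ra_lqh_percent" in r.output
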