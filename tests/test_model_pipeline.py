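"""The cohort model facade, end-to-end pipeline runs and the CLI."""

import hashlib
import json

import pytest
from click.testing import CliRunner

from cnakit.cli import main as cli_main
from cnakit.config import PipelineConfig
from cnakit.model import CohortAnalysis
from cnakit.pipeline import run_pipeline
from cnakit.simulate import CohortSpec, demo_gene_sets, simulate_cohort


@pytest.fixture(scope="module")
def fitted(small_sim):
    analysis = CohortAnalysis.from_simulation(small_sim)
    analysis.gene_sets = demo_gene_sets(small_sim.gene_models, seed=1)
    return analysis, analysis.fit(seed=3)


class TestConfig:
    def test_round_trips_through_json(self, tmp_path):
        cfg = PipelineConfig(cbs_alpha=1e-4, cluster_k=4)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        assert PipelineConfig.from_json(path) == cfg

    def test_documented_operating_points_are_the_defaults(self):
        cfg = PipelineConfig()
        assert cfg.bins == (0.5, 1.7, 2.3, 3.8)
        assert cfg.cbs_alpha == 1e-6
        assert cfg.mcr_min_freq == 0.10
        assert cfg.stac_p == 0.01
        assert cfg.gistic_q == 0.25
        assert (cfg.compare_diff, cfg.compare_p) == (15.0, 0.01)
        assert cfg.cluster_k == 3
        assert cfg.r_threshold == 0.3
        assert cfg.set_size == (10, 500)
        assert cfg.survival_p == 0.01
        assert cfg.mapd_cutoff == 0.6

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(cbs_alpha=0.0)
        with pytest.raises(ValueError):
            PipelineConfig(bins=(1.7, 0.5, 2.3, 3.8))
        with pytest.raises(ValueError, match="unknown config keys"):
            PipelineConfig.from_json('{"not_a_key": 1}')


class TestModelFit:
    def test_all_stage_outputs_present(self, fitted):
        _, res = fitted
        assert res.qc_table is not None and res.qc_table["pass"].all()
        assert res.segments is not None and len(res.segments) > 0
        assert res.event_counts is not None
        assert res.track is not None
        assert res.mcr_table is not None and len(res.mcr_table) > 0
        assert res.peak_table is not None
        assert res.comparisons  # MSI vs MSS and stage comparisons
        assert res.clusters is not None
        assert res.gene_cn is not None
        assert res.concordance is not None and res.concordance["testable"].any()
        assert res.correlation is not None
        assert res.survival_table is not None
        summary = res.summary()
        assert "events/tumor" in summary and "MCRs" in summary

    def test_burden_difference_recovered(self, fitted):
        _, res = fitted
        t, p, (m_mss, _), (m_msi, _) = res.burden["MSS_vs_MSI"]
        assert m_mss > m_msi
        assert p < 0.01

    def test_stage_subsetting_runs_only_requested_stages(self, small_sim):
        analysis = CohortAnalysis.from_simulation(small_sim)
        res = analysis.fit(stages=["classify"], seed=0)
        assert res.segments is not None
        assert res.track is None
        assert res.mcr_table is None

    def test_unknown_stage_rejected(self, small_sim):
        analysis = CohortAnalysis.from_simulation(small_sim)
        with pytest.raises(ValueError, match="unknown stages"):
            analysis.fit(stages=["nonsense"])


class TestPipeline:
    def _run(self, tmp_path, name, seed=5):
        sim = simulate_cohort(CohortSpec.default_combined(n_mss=14, n_msi=6), seed=9)
        analysis = CohortAnalysis.from_simulation(sim)
        analysis.gene_sets = demo_gene_sets(sim.gene_models, seed=2)
        return run_pipeline(analysis, tmp_path / name, seed=seed)

    def test_full_run_emits_result_tables_and_manifest(self, tmp_path):
        manifest = self._run(tmp_path, "run1")
        out = tmp_path / "run1"
        assert (out / "manifest.json").exists()
        for table in (
            "qc",
            "segments.seg",
            "event_counts",
            "frequency_track",
            "mcrs",
            "clusters",
            "gene_cn",
            "concordance",
            "survival",
        ):
            fname = table if table.endswith(".seg") else f"{table}.tsv"
            assert (out / fname).exists(), fname
        assert len(manifest["tables"]) >= 10

    def test_rerun_is_bitwise_identical(self, tmp_path):
        self._run(tmp_path, "a", seed=5)
        self._run(tmp_path, "b", seed=5)

        def digest(d):
            out = {}
            for f in sorted(d.iterdir()):
                out[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
            return out

        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_zero_mapd_cutoff_aborts_with_message(self, tmp_path, small_sim):
        analysis = CohortAnalysis.from_simulation(small_sim)
        analysis.config = PipelineConfig(mapd_cutoff=1e-12)
        with pytest.raises(RuntimeError, match="MAPD"):
            run_pipeline(analysis, tmp_path / "bad", seed=0)


class TestCli:
    def test_simulate_then_run_all(self, tmp_path):
        runner = CliRunner()
        cohort = tmp_path / "cohort"
        r = runner.invoke(
            cli_main,
            [
                "simulate",
                "--preset",
                "combined",
                "--n-mss",
                "10",
                "--n-msi",
                "5",
                "--seed",
                "1",
                "--out",
                str(cohort),
            ],
        )
        assert r.exit_code == 0, r.output
        assert (cohort / "probes.tsv").exists()
        assert (cohort / "clinical.tsv").exists()

        out = tmp_path / "results"
        r = runner.invoke(
            cli_main,
            ["run-all", str(cohort), "--seed", "2", "--out", str(out)],
        )
        assert r.exit_code == 0, r.output
        assert (out / "manifest.json").exists()
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 2

    def test_seed_is_mandatory(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(
            cli_main, ["simulate", "--out", str(tmp_path / "x")]
        )
        assert r.exit_code != 0
        assert "seed" in r.output.lower()
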