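"""Configuration defaults, file-format roundtrips, study validation, and
pipeline orchestration (determinism, degenerate configs, CLI smoke)."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from pedmeth import io as pio
from pedmeth.cli import main as cli_main
from pedmeth.config import AnalysisConfig
from pedmeth.containers import PedigreeSet
from pedmeth.pipeline import (OUTPUT_FILES, Study, load_study, run_pipeline,
                              write_study)


def test_config_defaults_pin_study_thresholds():
    """Every default equals the study's stated value."""
    c = AnalysisConfig()
    assert c.min_depth == 10
    assert c.min_present_fraction == 0.8
    assert c.sd_variable == 0.1
    assert c.sd_highly_variable == 0.3
    assert c.h2_min == 0.2
    assert c.min_trios == 10
    assert c.fdr == 0.05
    assert c.window == 1_000_000
    assert c.maf_min == 0.05
    assert c.hwe_min_p == 0.001
    assert c.n_perm == 10_000
    assert c.asm_p_max == 0.001
    assert c.asm_delta_min == 0.2
    assert c.vmr_min_cpgs == 5
    assert c.vmr_max_spacing == 200
    assert c.vmr_cluster_distance == 100_000


def test_config_validation():
    with pytest.raises(ValueError):
        AnalysisConfig(fdr=1.5)
    with pytest.raises(ValueError):
        AnalysisConfig(min_trios=0)
    with pytest.raises(ValueError, match="unknown"):
        AnalysisConfig.from_dict({"not_a_field": 1})


def test_config_hash_stable_and_sensitive():
    assert AnalysisConfig().hash() == AnalysisConfig().hash()
    assert AnalysisConfig().hash() != AnalysisConfig(seed=1).hash()


class TestRoundtrips:
    def test_study_roundtrip(self, demo_cohort, tmp_path):
        eff, ped, g, m, truth, frags = demo_cohort
        study = Study(ped, g, m, frags)
        paths = write_study(study, tmp_path)
        loaded = load_study(paths["vcf"], paths["fam"], paths["meth"],
                            paths["frags"])
        assert loaded.methylation.samples == m.samples
        np.testing.assert_allclose(loaded.methylation.values, m.values,
                                   atol=1e-6)
        np.testing.assert_array_equal(loaded.genotypes.dosages, g.dosages)
        assert list(loaded.genotypes.snps["pos"]) == list(g.snps["pos"])
        assert len(loaded.pedigree.trios()) == len(ped.trios())
        pd.testing.assert_frame_equal(
            loaded.fragments.records.sort_index(axis=1),
            frags.records.sort_index(axis=1))

    def test_truth_roundtrip(self, demo_cohort, tmp_path):
        eff, ped, g, m, truth, frags = demo_cohort
        pio.write_truth_json(truth, tmp_path / "truth.json")
        loaded = pio.read_truth_json(tmp_path / "truth.json")
        assert loaded.snp_cpg_pairs == truth.snp_cpg_pairs
        assert loaded.cis_pairs == truth.cis_pairs
        np.testing.assert_allclose(loaded.baseline, truth.baseline)
        assert loaded.allele_meth_probs == truth.allele_meth_probs

    def test_missing_values_roundtrip_as_na(self, tmp_path):
        from .conftest import make_matrix
        m = make_matrix([[0.5, np.nan], [np.nan, 0.25]])
        pio.write_methylation_tsv(m, tmp_path / "m.tsv")
        text = (tmp_path / "m.tsv").read_text()
        assert "NA" in text
        loaded = pio.read_methylation_tsv(tmp_path / "m.tsv")
        np.testing.assert_array_equal(np.isnan(loaded.values),
                                      np.isnan(m.values))


class TestValidation:
    def test_child_with_absent_parent_is_fatal(self):
        df = pd.DataFrame({
            "sample_id": ["kid"], "family_id": ["f1"],
            "father_id": ["ghost"], "mother_id": [None], "sex": [1]})
        with pytest.raises(ValueError, match="ghost"):
            PedigreeSet(df)

    def test_out_of_range_fraction_rejected_with_line(self, tmp_path, caplog):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\tstrand\ts0.frac\ts0.depth\n"
                        "chr1\t100\t+\t0.5\t30\n"
                        "chr1\t200\t+\t1.2\t30\n")
        with caplog.at_level("WARNING"):
            m = pio.read_methylation_tsv(path)
        assert m.n_sites == 1
        assert any("line 3" in r.message for r in caplog.records)

    def test_zero_sample_overlap_is_fatal(self, demo_cohort, tmp_path):
        eff, ped, g, m, truth, frags = demo_cohort
        paths = write_study(Study(ped, g, m), tmp_path)
        other = m.subset_samples(m.samples[:2])
        other = type(m)(other.sites, ["x1", "x2"], other.values, other.depths)
        pio.write_methylation_tsv(other, tmp_path / "other.tsv")
        with pytest.raises(ValueError, match="shared"):
            load_study(paths["vcf"], paths["fam"], tmp_path / "other.tsv")

    def test_multiallelic_vcf_record_skipped(self, tmp_path, caplog):
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\n"
            "chr1\t100\tsnpA\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\n"
            "chr1\t200\tsnpB\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t1/2\n")
        with caplog.at_level("WARNING"):
            g = pio.read_vcf(vcf)
        assert g.n_snps == 1
        assert any("multi-allelic" in r.message for r in caplog.records)


class TestPipeline:
    @pytest.fixture()
    def study(self, demo_cohort):
        eff, ped, g, m, truth, frags = demo_cohort
        return Study(ped, g, m, frags)

    def fast_config(self, **kw):
        kw.setdefault("n_perm", 30)
        kw.setdefault("seed", 5)
        return AnalysisConfig(**kw)

    def test_smoke_emits_all_output_files(self, study, tmp_path):
        run_pipeline(study, self.fast_config(), tmp_path)
        for name in OUTPUT_FILES:
            assert (tmp_path / name).exists(), name
        assert (tmp_path / "summary.json").exists()

    def test_n_perm_zero_gives_asymptotic_only(self, study, tmp_path):
        res = run_pipeline(study, self.fast_config(n_perm=0), tmp_path)
        mq = res["mqtl"]
        assert len(mq) > 0
        assert mq["p_emp"].isna().all()
        assert mq["p_asym"].notna().all()

    def test_rerun_same_seed_is_byte_identical(self, study, tmp_path):
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        run_pipeline(study, self.fast_config(), out1)
        run_pipeline(study, self.fast_config(), out2)
        for name in OUTPUT_FILES + ("summary.json",):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes(), name

    def test_outputs_stamped_with_config_hash(self, study, tmp_path):
        config = self.fast_config()
        run_pipeline(study, config, tmp_path)
        head = (tmp_path / "mpo_results.tsv").read_text().splitlines()[0]
        assert config.hash() in head
        summary = json.loads((tmp_path / "summary.json").read_text())
        assert summary["config_hash"] == config.hash()


class TestCli:
    def test_simulate_then_run_all(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        r = runner.invoke(cli_main, ["simulate", "--n-families", "8",
                                     "--n-cpgs", "25", "--n-snps", "12",
                                     "--seed", "3",
                                     "--out-dir", str(sim_dir)])
        assert r.exit_code == 0, r.output
        out_dir = tmp_path / "res"
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("n_perm: 20\nseed: 3\n")
        r = runner.invoke(cli_main, [
            "run-all", "--vcf", str(sim_dir / "genotypes.vcf"),
            "--fam", str(sim_dir / "pedigree.fam"),
            "--meth", str(sim_dir / "methylation.tsv"),
            "--frags", str(sim_dir / "fragments.tsv"),
            "--config", str(cfg), "--out-dir", str(out_dir)])
        assert r.exit_code == 0, r.output
        assert (out_dir / "summary.json").exists()
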