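"""Readers/writers, pipeline orchestration, manifest and CLI."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from pleiopath import (
    LocusWindow,
    RunConfig,
    SimulationConfig,
    run_pipeline,
    simulate_dataset,
    simulate_genotypes,
)
from pleiopath.cli import main as cli_main
from pleiopath.io import (
    read_genotypes,
    read_phenotypes,
    read_vcf,
    write_genotypes,
    write_phenotypes,
    write_windows_bed,
)

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t1/1
1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t1/1\t0/1\t1/1\t1/1
1\t300\trs3\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\t0/0
"""


class TestGenotypeIO:
    def test_raw_tsv_roundtrip_with_missing(self, tmp_path):
        cfg = SimulationConfig(n_subjects=40, n_snps=6, seed=3)
        geno = simulate_genotypes(cfg)
        geno.dosages[2, 1] = np.nan
        path = tmp_path / "g.raw.tsv"
        write_genotypes(geno, path)
        back = read_genotypes(path)
        assert back == geno

    def test_malformed_dosage_names_line(self, tmp_path):
        path = tmp_path / "bad.raw.tsv"
        path.write_text("FID\tIID\trs1_G\na\ta\t0\nb\tb\t3\n")
        with pytest.raises(ValueError, match="line"):
            read_genotypes(path)

    def test_vcf_alt_minor_dosage(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_TEXT)
        geno = read_vcf(path)
        # rs1: ALT freq 3/8 < 0.5 -> ALT counted; 0/1 -> dosage 1
        assert geno.a_counted[0] == "G"
        assert geno.dosages[0, 0] == 1.0
        assert not geno.counted_is_ref[0]

    def test_vcf_ref_minor_is_flipped_and_flagged(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_TEXT)
        geno = read_vcf(path)
        # rs2: ALT freq 7/8 -> REF is minor; 0/1 becomes dosage 1 counting REF
        assert geno.counted_is_ref[1]
        assert geno.a_counted[1] == "A"
        assert geno.dosages[1, 1] == 1.0  # the 0/1 sample
        assert geno.dosages[0, 1] == 0.0  # 1/1 -> zero REF copies
        # empirical counted-allele frequency now the minor one
        assert geno.counted_allele_freq()[1] == pytest.approx(1 / 8)

    def test_vcf_missing_call_is_nan(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_TEXT)
        geno = read_vcf(path)
        assert np.isnan(geno.dosages[0, 2])

    def test_phenotype_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            {"subject_id": ["a", "b"], "SS": [1.0, np.nan], "age": [50.0, 61.5]}
        )
        path = tmp_path / "p.tsv"
        write_phenotypes(df, path)
        back = read_phenotypes(path)
        pd.testing.assert_frame_equal(back, df)

    def test_bed_export_is_zero_based_half_open(self, tmp_path):
        path = tmp_path / "w.bed"
        write_windows_bed([LocusWindow("1", 250_000, 850_000)], path)
        assert path.read_text() == "1\t249999\t850000\n"


def _pipeline_config(tmp_path, **overrides):
    sim = dict(
        n_subjects=1500, n_snps=30, n_pleiotropic=3, true_model=1,
        beta_g_m=-0.4, beta_g_y=0.8, beta_m_y=-0.5,
        outcome_type="binary", seed=17,
    )
    sim.update(overrides.pop("sim", {}))
    kwargs = dict(
        simulation=SimulationConfig(**sim),
        outcome="SS",
        window_pad=3000,
        n_boot=200,
        seed=5,
        output_dir=str(tmp_path / "out"),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


class TestPipeline:
    def test_end_to_end_discovers_and_mediates(self, tmp_path):
        config = _pipeline_config(tmp_path)
        result = run_pipeline(config)
        assert result.manifest["completed"]
        # strong simulated signal: GWAS peaks found and windows merged
        assert result.manifest["stages"]["gwas"]["n_significant"] >= 1
        declared = result.pathway_table[result.pathway_table["declared_pleiotropic"]]
        assert len(declared) >= 1
        assert set(declared["classification"]) <= {"horizontal", "vertical"}
        # mediated SNPs carry a typed result
        if len(result.mediation_table):
            assert set(result.mediation_table["mediation_type"]) <= {
                "complementary", "competitive", "indirect_only", "none",
            }
        for fname in (
            "manifest.json", "qc_report.tsv", "gwas_summary.tsv",
            "windows.tsv", "pathway_results.tsv", "mediation_results.tsv",
        ):
            assert (Path(config.output_dir) / fname).exists()

    def test_byte_identical_rerun(self, tmp_path):
        config = _pipeline_config(tmp_path, sim={"n_subjects": 800, "n_snps": 10})
        run_pipeline(config)
        out = Path(config.output_dir)
        snapshot = {p.name: p.read_bytes() for p in out.iterdir()}
        run_pipeline(config)
        again = {p.name: p.read_bytes() for p in out.iterdir()}
        assert snapshot == again

    def test_empty_gwas_path_completes(self, tmp_path):
        config = _pipeline_config(
            tmp_path,
            sim=dict(n_subjects=400, n_snps=10, n_pleiotropic=0,
                     beta_g_m=0.0, beta_g_y=0.0, beta_m_y=0.0),
        )
        result = run_pipeline(config)
        assert result.manifest["completed"]
        assert result.manifest["stages"]["gwas"]["n_significant"] == 0
        assert len(result.mediation_table) == 0

    def test_manifest_records_thresholds(self, tmp_path):
        config = _pipeline_config(tmp_path, sim={"n_subjects": 400, "n_snps": 5})
        result = run_pipeline(config)
        echo = result.manifest["config"]
        assert echo["gwas_threshold"] == 5e-8
        assert echo["fdr_target"] == 0.15
        assert echo["qc"]["maf_min"] == 0.01
        assert echo["ci_alpha"] == 0.05

    def test_config_requires_data_or_simulation(self):
        with pytest.raises(ValueError):
            RunConfig()

    def test_file_backed_run_matches_simulation_backed(self, tmp_path):
        """Loading the written TSVs reproduces the simulation-backed stages."""
        sim_cfg = SimulationConfig(
            n_subjects=600, n_snps=8, n_pleiotropic=2, true_model=0,
            beta_g_m=0.4, beta_g_y=0.6, outcome_type="binary", seed=23,
        )
        geno, pheno, _ = simulate_dataset(sim_cfg)
        gpath = tmp_path / "g.raw.tsv"
        ppath = tmp_path / "p.tsv"
        write_genotypes(geno, gpath)
        write_phenotypes(pheno, ppath)
        config = RunConfig(
            genotype_path=str(gpath), phenotype_path=str(ppath),
            outcome="SS", window_pad=2000, n_boot=200,
            output_dir=str(tmp_path / "out2"),
        )
        result = run_pipeline(config)
        assert result.manifest["completed"]
        assert result.genotypes.n_snps == 8


class TestCLI:
    def test_simulate_qc_gwas_chain(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim"
        r = runner.invoke(
            cli_main,
            ["simulate", "--n-subjects", "300", "--n-snps", "5",
             "--seed", "4", "--out-dir", str(out)],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            cli_main,
            ["qc", "--genotypes", str(out / "genotypes.raw.tsv"),
             "--out-dir", str(tmp_path / "qc")],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            cli_main,
            ["gwas", "--genotypes", str(out / "genotypes.raw.tsv"),
             "--phenotypes", str(out / "phenotypes.tsv"),
             "--outcome", "SS", "--out", str(tmp_path / "gwas.tsv")],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "gwas.tsv").exists()

    def test_run_all_from_yaml(self, tmp_path):
        cfg = {
            "simulation": dict(
                n_subjects=800, n_snps=10, n_pleiotropic=2, true_model=1,
                beta_g_m=-0.4, beta_g_y=0.9, beta_m_y=-0.5,
                outcome_type="binary", seed=31,
            ),
            "outcome": "SS",
            "window_pad": 2000,
            "n_boot": 200,
            "output_dir": str(tmp_path / "bundle"),
        }
        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        r = CliRunner().invoke(cli_main, ["run-all", "--config", str(cfg_path)])
        assert r.exit_code == 0, r.output
        manifest = json.loads((tmp_path / "bundle" / "manifest.json").read_text())
        assert manifest["completed"]
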