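"""End-to-end orchestration: simulate/load -> QC -> screen -> GWAS ->
pathway discovery -> mediation.

`run_pipeline` executes the stages in order, writes one TSV per stage
into the output directory plus a JSON run manifest (config echo,
package version, seeds, per-stage sample sizes and counts), and returns
everything in a :class:`PipelineResult`.  Outputs carry no timestamps
and all randomness is seeded, so identical configs reproduce
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    GWAS_P_THRESHOLD,
    WINDOW_PAD_BP,
    extend_regions,
    scan_snps,
    select_gwas_loci,
    snps_in_windows,
)
from .datatypes import GenotypeMatrix, LocusWindow
from .io import (
    load_config_file,
    read_genotypes,
    read_phenotypes,
    write_genotypes,
    write_table,
    write_windows_bed,
)
from .mediation import analyze_mediation
from .pathway import (
    BIC_TIE_TOL,
    CI_ALPHA,
    FDR_TARGET,
    identify_pleiotropic,
    results_to_frame,
    select_mediation_model,
    test_conditional_independence,
)
from .preprocess import (
    QCThresholds,
    apply_genotype_qc,
    derive_smoking_status,
    recode_cpd,
    screen_fa_measures,
)
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Defaults reproduce the study's analysis constants: QC at MAF 0.01 /
    HWE p 0.001 / SNP missingness 5% / subject missingness 2%, GWAS
    threshold 5e-8, ±250 kb windows, overall FDR 0.15 for step 1,
    0.05 for the conditional-independence and mediation tests, and CPD
    recoding into [0, 60] (applied during phenotype derivation).
    """

    genotype_path: str | None = None
    genotype_dialect: str = "raw-tsv"
    phenotype_path: str | None = None
    simulation: SimulationConfig | None = None
    outcome: str = "SS"  # "SS" or "CPD"
    qc: QCThresholds = dataclasses.field(default_factory=QCThresholds)
    gwas_threshold: float = GWAS_P_THRESHOLD
    window_pad: int = WINDOW_PAD_BP
    fdr_target: float = FDR_TARGET
    ci_alpha: float = CI_ALPHA
    mediation_alpha: float = 0.05
    fa_screen_alpha: float = 0.05
    inference_method: str = "bootstrap"
    n_boot: int = 1000
    tie_tol: float = BIC_TIE_TOL
    seed: int = 0
    output_dir: str = "pleiopath_out"

    def __post_init__(self) -> None:
        if self.simulation is None and (
            self.genotype_path is None or self.phenotype_path is None
        ):
            raise ValueError(
                "either a simulation block or both genotype_path and "
                "phenotype_path must be provided"
            )
        if self.outcome not in ("SS", "CPD"):
            raise ValueError("outcome must be 'SS' or 'CPD'")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        if "simulation" in data and data["simulation"] is not None:
            data["simulation"] = SimulationConfig(**data["simulation"])
        if "qc" in data and isinstance(data["qc"], dict):
            data["qc"] = QCThresholds(**data["qc"])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(load_config_file(path))

    def to_manifest(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


@dataclasses.dataclass
class PipelineResult:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    qc_report: pd.DataFrame
    fa_measures: list[str]
    gwas_summary: pd.DataFrame
    windows: list[LocusWindow]
    pathway_table: pd.DataFrame
    mediation_table: pd.DataFrame
    manifest: dict[str, Any]


def _write_manifest(manifest: dict[str, Any], out: Path) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n"
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage and write the result bundle to ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "pleiopath",
        "version": __version__,
        "config": config.to_manifest(),
        "stages": {},
        "completed": False,
    }

    def stage(name: str, **info: Any) -> None:
        manifest["stages"][name] = info
        log.info("stage %s: %s", name, info)
        _write_manifest(manifest, out)

    try:
        # ---- stage 0: data -------------------------------------------------
        if config.simulation is not None:
            geno, pheno, truth = simulate_dataset(config.simulation)
            (out / "truth.json").write_text(truth.to_json() + "\n")
            write_genotypes(geno, out / "genotypes.raw.tsv")
            write_table(pheno, out / "phenotypes.tsv")
        else:
            geno = read_genotypes(config.genotype_path, config.genotype_dialect)
            pheno = read_phenotypes(config.phenotype_path)
        stage("data", n_subjects=geno.n_subjects, n_snps=geno.n_snps)

        # ---- stage 1: phenotype derivation ---------------------------------
        if "smoking" in pheno.columns and "SS" not in pheno.columns:
            pheno = derive_smoking_status(pheno)
        if "CPD" in pheno.columns:
            pheno = pheno.assign(CPD=recode_cpd(pheno["CPD"]))
        if config.outcome not in pheno.columns:
            raise ValueError(
                f"outcome column {config.outcome!r} absent from phenotype table"
            )
        stage(
            "phenotypes",
            n_outcome_nonmissing=int(pheno[config.outcome].notna().sum()),
        )

        # ---- stage 2: genotype QC ------------------------------------------
        geno, report = apply_genotype_qc(geno, config.qc)
        keep = set(geno.subject_ids)
        pheno = pheno[pheno["subject_id"].isin(keep)].reset_index(drop=True)
        pheno = pheno.set_index("subject_id").loc[geno.subject_ids].reset_index()
        write_table(report.to_frame(), out / "qc_report.tsv")
        stage("qc", **dataclasses.asdict(report))

        # ---- stage 3: FA screen --------------------------------------------
        fa_measures = screen_fa_measures(
            pheno, config.outcome, alpha=config.fa_screen_alpha
        )
        write_table(pd.DataFrame({"fa_measure": fa_measures}), out / "fa_screen.tsv")
        stage("fa_screen", n_retained=len(fa_measures))
        if not fa_measures:
            log.warning("no FA measure passed the smoking screen")

        # ---- stage 4: GWAS + windows ---------------------------------------
        gwas = scan_snps(geno, pheno, config.outcome)
        write_table(gwas, out / "gwas_summary.tsv")
        loci = select_gwas_loci(gwas, config.gwas_threshold)
        peak_rows = gwas.set_index("snp_id").loc[loci]
        peaks = [
            LocusWindow(str(r["chr"]), int(r["bp"]), int(r["bp"]))
            for _, r in peak_rows.iterrows()
        ]
        windows = extend_regions(peaks, config.window_pad)
        write_table(
            pd.DataFrame(
                [(w.chrom, w.start_bp, w.end_bp) for w in windows],
                columns=["chr", "start_bp", "end_bp"],
            ),
            out / "windows.tsv",
        )
        write_windows_bed(windows, out / "windows.bed")
        cand_idx = snps_in_windows(geno, windows)
        stage(
            "gwas",
            threshold=config.gwas_threshold,
            n_significant=len(loci),
            n_windows=len(windows),
            n_candidate_snps=int(cand_idx.size),
        )
        if not len(loci):
            log.warning("no SNP passed the GWAS threshold; downstream tables empty")

        # ---- stage 5-7: pathway discovery ----------------------------------
        cand = geno.take_snps(cand_idx)
        all_results = []
        for fa in fa_measures:
            results = identify_pleiotropic(
                cand, pheno, fa, config.outcome,
                fdr_target=config.fdr_target, return_all=True,
            )
            declared = [r for r in results if r.declared_pleiotropic]
            for r in declared:
                r.ci_p, r.classification = test_conditional_independence(
                    cand, pheno, r.snp_id, fa, config.outcome,
                    alpha=config.ci_alpha,
                )
                if r.classification == "horizontal":
                    r.selected_model = 0
                elif r.classification == "vertical":
                    step3 = select_mediation_model(
                        cand, pheno, r.snp_id, fa, config.outcome,
                        tie_tol=config.tie_tol,
                    )
                    r.loglik_m1, r.loglik_m2 = step3.loglik_m1, step3.loglik_m2
                    r.bic_m1, r.bic_m2 = step3.bic_m1, step3.bic_m2
                    r.selected_model = step3.selected_model
            all_results.extend(results)
        pathway_table = results_to_frame(all_results)
        write_table(pathway_table, out / "pathway_results.tsv")
        n_decl = (
            int(pathway_table["declared_pleiotropic"].sum())
            if len(pathway_table)
            else 0
        )
        stage("pathway", n_pairs_tested=len(all_results), n_declared=n_decl)

        # ---- stage 8: mediation --------------------------------------------
        med_rows = []
        vertical = [
            r for r in all_results if r.selected_model in (1, 2)
        ]
        for i, r in enumerate(vertical):
            med = analyze_mediation(
                cand, pheno, r.snp_id, r.fa_measure, config.outcome,
                model_label=int(r.selected_model),
                method=config.inference_method,
                n_boot=config.n_boot,
                seed=(config.seed * 100003 + i) % (2**31),
                alpha=config.mediation_alpha,
            )
            med_rows.append(med.to_dict())
        mediation_table = pd.DataFrame(med_rows)
        write_table(mediation_table, out / "mediation_results.tsv")
        stage("mediation", n_snps=len(med_rows))

        manifest["completed"] = True
        _write_manifest(manifest, out)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(manifest, out)
        raise

    return PipelineResult(
        genotypes=geno,
        phenotypes=pheno,
        qc_report=report.to_frame(),
        fa_measures=fa_measures,
        gwas_summary=gwas,
        windows=windows,
        pathway_table=pathway_table,
        mediation_table=mediation_table,
        manifest=manifest,
    )
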