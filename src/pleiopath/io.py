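"""Readers and writers for dosage tables, phenotypes and configs.

Genotypes travel as PLINK ``.raw``-style dosage TSVs (``FID IID`` then
one column per SNP, named ``<snp_id>_<counted allele>``, missing = NA)
with an optional ``<stem>.snps.tsv`` sidecar carrying chromosome,
position and alleles.  VCF input is read through cyvcf2 when available.
All numeric output uses a fixed repr-based format so identical runs are
byte-identical.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import GenotypeMatrix, LocusWindow

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "read_vcf",
    "write_phenotypes",
    "read_phenotypes",
    "write_windows_bed",
    "write_table",
    "load_config_file",
]

FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV writer used for every tabular output."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="NA")


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a dosage TSV plus the ``.snps.tsv`` metadata sidecar."""
    path = Path(path)
    cols = {"FID": geno.subject_ids, "IID": geno.subject_ids}
    for j, sid in enumerate(geno.snp_ids):
        cols[f"{sid}_{geno.a_counted[j]}"] = geno.dosages[:, j]
    write_table(pd.DataFrame(cols), path)
    meta = pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "chr": geno.chrom,
            "bp": geno.pos,
            "a_counted": geno.a_counted,
            "a_other": geno.a_other,
        }
    )
    write_table(meta, path.with_suffix(path.suffix + ".snps.tsv"))


_RAW_SKIP = {"FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"}


def read_genotypes(path: str | Path, dialect: str = "raw-tsv") -> GenotypeMatrix:
    """Read genotypes from a dosage table or a VCF.

    ``dialect="raw-tsv"`` accepts both this package's minimal layout and
    full PLINK ``.raw`` headers (PAT/MAT/SEX/PHENOTYPE columns are
    skipped).  ``dialect="vcf"`` delegates to :func:`read_vcf`.
    """
    if dialect == "vcf":
        return read_vcf(path)
    if dialect != "raw-tsv":
        raise ValueError(f"unknown genotype dialect: {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    snp_cols = [c for c in df.columns if c not in _RAW_SKIP]
    snp_ids, counted = [], []
    for c in snp_cols:
        m = re.match(r"^(.*)_([ACGT0-9]+)$", c)
        if m:
            snp_ids.append(m.group(1))
            counted.append(m.group(2))
        else:
            snp_ids.append(c)
            counted.append("?")
    dosages = df[snp_cols].to_numpy(dtype=float)
    bad = np.flatnonzero(
        ~np.all(np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0)), axis=1)
    )
    if bad.size:
        raise ValueError(
            f"{path}: non-dosage values in data line(s) {(bad + 2).tolist()}"
        )
    m = len(snp_ids)
    chrom = np.array(["0"] * m, dtype=object)
    pos = np.arange(1, m + 1, dtype=np.int64)
    other = ["?"] * m
    sidecar = path.with_suffix(path.suffix + ".snps.tsv")
    if sidecar.exists():
        meta = pd.read_csv(sidecar, sep="\t", dtype={"chr": str})
        meta = meta.set_index("snp_id").loc[snp_ids]
        chrom = meta["chr"].astype(str).to_numpy(dtype=object)
        pos = meta["bp"].to_numpy(dtype=np.int64)
        counted = meta["a_counted"].astype(str).tolist()
        other = meta["a_other"].astype(str).tolist()
    iid = df["IID"] if "IID" in df.columns else df.iloc[:, 0]
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=snp_ids,
        chrom=chrom,
        pos=pos,
        a_counted=counted,
        a_other=other,
        subject_ids=iid.astype(str).tolist(),
    )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read diploid genotypes from a VCF as minor-allele dosages.

    ALT copies are counted first; where the sample ALT frequency
    exceeds 0.5 the REF allele is the minor allele and the dosage is
    flipped to count REF, recorded per SNP in ``counted_is_ref``.
    Mixed-ploidy records are unsupported.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading VCF requires cyvcf2 (install pleiopath[vcf])"
        ) from exc
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snp_ids, chrom, pos, ref_l, alt_l, rows = [], [], [], [], [], []
    for k, rec in enumerate(vcf):
        gts = np.asarray(rec.genotype.array())
        if gts.shape[1] != 3:  # two alleles + phase flag
            raise ValueError(
                f"{path}: record {rec.CHROM}:{rec.POS} is not diploid"
            )
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan  # missing calls
        dosage = alleles.sum(axis=1)
        if np.nanmax(dosage, initial=0.0) > 2.0:
            raise ValueError(
                f"{path}: multi-allelic genotype at {rec.CHROM}:{rec.POS}"
            )
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chrom.append(str(rec.CHROM))
        pos.append(rec.POS)
        ref_l.append(rec.REF)
        alt_l.append(rec.ALT[0] if rec.ALT else ".")
        rows.append(dosage)
    dosages = np.column_stack(rows) if rows else np.empty((len(subjects), 0))
    m = dosages.shape[1]
    with np.errstate(invalid="ignore"):
        alt_freq = np.nanmean(dosages, axis=0) / 2.0
    counted_is_ref = alt_freq > 0.5
    a_counted, a_other = [], []
    for j in range(m):
        if counted_is_ref[j]:
            dosages[:, j] = 2.0 - dosages[:, j]
            a_counted.append(ref_l[j])
            a_other.append(alt_l[j])
        else:
            a_counted.append(alt_l[j])
            a_other.append(ref_l[j])
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=snp_ids,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        a_counted=a_counted,
        a_other=a_other,
        subject_ids=subjects,
        counted_is_ref=counted_is_ref,
    )


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    write_table(pheno, path)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"subject_id": str})


def write_windows_bed(windows: list[LocusWindow], path: str | Path) -> None:
    """BED export: 0-based half-open, i.e. start-1 .. end."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start_bp - 1}\t{w.end_bp}\n")


def load_config_file(path: str | Path) -> dict:
    """Load a YAML (or JSON) key/value config file into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data
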