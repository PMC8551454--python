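"""Core in-memory containers.

Genotypes live in a :class:`GenotypeMatrix` (an n-subjects by m-SNPs
additive dosage array plus per-SNP metadata).  Phenotypes and covariates
are plain :class:`pandas.DataFrame` objects keyed by ``subject_id``; the
column conventions used throughout the package are:

``subject_id``
    string identifier, matches ``GenotypeMatrix.subject_ids``.
``SS``
    binary smoking status (1 = current smoker, 0 = never smoker; past
    smokers are missing).
``CPD``
    cigarettes per day among ever smokers, recoded into [0, 60].
``FA_*``
    fractional-anisotropy tract measures (continuous mediator columns).
``age``, ``sex``, and optionally ``bmi``, ``chip``, ``PC1..PC10``
    covariates.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "LocusWindow"]


@dataclasses.dataclass
class GenotypeMatrix:
    """Additive-coded genotype dosages with SNP metadata.

    ``dosages`` is float with values in {0, 1, 2} and NaN for missing
    calls; rows are subjects, columns SNPs.  Minor-allele dosage coding:
    ``a_counted`` is the allele whose copies are counted (normally the
    minor allele; readers flag when the counted allele is REF).
    """

    dosages: np.ndarray
    snp_ids: list[str]
    chrom: np.ndarray  # per-SNP chromosome labels (str)
    pos: np.ndarray  # per-SNP 1-based positions (int)
    a_counted: list[str]
    a_other: list[str]
    subject_ids: list[str]
    counted_is_ref: np.ndarray | None = None  # flag set by VCF reader

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, m = self.dosages.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match dosage rows")
        for name, val in (
            ("snp_ids", self.snp_ids),
            ("chrom", self.chrom),
            ("pos", self.pos),
            ("a_counted", self.a_counted),
            ("a_other", self.a_other),
        ):
            if len(val) != m:
                raise ValueError(f"{name} length does not match dosage columns")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Empirical minor-allele frequency per SNP over observed calls.

        The counted-allele frequency is folded at 0.5, i.e. the minor
        allele is re-identified from the sample.
        """
        with np.errstate(invalid="ignore"):
            f = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def counted_allele_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def snp_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subject_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def take_snps(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            a_counted=[self.a_counted[i] for i in idx],
            a_other=[self.a_other[i] for i in idx],
            subject_ids=list(self.subject_ids),
            counted_is_ref=None
            if self.counted_is_ref is None
            else self.counted_is_ref[idx],
        )

    def take_subjects(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            snp_ids=list(self.snp_ids),
            chrom=self.chrom,
            pos=self.pos,
            a_counted=list(self.a_counted),
            a_other=list(self.a_other),
            subject_ids=[self.subject_ids[i] for i in idx],
            counted_is_ref=self.counted_is_ref,
        )

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chr": self.chrom,
                "bp": self.pos,
                "a_counted": self.a_counted,
                "a_other": self.a_other,
                "maf": self.maf(),
                "missing_rate": self.snp_missing_rate(),
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.snp_ids == other.snp_ids
            and self.subject_ids == other.subject_ids
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and self.a_counted == other.a_counted
            and self.a_other == other.a_other
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


@dataclasses.dataclass(frozen=True)
class LocusWindow:
    """A genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp < 1:
            raise ValueError("start_bp must be >= 1")
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must not exceed end_bp")

    def __len__(self) -> int:
        return self.end_bp - self.start_bp + 1

    def contains(self, chrom: str, bp: int) -> bool:
        return str(chrom) == self.chrom and self.start_bp <= bp <= self.end_bp
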