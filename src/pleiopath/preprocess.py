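"""Genotype quality control and smoking/FA phenotype derivation.

QC filters follow the study's thresholds: drop SNPs with call-rate
failures (>5% missing), minor-allele frequency below 0.01, or
Hardy–Weinberg disequilibrium (chi-square p < 0.001), then drop subjects
with more than 2% missing genotypes.  Phenotype derivation builds the
binary smoking-status trait (current vs never, past smokers set
missing), caps cigarettes-per-day into [0, 60], and screens the
fractional-anisotropy tract measures for the smoking-reduced subset
(negative coefficient, p < 0.05).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import linear_fit
from .datatypes import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "apply_genotype_qc",
    "hwe_test",
    "derive_smoking_status",
    "recode_cpd",
    "screen_fa_measures",
]

log = logging.getLogger(__name__)

SMOKING_LEVELS = {"current": 1.0, "never": 0.0, "past": np.nan}
CPD_MIN_CODE, CPD_MAX_CODE = 0.0, 60.0


@dataclasses.dataclass(frozen=True)
class QCThresholds:
    """Variant/subject QC cutoffs; defaults are the study's values."""

    maf_min: float = 0.01
    hwe_p_min: float = 0.001
    snp_missing_max: float = 0.05
    subject_missing_max: float = 0.02

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must lie in [0, 1], got {v}")


@dataclasses.dataclass
class QCReport:
    n_snps_in: int
    n_subjects_in: int
    n_snps_missing_removed: int
    n_snps_maf_removed: int
    n_snps_hwe_removed: int
    n_subjects_removed: int
    n_snps_out: int
    n_subjects_out: int

    def to_frame(self) -> pd.DataFrame:
        d = dataclasses.asdict(self)
        return pd.DataFrame({"criterion": list(d), "count": list(d.values())})


def hwe_test(n0: int, n1: int, n2: int, method: str = "chisq") -> float:
    """Hardy–Weinberg equilibrium p-value from genotype counts.

    ``(n0, n1, n2)`` are counts of dosage 0/1/2 genotypes.  The default
    is the one-degree-of-freedom chi-square test of observed counts
    against the p^2 : 2pq : q^2 expectation with the allele frequency
    estimated from the sample.  ``method="exact"`` gives the exact
    conditional mid-p test (sum over heterozygote counts with the same
    allele counts), useful at low minor-allele counts.
    """
    n = n0 + n1 + n2
    if n == 0:
        return 1.0
    q = (n1 + 2 * n2) / (2 * n)  # counted-allele frequency
    p = 1.0 - q
    if q == 0.0 or q == 1.0:
        return 1.0  # monomorphic: nothing to test
    if method == "chisq":
        expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
        observed = np.array([n0, n1, n2], dtype=float)
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact_midp(n0, n1, n2)
    raise ValueError(f"unknown HWE method: {method!r}")


def _hwe_exact_midp(n0: int, n1: int, n2: int) -> float:
    """Exact conditional HWE test (mid-p), minor-allele heterozygosity tail."""
    n = n0 + n1 + n2
    n_minor = min(n1 + 2 * n2, n1 + 2 * n0)
    # heterozygote count has the parity of the minor-allele count
    het_values = np.arange(n_minor % 2, n_minor + 1, 2)
    logprob = np.empty(het_values.size)
    from scipy.special import gammaln

    for i, h in enumerate(het_values):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        logprob[i] = (
            h * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(hom_minor + 1)
            - gammaln(hom_major + 1)
            - (gammaln(2 * n + 1) - gammaln(n_minor + 1) - gammaln(2 * n - n_minor + 1))
        )
    prob = np.exp(logprob - logprob.max())
    prob /= prob.sum()
    obs_het = n1
    p_obs = prob[het_values == obs_het][0]
    return float(prob[prob < p_obs].sum() + 0.5 * prob[prob == p_obs].sum())


def apply_genotype_qc(
    geno: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    hwe_method: str = "chisq",
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply SNP-level filters (missingness, MAF, HWE — in that order),
    then the subject-level missingness filter.

    The filter order is part of the contract: SNP filters are evaluated
    on all input subjects, the subject filter on the surviving SNPs.
    Raises ``ValueError`` if nothing survives.
    """
    t = thresholds or QCThresholds()
    n_snps_in, n_subj_in = geno.n_snps, geno.n_subjects

    keep = geno.snp_missing_rate() <= t.snp_missing_max
    n_miss_removed = int((~keep).sum())
    g = geno.take_snps(np.flatnonzero(keep))

    keep = g.maf() >= t.maf_min
    n_maf_removed = int((~keep).sum())
    g = g.take_snps(np.flatnonzero(keep))

    hwe_p = np.empty(g.n_snps)
    for j in range(g.n_snps):
        col = g.dosages[:, j]
        col = col[~np.isnan(col)]
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        hwe_p[j] = hwe_test(n0, n1, n2, method=hwe_method)
    keep = hwe_p >= t.hwe_p_min
    n_hwe_removed = int((~keep).sum())
    g = g.take_snps(np.flatnonzero(keep))

    if g.n_snps == 0:
        raise ValueError("no SNPs survive QC filters")

    keep_subj = g.subject_missing_rate() <= t.subject_missing_max
    n_subj_removed = int((~keep_subj).sum())
    g = g.take_subjects(np.flatnonzero(keep_subj))
    if g.n_subjects == 0:
        raise ValueError("no subjects survive QC filters")

    report = QCReport(
        n_snps_in=n_snps_in,
        n_subjects_in=n_subj_in,
        n_snps_missing_removed=n_miss_removed,
        n_snps_maf_removed=n_maf_removed,
        n_snps_hwe_removed=n_hwe_removed,
        n_subjects_removed=n_subj_removed,
        n_snps_out=g.n_snps,
        n_subjects_out=g.n_subjects,
    )
    log.info(
        "genotype QC: %d/%d SNPs and %d/%d subjects retained",
        report.n_snps_out,
        n_snps_in,
        report.n_subjects_out,
        n_subj_in,
    )
    return g, report


def derive_smoking_status(
    pheno: pd.DataFrame, source: str = "smoking", target: str = "SS"
) -> pd.DataFrame:
    """Binary smoking status: current = 1, never = 0, past/missing = NaN.

    Past smokers are coded missing rather than dropped, so the same
    table still serves cigarettes-per-day analyses (which instead
    exclude never smokers).  Unrecognized category levels raise.
    """
    raw = pheno[source]
    levels = set(raw.dropna().astype(str).str.lower().unique())
    unknown = levels - set(SMOKING_LEVELS)
    if unknown:
        raise ValueError(
            f"unrecognized smoking category level(s): {sorted(unknown)}"
        )
    out = pheno.copy()
    mapped = raw.astype("string").str.lower().map(SMOKING_LEVELS)
    out[target] = mapped.astype(float)
    if out[target].isna().all():
        warnings.warn("derived smoking status is entirely missing", UserWarning)
    return out


def recode_cpd(cpd: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Cap cigarettes-per-day into [0, 60]: values < 1 become 0, values
    > 60 become 60; in-range values and missingness pass through."""
    arr = np.asarray(cpd, dtype=float)
    finite = arr[~np.isnan(arr)]
    if np.any(finite < 0):
        raise ValueError("cigarettes-per-day values must be nonnegative")
    out = arr.copy()
    out[out < 1.0] = CPD_MIN_CODE
    out[out > 60.0] = CPD_MAX_CODE
    if isinstance(cpd, pd.Series):
        return pd.Series(out, index=cpd.index, name=cpd.name)
    return out


def screen_fa_measures(
    pheno: pd.DataFrame,
    outcome: str,
    fa_columns: list[str] | None = None,
    covariates: tuple[str, ...] = ("age", "sex"),
    alpha: float = 0.05,
    adjusted: bool = True,
) -> list[str]:
    """Retain FA measures reduced by smoking (negative coefficient,
    p < ``alpha`` in the regression of FA on the smoking phenotype).

    ``adjusted=True`` (default) includes ``covariates`` in the screen;
    the unadjusted variant regresses FA on the smoking trait alone.
    Constant FA columns are skipped with a warning.  Names are returned
    in input order.
    """
    if fa_columns is None:
        fa_columns = [c for c in pheno.columns if c.startswith("FA")]
    if not fa_columns:
        raise ValueError("no FA measure columns found")
    covs = list(covariates) if adjusted else []
    retained: list[str] = []
    for col in fa_columns:
        sub = pheno[[col, outcome, *covs]].dropna()
        fa = sub[col].to_numpy(dtype=float)
        if sub.empty or np.ptp(fa) == 0.0:
            warnings.warn(f"FA measure {col!r} is constant or empty; skipped")
            continue
        X = np.column_stack(
            [np.ones(len(sub)), sub[outcome].to_numpy(dtype=float)]
            + [sub[c].to_numpy(dtype=float) for c in covs]
        )
        fit = linear_fit(X, fa, ["intercept", outcome, *covs])
        if fit[outcome] < 0.0 and fit.p_of(outcome) < alpha:
            retained.append(col)
    return retained
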