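"""Per-SNP association screening and locus/window selection.

Implements the GWAS-then-extend-regions design at desk scale: each SNP
is tested one at a time in a linear or logistic regression of the trait
on dosage plus covariates, genome-wide-significant SNPs (p < 5e-8 by
default) define peaks, and candidate regions are the peaks padded by
±250 kb with overlapping windows merged.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from ._glm import (
    CollinearityError,
    RegressionFit,
    linear_fit,
    logistic_fit,
)
from .datatypes import GenotypeMatrix, LocusWindow

__all__ = [
    "RegressionFit",
    "CollinearityError",
    "fit_snp_regression",
    "scan_snps",
    "select_gwas_loci",
    "extend_regions",
    "snps_in_windows",
    "GWAS_P_THRESHOLD",
    "WINDOW_PAD_BP",
]

log = logging.getLogger(__name__)

GWAS_P_THRESHOLD = 5e-8
WINDOW_PAD_BP = 250_000

# covariate set used when the columns exist; missing ones are dropped
# with a logged notice (synthetic tables usually carry only age/sex)
DEFAULT_GWAS_COVARIATES = (
    "age",
    "sex",
    "bmi",
    "chip",
    *[f"PC{i}" for i in range(1, 11)],
)


def _design(
    g_col: np.ndarray, y: np.ndarray, z: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack intercept/dosage/covariates and drop incomplete cases."""
    cols = [np.ones_like(g_col), g_col]
    if z is not None and z.size:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[0] != g_col.shape[0]:
            z = z.T
        cols.extend(z.T)
    X = np.column_stack(cols)
    mask = np.isfinite(X).all(axis=1) & np.isfinite(y)
    return X[mask], y[mask]


def fit_snp_regression(
    g_col: np.ndarray,
    y: np.ndarray,
    z: np.ndarray | None = None,
    family: str = "linear",
    covariate_names: Sequence[str] | None = None,
    start: np.ndarray | None = None,
) -> RegressionFit:
    """Regress a trait on one SNP's dosage plus covariates.

    Complete cases only; ``family`` is ``"linear"`` (ordinary least
    squares) or ``"logistic"`` (maximum likelihood, with convergence
    status on the returned fit).  Rank-deficient designs raise
    :class:`CollinearityError` naming the collinear columns.
    """
    g_col = np.asarray(g_col, dtype=float)
    y = np.asarray(y, dtype=float)
    X, yy = _design(g_col, y, z)
    k = X.shape[1]
    if covariate_names is None:
        covariate_names = [f"z{i}" for i in range(1, k - 1)]
    terms = ["intercept", "snp", *covariate_names]
    if family == "linear":
        return linear_fit(X, yy, terms)
    if family == "logistic":
        return logistic_fit(X, yy, terms, start=start)
    raise ValueError(f"unknown family: {family!r}")


def scan_snps(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = DEFAULT_GWAS_COVARIATES,
    family: str | None = None,
) -> pd.DataFrame:
    """Per-SNP association scan; returns the summary table
    ``snp_id, chr, bp, beta, se, p, n, converged``.

    ``family`` defaults to logistic when the outcome column is 0/1 and
    linear otherwise.  Covariate columns absent from the table are
    dropped with a logged notice.  Logistic scans are warm-started from
    the covariate-only fit.  Non-converged (e.g. separated) fits are
    kept in the table but flagged, and excluded from locus ranking.
    """
    covs = [c for c in covariates if c in pheno.columns]
    missing = [c for c in covariates if c not in pheno.columns]
    if missing:
        log.info("covariates not in phenotype table, skipped: %s", missing)
    y = pheno[outcome].to_numpy(dtype=float)
    if family is None:
        vals = np.unique(y[np.isfinite(y)])
        family = "logistic" if np.all(np.isin(vals, (0.0, 1.0))) else "linear"
    Z = pheno[covs].to_numpy(dtype=float) if covs else None

    start = None
    if family == "logistic":
        base_mask = np.isfinite(y)
        if Z is not None:
            base_mask &= np.isfinite(Z).all(axis=1)
        Xnull = (
            np.column_stack([np.ones(base_mask.sum()), Z[base_mask]])
            if Z is not None
            else np.ones((base_mask.sum(), 1))
        )
        null = logistic_fit(Xnull, y[base_mask], ["intercept", *covs])
        start = np.insert(null.coef, 1, 0.0)

    rows = []
    for j in range(geno.n_snps):
        try:
            fit = fit_snp_regression(
                geno.dosages[:, j], y, Z, family=family,
                covariate_names=covs, start=start,
            )
            rows.append(
                (
                    geno.snp_ids[j], geno.chrom[j], int(geno.pos[j]),
                    fit.snp_effect, fit.snp_se, fit.snp_p,
                    fit.n_used, fit.converged,
                )
            )
        except (CollinearityError, ValueError) as exc:
            log.warning("SNP %s not testable: %s", geno.snp_ids[j], exc)
            rows.append(
                (geno.snp_ids[j], geno.chrom[j], int(geno.pos[j]),
                 np.nan, np.nan, np.nan, 0, False)
            )
    return pd.DataFrame(
        rows, columns=["snp_id", "chr", "bp", "beta", "se", "p", "n", "converged"]
    )


def select_gwas_loci(
    summary: pd.DataFrame, threshold: float = GWAS_P_THRESHOLD
) -> list[str]:
    """SNPs with Wald p below ``threshold``, sorted by genomic position.

    Flagged (non-converged) fits are excluded from ranking.  An empty
    selection is a valid result.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    ok = summary[(summary["converged"]) & (summary["p"] < threshold)]
    ok = ok.sort_values(["chr", "bp"], kind="mergesort")
    return ok["snp_id"].tolist()


def extend_regions(
    peaks: Sequence[LocusWindow], pad: int = WINDOW_PAD_BP
) -> list[LocusWindow]:
    """Pad each peak window by ``pad`` bp on both sides (clipped at
    position 1) and merge overlapping windows per chromosome."""
    if pad < 0:
        raise ValueError("pad must be nonnegative")
    padded = [
        LocusWindow(w.chrom, max(1, w.start_bp - pad), w.end_bp + pad)
        for w in peaks
    ]
    merged: list[LocusWindow] = []
    for w in sorted(padded, key=lambda w: (w.chrom, w.start_bp, w.end_bp)):
        if merged and merged[-1].chrom == w.chrom and w.start_bp <= merged[-1].end_bp:
            prev = merged.pop()
            merged.append(
                LocusWindow(prev.chrom, prev.start_bp, max(prev.end_bp, w.end_bp))
            )
        else:
            merged.append(w)
    return merged


def snps_in_windows(
    geno: GenotypeMatrix, windows: Sequence[LocusWindow]
) -> np.ndarray:
    """Column indices of SNPs falling inside any window."""
    mask = np.zeros(geno.n_snps, dtype=bool)
    for w in windows:
        mask |= (
            (geno.chrom.astype(str) == w.chrom)
            & (geno.pos >= w.start_bp)
            & (geno.pos <= w.end_bp)
        )
    return np.flatnonzero(mask)
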