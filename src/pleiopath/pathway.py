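"""Three-step causal pathway discovery for pleiotropic variants.

For a candidate SNP set, a continuous imaging mediator M (an FA tract
measure) and a smoking phenotype Y (binary status or continuous
cigarettes-per-day), three causal structures compete:

* model 0 — horizontal pleiotropy: the SNP affects M and Y through
  independent paths; M and Y are conditionally independent given the
  SNP and covariates.
* model 1 — vertical, SNP -> M -> Y: M mediates the genetic effect on
  smoking.
* model 2 — vertical, SNP -> Y -> M: smoking mediates the genetic
  effect on brain structure.

Step 1 screens for SNPs associated with *both* traits, controlling the
overall false discovery rate over the composite null ("associated with
at most one trait") at 0.15.  Step 2 tests conditional independence of
M and Y given each SNP: if the mediator coefficient in the regression
of Y on (G, M, Z) is non-significant (p > 0.05), the SNP is horizontal;
otherwise vertical.  Step 3 chooses between the two vertical DAGs by
BIC = -2 log(L) + p log(n), where each model's likelihood is the product
of its two component regressions evaluated at the MLE; since the two
DAGs have exactly the same number of parameters, the BIC comparison
reduces to comparing maximized likelihoods.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._glm import RegressionFit, linear_fit, logistic_fit
from .datatypes import GenotypeMatrix

__all__ = [
    "PathwayResult",
    "identify_pleiotropic",
    "test_conditional_independence",
    "select_mediation_model",
    "fit_component_models",
    "FDR_TARGET",
    "CI_ALPHA",
    "BIC_TIE_TOL",
]

log = logging.getLogger(__name__)

FDR_TARGET = 0.15  # overall FDR for step-1 pleiotropy discovery
CI_ALPHA = 0.05  # conditional-independence significance level
BIC_TIE_TOL = 1e-6  # |delta BIC| below this is an undecidable tie

DEFAULT_COVARIATES = ("age", "sex")  # mediation-stage adjustment set


@dataclasses.dataclass
class PathwayResult:
    """Per-(SNP, FA measure) record accumulated across the three steps."""

    snp_id: str
    fa_measure: str
    outcome: str
    p_snp_fa: float = np.nan  # step 1: SNP–mediator association p
    p_snp_y: float = np.nan  # step 1: SNP–outcome association p
    p_max: float = np.nan  # composite-null p-value max(p_fa, p_y)
    q_pleiotropy: float = np.nan  # BH-adjusted p_max
    declared_pleiotropic: bool = False
    beta_snp_fa: float = np.nan
    beta_snp_y: float = np.nan
    ci_p: float = np.nan  # step 2: conditional-independence p
    classification: str = ""  # horizontal | vertical | indeterminate
    loglik_m1: float = np.nan
    loglik_m2: float = np.nan
    bic_m1: float = np.nan
    bic_m2: float = np.nan
    n_used: int = 0
    selected_model: int | str | None = None  # 0 | 1 | 2 | "indeterminate"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _family_of(y: np.ndarray) -> str:
    vals = np.unique(y[np.isfinite(y)])
    return "logistic" if vals.size and np.all(np.isin(vals, (0.0, 1.0))) else "linear"


def _complete_frame(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    snp_idx: np.ndarray,
    fa_measure: str,
    outcome: str,
    covariates: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Complete cases across mediator, outcome and covariates.

    SNP-level missingness is handled per fit; the trait/covariate mask
    is shared so every component regression of one joint model sees the
    same subjects.
    """
    M = pheno[fa_measure].to_numpy(dtype=float)
    Y = pheno[outcome].to_numpy(dtype=float)
    Z = pheno[list(covariates)].to_numpy(dtype=float)
    mask = np.isfinite(M) & np.isfinite(Y) & np.isfinite(Z).all(axis=1)
    G = geno.dosages[:, snp_idx]
    return G[mask], M[mask], Y[mask], Z[mask], mask


def identify_pleiotropic(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    fa_measure: str,
    outcome: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    fdr_target: float = FDR_TARGET,
    method: str = "max_p",
    return_all: bool = False,
) -> list[PathwayResult]:
    """Step 1: find SNPs associated with both the FA measure and the
    smoking phenotype, controlling the overall FDR.

    Per SNP, fits the linear regression of M on (G, Z) and the
    logistic/linear regression of Y on (G, Z).  The composite null
    "associated with at most one trait" is handled by the max-p
    statistic: p_max = max(p_fa, p_y) is a valid (conservative) p-value
    for the composite null, and Benjamini–Hochberg on the p_max list at
    ``fdr_target`` controls the overall FDR of the declared pleiotropic
    set.  ``method="intersection"`` instead applies BH to each trait
    separately and declares the intersection of the two discovery sets.

    Returns results for declared SNPs only (``return_all=True`` returns
    every SNP with its ``declared_pleiotropic`` flag).
    """
    if not 0.0 < fdr_target < 1.0:
        raise ValueError("fdr_target must lie in (0, 1)")
    if geno.n_snps == 0:
        log.info("step 1: zero candidate SNPs, nothing to test")
        return []
    all_idx = np.arange(geno.n_snps)
    G, M, Y, Z, _ = _complete_frame(
        pheno, geno, all_idx, fa_measure, outcome, covariates
    )
    family_y = _family_of(Y)
    n, m = G.shape
    covs = list(covariates)
    terms = ["intercept", "snp", *covs]

    # warm start for logistic scans: covariate-only fit
    start = None
    if family_y == "logistic":
        Xnull = np.column_stack([np.ones(n), Z])
        null = logistic_fit(Xnull, Y, ["intercept", *covs])
        start = np.insert(null.coef, 1, 0.0)

    p_fa = np.full(m, np.nan)
    p_y = np.full(m, np.nan)
    b_fa = np.full(m, np.nan)
    b_y = np.full(m, np.nan)
    for j in range(m):
        g = G[:, j]
        ok = np.isfinite(g)
        Xg = np.column_stack([np.ones(ok.sum()), g[ok], Z[ok]])
        try:
            fit_m = linear_fit(Xg, M[ok], terms)
            if family_y == "logistic":
                fit_y = logistic_fit(Xg, Y[ok], terms, start=start)
                if not fit_y.converged:
                    log.warning("step 1: logistic fit for %s did not converge",
                                geno.snp_ids[j])
                    continue
            else:
                fit_y = linear_fit(Xg, Y[ok], terms)
        except ValueError as exc:
            log.warning("step 1: SNP %s not testable: %s", geno.snp_ids[j], exc)
            continue
        p_fa[j], p_y[j] = fit_m.snp_p, fit_y.snp_p
        b_fa[j], b_y[j] = fit_m.snp_effect, fit_y.snp_effect

    testable = np.isfinite(p_fa) & np.isfinite(p_y)
    p_max = np.maximum(p_fa, p_y)
    q = np.full(m, np.nan)
    declared = np.zeros(m, dtype=bool)
    if testable.any():
        if method == "max_p":
            rej, q_bh, _, _ = multipletests(
                p_max[testable], alpha=fdr_target, method="fdr_bh"
            )
            declared[testable] = rej
            q[testable] = q_bh
        elif method == "intersection":
            rej_fa, q_fa, _, _ = multipletests(
                p_fa[testable], alpha=fdr_target, method="fdr_bh"
            )
            rej_y, q_y, _, _ = multipletests(
                p_y[testable], alpha=fdr_target, method="fdr_bh"
            )
            declared[testable] = rej_fa & rej_y
            q[testable] = np.maximum(q_fa, q_y)
        else:
            raise ValueError(f"unknown step-1 method: {method!r}")

    results = [
        PathwayResult(
            snp_id=geno.snp_ids[j],
            fa_measure=fa_measure,
            outcome=outcome,
            p_snp_fa=float(p_fa[j]),
            p_snp_y=float(p_y[j]),
            p_max=float(p_max[j]),
            q_pleiotropy=float(q[j]),
            declared_pleiotropic=bool(declared[j]),
            beta_snp_fa=float(b_fa[j]),
            beta_snp_y=float(b_y[j]),
            n_used=n,
        )
        for j in range(m)
    ]
    log.info(
        "step 1 (%s vs %s): %d/%d SNPs declared pleiotropic at FDR %.3g",
        fa_measure, outcome, int(declared.sum()), m, fdr_target,
    )
    if return_all:
        return results
    return [r for r in results if r.declared_pleiotropic]


def test_conditional_independence(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    snp_id: str,
    fa_measure: str,
    outcome: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = CI_ALPHA,
) -> tuple[float, str]:
    """Step 2: test FA–smoking association conditioning on one SNP.

    Fits the regression of Y on (G, M, Z) — logistic for a binary
    outcome, linear otherwise — and reads off the Wald p-value of the
    mediator coefficient.  p > ``alpha`` means the conditional
    independence of model 0 is tenable: classification "horizontal";
    otherwise "vertical".  A non-converged logistic fit yields
    ("indeterminate", NaN p).
    """
    j = geno.snp_ids.index(snp_id)
    G, M, Y, Z, _ = _complete_frame(
        pheno, geno, np.array([j]), fa_measure, outcome, covariates
    )
    g = G[:, 0]
    ok = np.isfinite(g)
    terms = ["intercept", "snp", "mediator", *covariates]
    X = np.column_stack([np.ones(ok.sum()), g[ok], M[ok], Z[ok]])
    if _family_of(Y) == "logistic":
        fit = logistic_fit(X, Y[ok], terms)
        if not fit.converged:
            log.warning("step 2: non-converged fit for %s; indeterminate", snp_id)
            return float("nan"), "indeterminate"
    else:
        fit = linear_fit(X, Y[ok], terms)
    ci_p = fit.p_of("mediator")
    return ci_p, ("horizontal" if ci_p > alpha else "vertical")


def fit_component_models(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    snp_id: str,
    fa_measure: str,
    outcome: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> dict[str, RegressionFit]:
    """Fit the four component regressions on one shared complete-case set.

    Keys follow the structural-equation roles:

    * ``"m_on_g"``  — M ~ G + Z (linear)
    * ``"y_on_g"``  — Y ~ G + Z (logistic/linear)
    * ``"y_on_gm"`` — Y ~ G + M + Z (logistic/linear)
    * ``"m_on_gy"`` — M ~ G + Y + Z (linear)

    Model 1's joint likelihood is m_on_g x y_on_gm; model 2's is
    y_on_g x m_on_gy.
    """
    j = geno.snp_ids.index(snp_id)
    G, M, Y, Z, _ = _complete_frame(
        pheno, geno, np.array([j]), fa_measure, outcome, covariates
    )
    g = G[:, 0]
    ok = np.isfinite(g)
    g, M, Y, Z = g[ok], M[ok], Y[ok], Z[ok]
    one = np.ones(g.shape[0])
    covs = list(covariates)
    family_y = _family_of(Y)
    yfit = linear_fit if family_y == "linear" else logistic_fit

    Xg = np.column_stack([one, g, Z])
    Xgm = np.column_stack([one, g, M, Z])
    Xgy = np.column_stack([one, g, Y, Z])
    return {
        "m_on_g": linear_fit(Xg, M, ["intercept", "snp", *covs]),
        "y_on_g": yfit(Xg, Y, ["intercept", "snp", *covs]),
        "y_on_gm": yfit(Xgm, Y, ["intercept", "snp", "mediator", *covs]),
        "m_on_gy": linear_fit(Xgy, M, ["intercept", "snp", "outcome", *covs]),
    }


def select_mediation_model(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    snp_id: str,
    fa_measure: str,
    outcome: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    tie_tol: float = BIC_TIE_TOL,
    fits: dict[str, RegressionFit] | None = None,
) -> PathwayResult:
    """Step 3: pick the better vertical DAG by BIC.

    The two joint log-likelihoods add the component fits (model 1:
    M|G,Z plus Y|G,M,Z; model 2: Y|G,Z plus M|G,Y,Z); both joints have
    the same parameter count, so BIC = -2 log(L) + p log(n) differs only
    through the likelihood term and the smaller BIC wins.  Ties within
    ``tie_tol`` and component-fit failures come back "indeterminate".
    """
    result = PathwayResult(snp_id=snp_id, fa_measure=fa_measure, outcome=outcome)
    try:
        if fits is None:
            fits = fit_component_models(
                geno, pheno, snp_id, fa_measure, outcome, covariates
            )
    except ValueError as exc:
        log.warning("step 3: component fit failed for %s: %s", snp_id, exc)
        result.selected_model = "indeterminate"
        result.classification = "indeterminate"
        return result
    bad = [k for k, f in fits.items() if not f.converged]
    if bad:
        log.warning("step 3: non-converged component fit(s) %s for %s", bad, snp_id)
        result.selected_model = "indeterminate"
        result.classification = "indeterminate"
        return result

    n = fits["m_on_g"].n_used
    ll1 = fits["m_on_g"].log_likelihood + fits["y_on_gm"].log_likelihood
    ll2 = fits["y_on_g"].log_likelihood + fits["m_on_gy"].log_likelihood
    p1 = fits["m_on_g"].n_parameters + fits["y_on_gm"].n_parameters
    p2 = fits["y_on_g"].n_parameters + fits["m_on_gy"].n_parameters
    assert p1 == p2, "the two mediation DAGs must have equal parameter counts"
    bic1 = -2.0 * ll1 + p1 * np.log(n)
    bic2 = -2.0 * ll2 + p2 * np.log(n)

    result.loglik_m1, result.loglik_m2 = float(ll1), float(ll2)
    result.bic_m1, result.bic_m2 = float(bic1), float(bic2)
    result.n_used = n
    result.classification = "vertical"
    if abs(bic1 - bic2) < tie_tol:
        result.selected_model = "indeterminate"
    else:
        result.selected_model = 1 if bic1 < bic2 else 2
    return result


def results_to_frame(results: Sequence[PathwayResult]) -> pd.DataFrame:
    """Flatten pathway results into the per-(SNP, FA) output table."""
    if not results:
        return pd.DataFrame(
            columns=[f.name for f in dataclasses.fields(PathwayResult)]
        )
    return pd.DataFrame([r.to_dict() for r in results])
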