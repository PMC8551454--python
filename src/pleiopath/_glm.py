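"""Lightweight regression engine for per-SNP screens.

Closed-form OLS and Newton–Raphson logistic regression tuned for the
many-small-fits workload of genome-wide screens (thousands of fits of a
handful of columns).  Coefficients, standard errors and log-likelihoods
agree with statsmodels to numerical precision; the test suite asserts
this against statsmodels as an independent oracle.

Log-likelihood conventions
--------------------------
Linear fits report the Gaussian *profile* log-likelihood with the MLE
variance (residual sum of squares divided by n, not n - k), so that
joint likelihoods assembled from component fits are genuine maximized
likelihoods and BIC comparisons between models with equal parameter
counts reduce exactly to likelihood comparisons.  Standard errors and
p-values for linear fits use the unbiased variance and Student-t
reference, matching ordinary OLS inference.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RegressionFit",
    "CollinearityError",
    "SeparationError",
    "linear_fit",
    "logistic_fit",
    "check_design",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


class SeparationError(RuntimeError):
    """Logistic fit diverged, consistent with (quasi-)complete separation."""


@dataclasses.dataclass
class RegressionFit:
    """A fitted linear or logistic regression.

    Parameters are stored positionally alongside ``terms``; the
    convention throughout the package is ``["intercept", "<focal>",
    *covariates]`` where the focal term is the SNP dosage (or, for
    conditional models, the dosage followed by the mediator).

    ``n_parameters`` counts the intercept plus every slope, plus one for
    the residual variance of linear fits, so that likelihood-based
    comparisons between joint models account for every estimated
    quantity identically.
    """

    terms: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    log_likelihood: float
    n_used: int
    n_parameters: int
    family: str  # "linear" | "logistic"
    residual_sd: float | None = None
    converged: bool = True
    n_iter: int = 0

    def __getitem__(self, term: str) -> float:
        return float(self.coef[self.terms.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def p_of(self, term: str) -> float:
        return float(self.pvalues[self.terms.index(term)])

    @property
    def intercept(self) -> float:
        return self["intercept"]

    @property
    def snp_effect(self) -> float:
        return float(self.coef[1])

    @property
    def snp_se(self) -> float:
        return float(self.se[1])

    @property
    def snp_p(self) -> float:
        return float(self.pvalues[1])

    @property
    def covariate_effects(self) -> dict[str, float]:
        return {t: float(c) for t, c in zip(self.terms[2:], self.coef[2:])}


def check_design(X: np.ndarray, terms: Sequence[str]) -> None:
    """Raise :class:`CollinearityError` naming collinear columns.

    A column is flagged when it adds (numerically) nothing beyond the
    columns to its left, detected from the diagonal of the R factor of
    a pivoted-free QR decomposition.
    """
    n, k = X.shape
    if n < k:
        raise CollinearityError(
            f"design has {n} rows for {k} columns; more complete cases needed"
        )
    R = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(R))
    scale = np.maximum(np.linalg.norm(X, axis=0), 1e-300)
    bad = [terms[j] for j in range(k) if diag[j] <= 1e-10 * scale[j]]
    if bad:
        raise CollinearityError(
            "rank-deficient design; collinear column(s): " + ", ".join(bad)
        )


def linear_fit(X: np.ndarray, y: np.ndarray, terms: Sequence[str]) -> RegressionFit:
    """Ordinary least squares with profile-likelihood bookkeeping."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    check_design(X, terms)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} complete cases, got {n}")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    df = n - k
    sigma2_hat = rss / df  # unbiased, for Wald inference
    sigma2_mle = rss / n  # MLE, for the profile likelihood
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2_hat * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    if sigma2_mle <= 0.0:
        sigma2_mle = np.finfo(float).tiny
    ll = -0.5 * n * (_LOG2PI + np.log(sigma2_mle) + 1.0)
    return RegressionFit(
        terms=tuple(terms),
        coef=coef,
        se=se,
        pvalues=pvals,
        log_likelihood=float(ll),
        n_used=n,
        n_parameters=k + 1,  # slopes + intercept + residual variance
        family="linear",
        residual_sd=float(np.sqrt(sigma2_hat)),
    )


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    terms: Sequence[str],
    start: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> RegressionFit:
    """Maximum-likelihood logistic regression by damped Newton–Raphson.

    ``start`` allows warm-starting per-SNP scans from the covariate-only
    fit, which roughly halves the iteration count.  A fit whose
    coefficients run away (|beta| > 30 on standardized-scale designs is
    far beyond any plausible odds ratio) is returned with
    ``converged=False`` so callers can exclude it from ranking.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    check_design(X, terms)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} complete cases, got {n}")
    beta = np.zeros(k) if start is None else np.array(start, dtype=float)

    def negll(b: np.ndarray) -> float:
        eta = X @ b
        # log(1 + e^eta) computed stably
        return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)

    ll_prev = -negll(beta)
    converged = False
    H = None
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the likelihood monotone near separation
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            ll_cand = -negll(cand)
            if ll_cand >= ll_prev - 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        ll_new = -negll(beta)
        if np.max(np.abs(lam * step)) < tol or abs(ll_new - ll_prev) < 1e-12:
            ll_prev = ll_new
            converged = True
            break
        ll_prev = ll_new
    if np.max(np.abs(beta)) > 30.0 or not np.all(np.isfinite(beta)):
        converged = False

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return RegressionFit(
        terms=tuple(terms),
        coef=beta,
        se=se,
        pvalues=pvals,
        log_likelihood=float(ll_prev),
        n_used=n,
        n_parameters=k,
        family="logistic",
        converged=converged,
        n_iter=it,
    )
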