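"""Mediation effect decomposition, indirect-effect inference and typing.

Once step 3 has fixed a vertical model, the genetic effect on the
outcome splits into a direct path and an indirect path through the
mediator (product of coefficients):

model 1 (SNP -> FA -> smoking)
    direct   = coefficient of G in  Y ~ G + M + Z
    indirect = (G coefficient in M ~ G + Z) x (M coefficient in Y ~ G + M + Z)
    total    = coefficient of G in  Y ~ G + Z
model 2 (SNP -> smoking -> FA)
    direct   = coefficient of G in  M ~ G + Y + Z
    indirect = (G coefficient in Y ~ G + Z) x (Y coefficient in M ~ G + Y + Z)
    total    = coefficient of G in  M ~ G + Z

For all-linear fits with a shared covariate set, total = direct +
indirect exactly (ordinary least-squares algebra).  With a logistic
component the products live on the log-odds scale and additivity holds
only approximately (non-collapsibility).

Significance of the indirect effect comes from either the Sobel normal
approximation or a nonparametric subject-level bootstrap (percentile
interval; default).  Mediation type follows the usual sign/significance
typology: complementary (both effects significant, same sign),
competitive (both significant, opposite signs), indirect-only
(significant indirect, non-significant direct), or none.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats

from ._glm import RegressionFit, linear_fit, logistic_fit
from .datatypes import GenotypeMatrix
from .pathway import DEFAULT_COVARIATES, _complete_frame, _family_of

__all__ = [
    "MediationResult",
    "decompose_effects",
    "test_indirect_effect",
    "classify_mediation",
    "analyze_mediation",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class MediationResult:
    snp_id: str
    fa_measure: str
    outcome: str
    model_label: int
    direct_effect: float
    direct_se: float
    direct_p: float
    indirect_effect: float
    total_effect: float
    indirect_ci: tuple[float, float] | None = None
    indirect_p: float = np.nan
    method: str = ""
    mediation_type: str = ""
    n_boot: int = 0
    n_redrawn: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        ci = d.pop("indirect_ci")
        d["indirect_lo"] = np.nan if ci is None else ci[0]
        d["indirect_hi"] = np.nan if ci is None else ci[1]
        return d


def _component_keys(model_label: int) -> tuple[str, str, str, str]:
    """(exposure-eq, conditional-eq, total-eq) fit keys plus mediator term."""
    if model_label == 1:
        return "m_on_g", "y_on_gm", "y_on_g", "mediator"
    if model_label == 2:
        return "y_on_g", "m_on_gy", "m_on_g", "outcome"
    raise ValueError("model_label must be 1 or 2")


def decompose_effects(
    fits: dict[str, RegressionFit],
    model_label: int,
    snp_id: str = "",
    fa_measure: str = "",
    outcome: str = "",
) -> MediationResult:
    """Direct/indirect/total point estimates for the chosen model.

    ``fits`` is the component-fit dictionary from
    :func:`pleiopath.pathway.fit_component_models`.  A missing component
    raises with the name of the equation that is absent.
    """
    first_key, cond_key, total_key, med_term = _component_keys(model_label)
    for key in (first_key, cond_key, total_key):
        if key not in fits:
            raise KeyError(f"missing component fit {key!r} for model {model_label}")
    first = fits[first_key]
    cond = fits[cond_key]
    a, se_a = first.snp_effect, first.snp_se
    b, se_b = cond[med_term], cond.se_of(med_term)
    return MediationResult(
        snp_id=snp_id,
        fa_measure=fa_measure,
        outcome=outcome,
        model_label=model_label,
        direct_effect=cond.snp_effect,
        direct_se=cond.snp_se,
        direct_p=cond.snp_p,
        indirect_effect=a * b,
        total_effect=fits[total_key].snp_effect,
    )


def _sobel(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Sobel z statistic and two-sided p for the product a*b."""
    var = a * a * se_b * se_b + b * b * se_a * se_a
    if var <= 0.0:
        return 0.0, 1.0
    z = a * b / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def test_indirect_effect(
    geno: GenotypeMatrix,
    pheno,
    snp_id: str,
    fa_measure: str,
    outcome: str,
    model_label: int,
    covariates=DEFAULT_COVARIATES,
    method: str = "bootstrap",
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    fits: dict[str, RegressionFit] | None = None,
) -> MediationResult:
    """Interval and p-value for the indirect (product) effect.

    ``method="sobel"`` uses the delta-method normal approximation;
    ``method="bootstrap"`` (default) resamples subjects with
    replacement, refits the two component regressions per resample and
    takes the percentile interval of the product.  Bootstrap p-values
    are the smallest two-sided level at which the percentile interval
    excludes zero.  Resamples with a degenerate binary outcome are
    redrawn (count recorded on the result).
    """
    from .pathway import fit_component_models

    if fits is None:
        fits = fit_component_models(
            geno, pheno, snp_id, fa_measure, outcome, covariates
        )
    result = decompose_effects(fits, model_label, snp_id, fa_measure, outcome)
    first_key, cond_key, _, med_term = _component_keys(model_label)
    a, se_a = fits[first_key].snp_effect, fits[first_key].snp_se
    b, se_b = fits[cond_key][med_term], fits[cond_key].se_of(med_term)

    if method == "sobel":
        z, p = _sobel(a, se_a, b, se_b)
        half = stats.norm.ppf(0.5 + ci_level / 2.0) * np.sqrt(
            a * a * se_b * se_b + b * b * se_a * se_a
        )
        result.indirect_ci = (result.indirect_effect - half, result.indirect_effect + half)
        result.indirect_p = p
        result.method = "sobel"
        return result
    if method != "bootstrap":
        raise ValueError(f"unknown inference method: {method!r}")
    if n_boot < 200:
        raise ValueError("bootstrap needs n_boot >= 200")

    j = geno.snp_ids.index(snp_id)
    G, M, Y, Z, _ = _complete_frame(
        pheno, geno, np.array([j]), fa_measure, outcome, covariates
    )
    g = G[:, 0]
    ok = np.isfinite(g)
    g, M, Y, Z = g[ok], M[ok], Y[ok], Z[ok]
    n = g.shape[0]
    covs = list(covariates)
    family_y = _family_of(Y)
    rng = np.random.default_rng(seed)
    products = np.empty(n_boot)
    n_redrawn = 0
    for t in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            yb = Y[idx]
            if family_y == "logistic" and yb.min() == yb.max():
                n_redrawn += 1
                continue
            break
        gb, mb, zb = g[idx], M[idx], Z[idx]
        one = np.ones(n)
        if model_label == 1:
            fit_a = linear_fit(
                np.column_stack([one, gb, zb]), mb, ["intercept", "snp", *covs]
            )
            yfit = logistic_fit if family_y == "logistic" else linear_fit
            fit_b = yfit(
                np.column_stack([one, gb, mb, zb]),
                yb,
                ["intercept", "snp", "mediator", *covs],
            )
            products[t] = fit_a.snp_effect * fit_b["mediator"]
        else:
            yfit = logistic_fit if family_y == "logistic" else linear_fit
            fit_a = yfit(
                np.column_stack([one, gb, zb]), yb, ["intercept", "snp", *covs]
            )
            fit_b = linear_fit(
                np.column_stack([one, gb, yb, zb]),
                mb,
                ["intercept", "snp", "outcome", *covs],
            )
            products[t] = fit_a.snp_effect * fit_b["outcome"]
    lo_q = (1.0 - ci_level) / 2.0
    result.indirect_ci = (
        float(np.quantile(products, lo_q)),
        float(np.quantile(products, 1.0 - lo_q)),
    )
    # two-sided percentile-bootstrap p: level at which 0 hits the interval
    frac_pos = float(np.mean(products > 0.0))
    result.indirect_p = float(min(1.0, 2.0 * min(frac_pos, 1.0 - frac_pos)))
    result.method = "bootstrap"
    result.n_boot = n_boot
    result.n_redrawn = n_redrawn
    if n_redrawn:
        log.info("bootstrap: %d degenerate resamples redrawn", n_redrawn)
    return result


def classify_mediation(
    result: MediationResult, alpha: float = 0.05
) -> str:
    """Sign/significance typology of an inferred mediation effect.

    complementary — indirect and direct both significant, same sign;
    competitive — both significant, opposite signs; indirect_only —
    indirect significant, direct not; none — indirect not significant.
    The label is also written back onto ``result``.
    """
    indirect_sig = (
        result.indirect_p < alpha
        if np.isfinite(result.indirect_p)
        else (
            result.indirect_ci is not None
            and not (result.indirect_ci[0] <= 0.0 <= result.indirect_ci[1])
        )
    )
    if not indirect_sig:
        label = "none"
    elif result.direct_p >= alpha:
        label = "indirect_only"
    elif np.sign(result.indirect_effect) == np.sign(result.direct_effect):
        label = "complementary"
    else:
        label = "competitive"
    result.mediation_type = label
    return label


def analyze_mediation(
    geno: GenotypeMatrix,
    pheno,
    snp_id: str,
    fa_measure: str,
    outcome: str,
    model_label: int,
    covariates=DEFAULT_COVARIATES,
    method: str = "bootstrap",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> MediationResult:
    """Decompose, test and classify in one call."""
    result = test_indirect_effect(
        geno, pheno, snp_id, fa_measure, outcome, model_label,
        covariates=covariates, method=method, n_boot=n_boot, seed=seed,
    )
    classify_mediation(result, alpha=alpha)
    return result
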