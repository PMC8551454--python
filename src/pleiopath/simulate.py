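"""Synthetic genotype–mediator–outcome datasets under three causal models.

The generator emulates the study design this package analyses: an
additive-coded SNP panel (optionally with local LD), a continuous
brain-imaging mediator M (fractional anisotropy of a white-matter
tract), and a smoking outcome Y that is either binary status (logistic
link) or continuous cigarettes-per-day, with age and sex as shared
covariates.  Datasets are drawn from exactly one of three structural
models:

model 0 (horizontal pleiotropy)
    M = a_m + b_gm * G + g'Z + e_m,   Y ~ a_y + b_gy * G + g'Z (+ e_y)
    with M and Y conditionally independent given (G, Z).
model 1 (vertical, G -> M -> Y)
    M as above;  Y ~ a_y + b_gy * G + b_my * M + g'Z (+ e_y).
model 2 (vertical, G -> Y -> M)
    Y as in model 0;  M = a_m + b_gm * G + b_ym * Y + g'Z + e_m.

Every non-null ("pleiotropic") SNP contributes additively with the same
per-allele effect; all remaining SNPs are null for both traits.  The
ground truth is returned as a :class:`TruthRecord` so downstream error
rates can be scored against it.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_dataset",
    "replicate_seeds",
    "DegenerateOutcomeWarning",
]

AGE_RANGE = (40.0, 69.0)  # recruitment ages of the cohort being emulated
_AGE_CENTER = 0.5 * (AGE_RANGE[0] + AGE_RANGE[1])


class DegenerateOutcomeWarning(UserWarning):
    """Binary outcome came out all-0 or all-1."""


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Effect sizes are on the natural model scales: FA-units per allele
    for ``beta_g_m`` (with ``sigma_m = 1`` these read as SD/allele),
    log-odds or CPD-units per allele for ``beta_g_y``, and so on.
    ``beta_g_y`` is the direct genotype-to-outcome coefficient of the
    structural equation that generates Y under ``true_model`` (the
    marginal genotype effect under models 0/2, the mediator-adjusted
    direct effect under model 1).
    """

    n_subjects: int = 2000
    n_snps: int = 1
    maf_spectrum: float | Sequence[float] = 0.2
    ld_rho: float = 0.0
    true_model: int = 0
    beta_g_m: float = 0.0
    beta_g_y: float = 0.0
    beta_m_y: float = 0.0
    beta_y_m: float = 0.0
    sigma_m: float = 1.0
    sigma_y: float = 1.0
    outcome_type: str = "binary"
    n_pleiotropic: int = 1
    covariate_effects: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"age": -0.01, "sex": 0.1}
    )
    alpha_m: float = 0.0
    alpha_y: float | None = None  # default: logit(0.3) binary, 0 continuous
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_snps < 1:
            raise ValueError("n_subjects and n_snps must be positive")
        mafs = self.mafs()
        if np.any(mafs <= 0.0) or np.any(mafs > 0.5):
            raise ValueError("maf_spectrum entries must lie in (0, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.true_model not in (0, 1, 2):
            raise ValueError("true_model must be 0, 1 or 2")
        if self.outcome_type not in ("binary", "continuous"):
            raise ValueError("outcome_type must be 'binary' or 'continuous'")
        if self.true_model != 1 and self.beta_m_y != 0.0:
            raise ValueError("beta_m_y must be zero unless true_model == 1")
        if self.true_model != 2 and self.beta_y_m != 0.0:
            raise ValueError("beta_y_m must be zero unless true_model == 2")
        if not 0 <= self.n_pleiotropic <= self.n_snps:
            raise ValueError("n_pleiotropic must lie in [0, n_snps]")
        if self.sigma_m <= 0 or self.sigma_y <= 0:
            raise ValueError("residual standard deviations must be positive")

    def mafs(self) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(self.maf_spectrum, dtype=float))
        if arr.size == 1:
            arr = np.full(self.n_snps, float(arr[0]))
        if arr.size != self.n_snps:
            raise ValueError("maf_spectrum length must be 1 or n_snps")
        return arr

    def resolved_alpha_y(self) -> float:
        if self.alpha_y is not None:
            return float(self.alpha_y)
        # ~30% case prevalence for a binary smoking-status outcome
        return float(np.log(0.3 / 0.7)) if self.outcome_type == "binary" else 0.0


@dataclasses.dataclass
class TruthRecord:
    """Generating parameters of one simulated dataset (for scoring)."""

    true_model: int
    pleiotropic_snps: list[str]
    beta_g_m: float
    beta_g_y: float
    beta_m_y: float
    beta_y_m: float
    sigma_m: float
    sigma_y: float
    alpha_m: float
    alpha_y: float
    covariate_effects: dict[str, float]
    outcome_type: str
    outcome_name: str
    mediator_name: str
    seed: int

    def is_pleiotropic(self, snp_ids: Sequence[str]) -> np.ndarray:
        truth = set(self.pleiotropic_snps)
        return np.array([s in truth for s in snp_ids])

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        return cls(**json.loads(text))


def replicate_seeds(master_seed: int, n_replicates: int) -> list[int]:
    """Independent per-replicate seeds derived from one master seed.

    Spawned through :class:`numpy.random.SeedSequence` so each replicate
    has its own reproducible stream; returned as plain ints < 2**31.
    """
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n_replicates)]


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw an additive dosage matrix with optional local LD.

    Each of the two haplotypes is an independent latent Gaussian AR(1)
    process across SNPs (lag-one correlation ``ld_rho``); a haplotype
    carries the minor allele at SNP j when its latent value exceeds the
    (1 - MAF_j) normal quantile.  Dosage is the sum of the two
    haplotypes, so marginally each SNP is Binomial(2, MAF) — exact
    Hardy–Weinberg proportions — while neighbouring SNPs are correlated
    whenever ``ld_rho > 0``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_subjects, config.n_snps
    mafs = config.mafs()
    thresholds = stats.norm.ppf(1.0 - mafs)  # carrier prob = MAF
    rho = config.ld_rho
    dosage = np.zeros((n, m), dtype=float)
    for _hap in range(2):
        z = rng.standard_normal((n, m))
        if rho > 0.0 and m > 1:
            innov_sd = np.sqrt(1.0 - rho * rho)
            for j in range(1, m):
                z[:, j] = rho * z[:, j - 1] + innov_sd * z[:, j]
        dosage += (z > thresholds[None, :]).astype(float)

    snp_ids = [f"snp{j + 1:05d}" for j in range(m)]
    pos = 10_000 + 1_000 * np.arange(m, dtype=np.int64)
    return GenotypeMatrix(
        dosages=dosage,
        snp_ids=snp_ids,
        chrom=np.array(["1"] * m, dtype=object),
        pos=pos,
        a_counted=["G"] * m,
        a_other=["A"] * m,
        subject_ids=[f"S{i + 1:06d}" for i in range(n)],
    )


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord]:
    """Generate one dataset under the configured structural model.

    Returns the genotype matrix, a phenotype table with columns
    ``subject_id, age, sex, FA_ALIC_R, SS|CPD``, and the ground-truth
    record.  Age enters the structural equations centred at the midpoint
    of its range so intercepts are interpretable as values at mean age.
    """
    rng = np.random.default_rng(config.seed)
    geno = simulate_genotypes(config, rng=rng)
    n = config.n_subjects

    age = rng.uniform(*AGE_RANGE, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    g_age = float(config.covariate_effects.get("age", 0.0))
    g_sex = float(config.covariate_effects.get("sex", 0.0))
    z_eff = g_age * (age - _AGE_CENTER) + g_sex * sex

    idx_pleio = rng.choice(config.n_snps, size=config.n_pleiotropic, replace=False)
    idx_pleio.sort()
    # centred at the expected dosage sum (2*sum(MAF)) so the intercepts
    # keep their meaning (value/prevalence at the mean genotype) no
    # matter how many non-null SNPs contribute
    g_burden = geno.dosages[:, idx_pleio].sum(axis=1)
    g_burden = g_burden - 2.0 * float(np.sum(config.mafs()[idx_pleio]))

    alpha_y = config.resolved_alpha_y()
    eps_m = rng.standard_normal(n) * config.sigma_m

    def draw_y(eta: np.ndarray) -> np.ndarray:
        if config.outcome_type == "binary":
            y = (rng.random(n) < _expit(eta)).astype(float)
            if y.min() == y.max():
                warnings.warn(
                    "binary outcome is degenerate (all "
                    f"{int(y[0])}); linear predictor too extreme",
                    DegenerateOutcomeWarning,
                    stacklevel=3,
                )
            return y
        return eta + rng.standard_normal(n) * config.sigma_y

    if config.true_model == 0:
        M = config.alpha_m + config.beta_g_m * g_burden + z_eff + eps_m
        Y = draw_y(alpha_y + config.beta_g_y * g_burden + z_eff)
    elif config.true_model == 1:
        M = config.alpha_m + config.beta_g_m * g_burden + z_eff + eps_m
        Y = draw_y(
            alpha_y + config.beta_g_y * g_burden + config.beta_m_y * M + z_eff
        )
    else:  # model 2
        Y = draw_y(alpha_y + config.beta_g_y * g_burden + z_eff)
        M = (
            config.alpha_m
            + config.beta_g_m * g_burden
            + config.beta_y_m * Y
            + z_eff
            + eps_m
        )

    outcome_name = "SS" if config.outcome_type == "binary" else "CPD"
    pheno = pd.DataFrame(
        {
            "subject_id": geno.subject_ids,
            "age": age,
            "sex": sex,
            "FA_ALIC_R": M,
            outcome_name: Y,
        }
    )
    truth = TruthRecord(
        true_model=config.true_model,
        pleiotropic_snps=[geno.snp_ids[j] for j in idx_pleio],
        beta_g_m=config.beta_g_m,
        beta_g_y=config.beta_g_y,
        beta_m_y=config.beta_m_y,
        beta_y_m=config.beta_y_m,
        sigma_m=config.sigma_m,
        sigma_y=config.sigma_y,
        alpha_m=config.alpha_m,
        alpha_y=alpha_y,
        covariate_effects={"age": g_age, "sex": g_sex},
        outcome_type=config.outcome_type,
        outcome_name=outcome_name,
        mediator_name="FA_ALIC_R",
        seed=config.seed,
    )
    return geno, pheno, truth
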