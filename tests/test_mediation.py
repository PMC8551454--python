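"""Effect decomposition, indirect-effect inference, mediation typing."""

import numpy as np
import pytest

from pleiopath import (
    MediationResult,
    SimulationConfig,
    classify_mediation,
    decompose_effects,
    fit_component_models,
    simulate_dataset,
)
from pleiopath.mediation import _sobel
from pleiopath.mediation import test_indirect_effect as indirect_effect_test
from pleiopath.simulate import replicate_seeds


@pytest.fixture(scope="module")
def model1_linear():
    cfg = SimulationConfig(
        n_subjects=4000, n_snps=1, n_pleiotropic=1, true_model=1,
        beta_g_m=0.4, beta_g_y=0.1, beta_m_y=0.5,
        outcome_type="continuous", seed=55,
    )
    geno, pheno, truth = simulate_dataset(cfg)
    fits = fit_component_models(geno, pheno, "snp00001", "FA_ALIC_R", "CPD")
    return geno, pheno, truth, fits


class TestDecomposition:
    def test_linear_additivity_exact(self, model1_linear):
        """OLS algebra: the marginal slope equals direct + indirect when
        the covariate set is shared, to numerical precision."""
        *_, fits = model1_linear
        res = decompose_effects(fits, model_label=1)
        assert res.total_effect == pytest.approx(
            res.direct_effect + res.indirect_effect, abs=1e-8
        )

    def test_model2_roles_swapped(self, model1_linear):
        *_, fits = model1_linear
        res = decompose_effects(fits, model_label=2)
        # all-linear: additivity holds in the reverse factorization too
        assert res.total_effect == pytest.approx(
            res.direct_effect + res.indirect_effect, abs=1e-8
        )
        assert res.direct_effect == fits["m_on_gy"].snp_effect
        assert res.indirect_effect == pytest.approx(
            fits["y_on_g"].snp_effect * fits["m_on_gy"]["outcome"]
        )

    def test_zero_exposure_effect_gives_zero_indirect(self, model1_linear):
        *_, fits = model1_linear
        import copy

        fits = dict(fits)
        fits["m_on_g"] = copy.deepcopy(fits["m_on_g"])
        fits["m_on_g"].coef[1] = 0.0
        res = decompose_effects(fits, model_label=1)
        assert res.indirect_effect == 0.0

    def test_missing_component_named(self, model1_linear):
        *_, fits = model1_linear
        partial = {k: v for k, v in fits.items() if k != "y_on_gm"}
        with pytest.raises(KeyError, match="y_on_gm"):
            decompose_effects(partial, model_label=1)

    def test_binary_outcome_recovery_on_logodds_scale(self):
        """Model 2 with binary smoking mediator pathway: the indirect
        product on the linear-predictor scale recovers the generating
        product within 3 propagated SEs at n = 10,000."""
        cfg = SimulationConfig(
            n_subjects=10_000, n_snps=1, n_pleiotropic=1, true_model=2,
            beta_g_m=0.1, beta_g_y=0.3, beta_y_m=0.5,
            outcome_type="binary", seed=56,
        )
        geno, pheno, truth = simulate_dataset(cfg)
        fits = fit_component_models(geno, pheno, "snp00001", "FA_ALIC_R", "SS")
        res = decompose_effects(fits, model_label=2)
        a, se_a = fits["y_on_g"].snp_effect, fits["y_on_g"].snp_se
        b, se_b = fits["m_on_gy"]["outcome"], fits["m_on_gy"].se_of("outcome")
        se_prod = np.sqrt(a * a * se_b**2 + b * b * se_a**2)
        assert abs(res.indirect_effect - truth.beta_g_y * truth.beta_y_m) < 3 * se_prod
        assert abs(res.direct_effect - truth.beta_g_m) < 3 * fits["m_on_gy"].snp_se


class TestIndirectInference:
    def test_sobel_statistic_hand_formula(self):
        z, p = _sobel(0.4, 0.05, 0.5, 0.1)
        var = 0.4**2 * 0.1**2 + 0.5**2 * 0.05**2
        from scipy import stats

        assert z == pytest.approx(0.2 / np.sqrt(var))
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_bootstrap_seed_reproducible(self, model1_linear):
        geno, pheno, _, fits = model1_linear
        kw = dict(model_label=1, method="bootstrap", n_boot=200, seed=9, fits=fits)
        r1 = indirect_effect_test(geno, pheno, "snp00001", "FA_ALIC_R", "CPD", **kw)
        r2 = indirect_effect_test(geno, pheno, "snp00001", "FA_ALIC_R", "CPD", **kw)
        assert r1.indirect_ci == r2.indirect_ci
        assert r1.indirect_p == r2.indirect_p

    def test_bootstrap_requires_enough_resamples(self, model1_linear):
        geno, pheno, _, fits = model1_linear
        with pytest.raises(ValueError, match="n_boot"):
            indirect_effect_test(
                geno, pheno, "snp00001", "FA_ALIC_R", "CPD",
                model_label=1, n_boot=50,
            )

    def test_power_with_strong_effects(self):
        """Effects (0.3, 0.5) at n = 2000: the Sobel test essentially
        always rejects the null of no indirect effect."""
        rejections = 0
        for seed in replicate_seeds(303, 40):
            cfg = SimulationConfig(
                n_subjects=2000, n_snps=1, n_pleiotropic=1, true_model=1,
                beta_g_m=0.3, beta_g_y=0.0, beta_m_y=0.5,
                outcome_type="continuous", seed=seed,
            )
            geno, pheno, _ = simulate_dataset(cfg)
            res = indirect_effect_test(
                geno, pheno, "snp00001", "FA_ALIC_R", "CPD",
                model_label=1, method="sobel",
            )
            rejections += res.indirect_p < 0.05
        assert rejections == 40

    def test_null_product_rejection_conservative(self):
        """Both component effects zero: Sobel rejects well below the
        nominal level (the product-null is conservative)."""
        rejections = 0
        reps = 120
        for seed in replicate_seeds(404, reps):
            cfg = SimulationConfig(
                n_subjects=500, n_snps=1, n_pleiotropic=0,
                outcome_type="continuous", seed=seed,
            )
            geno, pheno, _ = simulate_dataset(cfg)
            res = indirect_effect_test(
                geno, pheno, "snp00001", "FA_ALIC_R", "CPD",
                model_label=1, method="sobel",
            )
            rejections += res.indirect_p < 0.05
        assert rejections / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_bootstrap_interval_covers_truth(self):
        """95% percentile intervals cover the true indirect effect at
        about the nominal rate (checked loosely over 40 replicates)."""
        covered = 0
        true_indirect = 0.3 * 0.5
        for seed in replicate_seeds(505, 40):
            cfg = SimulationConfig(
                n_subjects=1000, n_snps=1, n_pleiotropic=1, true_model=1,
                beta_g_m=0.3, beta_g_y=0.1, beta_m_y=0.5,
                outcome_type="continuous", seed=seed,
            )
            geno, pheno, _ = simulate_dataset(cfg)
            res = indirect_effect_test(
                geno, pheno, "snp00001", "FA_ALIC_R", "CPD",
                model_label=1, method="bootstrap", n_boot=300, seed=seed,
            )
            lo, hi = res.indirect_ci
            covered += lo <= true_indirect <= hi
        assert covered >= 33  # ~95% nominal with binomial noise at 40 reps


class TestClassification:
    @staticmethod
    def _result(indirect, indirect_p, direct, direct_p):
        return MediationResult(
            snp_id="s", fa_measure="FA", outcome="SS", model_label=1,
            direct_effect=direct, direct_se=0.1, direct_p=direct_p,
            indirect_effect=indirect, total_effect=direct + indirect,
            indirect_p=indirect_p,
        )

    @pytest.mark.parametrize(
        "indirect,indirect_p,direct,direct_p,expected",
        [
            (0.2, 0.001, 0.3, 0.001, "complementary"),
            (-0.2, 0.001, -0.3, 0.001, "complementary"),
            (-0.2, 0.001, 0.3, 0.001, "competitive"),
            (0.2, 0.001, -0.3, 0.001, "competitive"),
            (0.2, 0.001, 0.3, 0.4, "indirect_only"),
            (-0.2, 0.001, 0.3, 0.4, "indirect_only"),
            (0.2, 0.4, 0.3, 0.001, "none"),
            (0.2, 0.4, 0.3, 0.4, "none"),
        ],
    )
    def test_truth_table_exhaustive(self, indirect, indirect_p, direct, direct_p, expected):
        res = self._result(indirect, indirect_p, direct, direct_p)
        assert classify_mediation(res) == expected
        assert res.mediation_type == expected

    def test_falls_back_to_interval_when_p_missing(self):
        res = self._result(0.2, np.nan, 0.3, 0.001)
        res.indirect_p = np.nan
        res.indirect_ci = (0.1, 0.3)
        assert classify_mediation(res) == "complementary"
        res.indirect_ci = (-0.1, 0.3)
        assert classify_mediation(res) == "none"
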