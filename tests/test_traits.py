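import numpy as np
import pytest

from admixepi import (
    EffectSpec,
    TraitModel,
    build_latent,
    draw_effects,
    rho_latent_ancestry,
    select_causals,
    simulate_phenotype,
    standardize_genotypes,
)
from admixepi.founders import draw_ancestral_frequencies, sample_founder_haplotypes
from admixepi.admixture import build_cohort


class TestSelectCausals:
    def test_vacuous_filter_accepts_common_snps(self, small_cohort):
        sel = select_causals(small_cohort, 2, K=3, differentiation_threshold=0.0,
                             seed=1)
        assert len(sel.indices) == 3
        mafs = small_cohort.genotypes[:, sel.indices].mean(axis=0) / 2
        assert np.all(np.minimum(mafs, 1 - mafs) > 0.10)

    def test_no_differentiation_yields_no_candidates(self):
        """With fst -> 0 no SNP correlates with ancestry at 0.5."""
        freqs = draw_ancestral_frequencies(300, 1e-3, seed=2)
        founders = sample_founder_haplotypes(freqs, 60, seed=2)
        cohort = build_cohort(founders, 300, 50_000_000, n_segments=3, seed=2)
        with pytest.raises(ValueError, match="only 0 SNPs"):
            select_causals(cohort, 1, K=1, differentiation_threshold=0.5, seed=0)

    def test_perfect_aim_passes_high_threshold(self, aim_cohort):
        sel = select_causals(aim_cohort, 1, K=1, differentiation_threshold=0.5,
                             maf_min=0.05, seed=0)
        assert abs(sel.ancestry_corr[0]) > 0.99

    def test_selection_reproducible(self, small_cohort):
        a = select_causals(small_cohort, 1, K=2, seed=9)
        b = select_causals(small_cohort, 1, K=2, seed=9)
        assert np.array_equal(a.indices, b.indices)


class TestDrawEffects:
    def test_truncated_support_and_mean(self):
        """Left-truncated standard normal is half-normal: mean sqrt(2/pi)."""
        beta = draw_effects(EffectSpec(K=4000, family="left-truncated-normal"),
                            seed=3)
        assert beta.min() >= 0
        se = np.sqrt(1 - 2 / np.pi) / np.sqrt(4000)
        assert abs(beta.mean() - np.sqrt(2 / np.pi)) < 3 * se

    def test_normal_family_symmetric(self):
        beta = draw_effects(EffectSpec(K=4000, family="normal"), seed=3)
        assert abs(beta.mean()) < 3 / np.sqrt(4000)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown effect family"):
            EffectSpec(K=2, family="cauchy")


class TestBuildLatent:
    def test_single_causal_identity(self, small_cohort):
        sel = select_causals(small_cohort, 0, K=1, seed=2)
        lt = build_latent(small_cohort, sel.indices, np.array([1.0]))
        g = standardize_genotypes(small_cohort.genotypes[:, sel.indices])
        assert np.allclose(lt.Z, g[:, 0])

    def test_zero_effects_zero_latent(self, small_cohort):
        sel = select_causals(small_cohort, 0, K=2, seed=2)
        lt = build_latent(small_cohort, sel.indices, np.zeros(2))
        assert np.allclose(lt.Z, 0)

    def test_variance_adds_over_independent_causals(self, small_cohort):
        """Equal betas on two near-independent SNPs: var(Z) ~ 2 beta^2."""
        sel = select_causals(small_cohort, 0, K=2, seed=5)
        lt = build_latent(small_cohort, sel.indices, np.array([1.0, 1.0]))
        assert abs(lt.Z.var() - 2.0) < 0.5

    def test_monomorphic_causal_rejected(self, small_cohort):
        g = small_cohort.genotypes.copy()
        g[:, 5] = 1
        cohort = small_cohort
        old = cohort.genotypes
        cohort.genotypes = g
        try:
            with pytest.raises(ValueError, match="monomorphic"):
                build_latent(cohort, np.array([5]), np.array([1.0]))
        finally:
            cohort.genotypes = old


class TestSimulatePhenotype:
    def test_residual_variance_formula(self):
        """sigma^2 = theta12^2 var(Z1 Z2) (1 - v)/v with no main effects."""
        rng = np.random.default_rng(0)
        Z1, Z2 = rng.standard_normal((2, 5000))
        vp = (Z1 * Z2).var()
        ph = simulate_phenotype(Z1, Z2,
                                TraitModel(target_interaction_variance=0.01),
                                seed=1)
        assert np.isclose(ph.epsilon_variance, 99 * vp, rtol=1e-10)

    def test_noiseless_limit(self):
        rng = np.random.default_rng(0)
        Z1, Z2 = rng.standard_normal((2, 1000))
        ph = simulate_phenotype(Z1, Z2,
                                TraitModel(target_interaction_variance=0.999),
                                seed=1)
        assert ph.epsilon_variance < 0.01 * (Z1 * Z2).var()

    def test_realized_interaction_variance(self):
        """At N = 1e5 the realized variance fraction hits the 1% target."""
        rng = np.random.default_rng(4)
        Z1, Z2 = rng.standard_normal((2, 100_000))
        ph = simulate_phenotype(Z1, Z2, TraitModel(), seed=2)
        assert abs(ph.realized_interaction_variance - 0.01) < 0.002

    def test_scaling_invariance(self):
        """Rescaling both latents leaves the variance fraction unchanged."""
        rng = np.random.default_rng(5)
        Z1, Z2 = rng.standard_normal((2, 3000))
        a = simulate_phenotype(Z1, Z2, TraitModel(), seed=7)
        b = simulate_phenotype(3 * Z1, 3 * Z2, TraitModel(), seed=7)
        assert np.isclose(a.realized_interaction_variance,
                          b.realized_interaction_variance, atol=1e-12)

    def test_pure_interaction_has_no_marginal_signal(self):
        rng = np.random.default_rng(6)
        Z1, Z2 = rng.standard_normal((2, 50_000))
        ph = simulate_phenotype(Z1, Z2,
                                TraitModel(target_interaction_variance=0.2),
                                seed=3)
        assert abs(np.corrcoef(ph.Y, Z1)[0, 1]) < 0.02
        assert abs(np.corrcoef(ph.Y, Z2)[0, 1]) < 0.02

    def test_degenerate_product_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            simulate_phenotype(np.zeros(100), np.ones(100), TraitModel(), seed=0)

    def test_main_effects_require_genotypes(self):
        rng = np.random.default_rng(7)
        Z1, Z2 = rng.standard_normal((2, 100))
        with pytest.raises(ValueError, match="causal_genotypes"):
            simulate_phenotype(Z1, Z2, TraitModel(snp_main_effects=True), seed=0)


class TestRhoLatentAncestry:
    def test_constant_ancestry_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            rho_latent_ancestry(np.random.default_rng(0).standard_normal(50),
                                np.full(50, 2.0))

    def test_symmetric_effects_give_null_mean(self, small_cohort):
        """Normal (zero-mean) effects: rho_ZL averages to zero."""
        rng = np.random.default_rng(8)
        rhos = []
        for _ in range(40):
            sel = select_causals(small_cohort, 1, K=5,
                                 differentiation_threshold=0.1, seed=rng)
            beta = draw_effects(EffectSpec(K=5, family="normal"), rng)
            lt = build_latent(small_cohort, sel.indices, beta, sel.flip)
            rhos.append(rho_latent_ancestry(
                lt.Z, small_cohort.local_ancestry[:, 1]))
        sem = np.std(rhos, ddof=1) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) < 3 * sem + 0.02

    def test_consistent_effects_grow_with_k(self, small_cohort):
        """Half-normal effects: |rho_ZL| larger with many causals than one."""
        rng = np.random.default_rng(9)
        means = {}
        for K in (1, 20):
            rhos = []
            for _ in range(40):
                sel = select_causals(small_cohort, 1, K=K,
                                     differentiation_threshold=0.1, seed=rng)
                beta = draw_effects(EffectSpec(K=K), rng)
                lt = build_latent(small_cohort, sel.indices, beta, sel.flip)
                rhos.append(abs(rho_latent_ancestry(
                    lt.Z, small_cohort.local_ancestry[:, 1])))
            means[K] = np.mean(rhos)
        assert means[20] > means[1]
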