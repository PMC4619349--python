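import numpy as np
import pytest

from admixepi import (
    best_tag,
    fit_interaction,
    product_correlation,
    scan_pairs,
    two_step_screen,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(21)


class TestFitInteraction:
    def test_exact_recovery(self, rng):
        a = rng.standard_normal(200)
        b = rng.standard_normal(200)
        res = fit_interaction(2 + a * b, a, b)
        assert np.isclose(res.beta_int, 1.0, atol=1e-10)
        assert res.p_value < 1e-50

    def test_matches_statsmodels(self, rng):
        """Independent OLS oracle for the estimate and its standard error."""
        import statsmodels.api as sm

        a = rng.standard_normal(150)
        b = rng.standard_normal(150)
        y = 1 + 0.5 * a + 0.3 * a * b + rng.standard_normal(150)
        res = fit_interaction(y, a, b)
        X = sm.add_constant(np.column_stack([a, b, a * b]))
        fit = sm.OLS(y, X).fit()
        assert np.isclose(res.beta_int, fit.params[3], rtol=1e-10)
        assert np.isclose(res.se, fit.bse[3], rtol=1e-10)

    def test_null_calibration(self, rng):
        """Under the null, ~5% of replicates reject at alpha 0.05."""
        from scipy.stats import binom

        hits = 0
        reps = 400
        for _ in range(reps):
            y = rng.standard_normal(150)
            a = rng.integers(0, 3, 150).astype(float)
            b = rng.integers(0, 3, 150).astype(float)
            hits += fit_interaction(y, a, b).p_value < 0.05
        lo, hi = binom.ppf([0.005, 0.995], reps, 0.05)
        assert lo <= hits <= hi

    def test_wald_scale_matches_variance_explained(self, rng):
        """With v of var(Y) from the product term, Wald/N ~ v/(1-v)."""
        N, v = 20_000, 0.01
        walds = []
        for _ in range(20):
            g1 = rng.standard_normal(N)
            g2 = rng.standard_normal(N)
            p = g1 * g2
            y = p + rng.normal(0, np.sqrt(p.var() * (1 - v) / v), N)
            walds.append(fit_interaction(y, g1, g2).wald)
        assert abs(np.mean(walds) / N - v / (1 - v)) < 0.002

    def test_centering_invariance(self, rng):
        """The product-term Wald is invariant to predictor centering."""
        a = rng.integers(0, 3, 300).astype(float)
        b = rng.integers(0, 3, 300).astype(float)
        y = rng.standard_normal(300) + 0.2 * a * b
        r1 = fit_interaction(y, a, b)
        r2 = fit_interaction(y, a - a.mean(), b - b.mean())
        assert np.isclose(r1.wald, r2.wald, rtol=1e-8)

    def test_permutation_invariance(self, rng):
        a = rng.standard_normal(100)
        b = rng.standard_normal(100)
        y = rng.standard_normal(100)
        perm = rng.permutation(100)
        r1 = fit_interaction(y, a, b)
        r2 = fit_interaction(y[perm], a[perm], b[perm])
        assert np.isclose(r1.wald, r2.wald, rtol=1e-10)

    def test_collinear_product_reported(self, rng):
        a = rng.integers(0, 2, 100).astype(float)  # binary: a*a == a
        y = rng.standard_normal(100)
        with pytest.raises(np.linalg.LinAlgError, match="a\\*b"):
            fit_interaction(y, a, a)

    def test_constant_predictor_rejected(self, rng):
        with pytest.raises(ValueError, match="non-constant"):
            fit_interaction(rng.standard_normal(50), np.ones(50),
                            rng.standard_normal(50))


class TestBestTag:
    def test_self_tagging(self, rng):
        G = rng.integers(0, 3, (200, 10)).astype(float)
        sel = best_tag(G, np.array([1.0]), np.array([4]), np.arange(10))
        assert sel.tag_index == 4

    def test_brute_force_score(self, rng):
        """Oracle: exhaustive |sum beta*corr| over every candidate."""
        G = rng.integers(0, 3, (300, 12)).astype(float)
        beta = np.abs(rng.standard_normal(3))
        causals = np.array([0, 1, 2])
        candidates = np.arange(3, 12)
        sel = best_tag(G, beta, causals, candidates)
        Gs = (G - G.mean(0)) / G.std(0)
        scores = [abs(sum(b * np.corrcoef(Gs[:, j], Gs[:, k])[0, 1]
                          for b, k in zip(beta, causals)))
                  for j in candidates]
        assert sel.tag_index == candidates[int(np.argmax(scores))]
        assert np.isclose(sel.score, max(scores), rtol=1e-8)

    def test_tie_broken_by_lowest_index(self, rng):
        G = rng.integers(0, 3, (100, 5)).astype(float)
        G[:, 3] = G[:, 2]  # duplicate column: identical scores
        sel = best_tag(G, np.array([1.0]), np.array([0]), np.array([2, 3]))
        assert sel.tag_index == 2

    def test_all_monomorphic_rejected(self):
        G = np.ones((50, 3))
        G[:25, 0] = 0
        with pytest.raises(ValueError, match="monomorphic"):
            best_tag(G, np.array([1.0]), np.array([0]), np.array([1, 2]))


class TestProductCorrelation:
    def test_identity(self, rng):
        a1, a2 = rng.standard_normal((2, 100))
        assert product_correlation(a1, a2, a1, a2) == pytest.approx(1.0)

    def test_independent_products_uncorrelated(self, rng):
        a1, a2, b1, b2 = rng.standard_normal((4, 20_000))
        assert abs(product_correlation(a1, a2, b1, b2)) < 0.03

    def test_perfect_aims_give_unit_ancestry_tagging(self, aim_cohort):
        """When causals are perfect AIMs, genotype and ancestry products coincide."""
        g = aim_cohort.genotypes[:, [0, 10]].astype(float)
        seg = [aim_cohort.segment_map.segment_of(int(aim_cohort.positions[j]))
               for j in (0, 10)]
        L = aim_cohort.local_ancestry[:, seg].astype(float)
        rho = product_correlation(g[:, 0], g[:, 1], L[:, 0], L[:, 1])
        assert rho == pytest.approx(1.0)

    def test_degenerate_product_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            product_correlation(np.zeros(50), np.ones(50),
                                np.ones(50), np.ones(50))


class TestScanPairs:
    def test_pair_count_and_order(self, rng):
        y = rng.standard_normal(100)
        X = rng.integers(0, 3, (100, 3)).astype(float)
        out = scan_pairs(y, X)
        assert len(out) == 3
        assert list(zip(out["i"], out["j"])) == [(0, 1), (0, 2), (1, 2)]

    def test_planted_interaction_found(self, rng):
        """A strong planted ancestry-pair interaction attains the smallest p."""
        N = 5000
        X = rng.integers(0, 3, (N, 6)).astype(float)
        p = X[:, 1] * X[:, 4]
        v = 0.05
        y = p + rng.normal(0, np.sqrt(p.var() * (1 - v) / v), N)
        out = scan_pairs(y, X, alpha_corrected=1e-7)
        top = out.loc[out["p_value"].idxmin()]
        assert (top["i"], top["j"]) == (1, 4)
        assert top["significant"]

    def test_degenerate_pair_flagged_not_fatal(self, rng):
        y = rng.standard_normal(100)
        X = np.column_stack([rng.integers(0, 3, 100),
                             np.ones(100),
                             rng.integers(0, 3, 100)]).astype(float)
        out = scan_pairs(y, X)
        assert len(out) == 3
        flagged = out[out["error"] != ""]
        assert {(0, 1), (1, 2)} == set(zip(flagged["i"], flagged["j"]))
        assert out[out["error"] == ""].notna().all().all()


class TestTwoStepScreen:
    def test_step2_budget_formula(self, rng):
        """n=1000 predictors at t=0.01 -> C(10, 2) = 45 step-2 tests."""
        y = rng.standard_normal(50)
        X = rng.standard_normal((50, 1000))
        _, approx = two_step_screen(y, X, t=0.01)
        assert approx == pytest.approx(45.0)

    def test_threshold_one_selects_all(self, rng):
        y = rng.standard_normal(60)
        X = rng.standard_normal((60, 20))
        selected, _ = two_step_screen(y, X, t=1.0)
        assert len(selected) == 20

    def test_null_selection_fraction(self, rng):
        y = rng.standard_normal(400)
        X = rng.standard_normal((400, 2000))
        selected, _ = two_step_screen(y, X, t=0.1)
        frac = len(selected) / 2000
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 2000)

    def test_marginal_signal_enriched(self, rng):
        """Predictors with real main effects survive the screen."""
        N = 800
        X = rng.standard_normal((N, 50))
        y = X[:, 7] + 0.8 * X[:, 23] + rng.standard_normal(N)
        selected, _ = two_step_screen(y, X, t=0.01)
        assert {7, 23} <= set(selected)

    def test_bad_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            two_step_screen(rng.standard_normal(20),
                            rng.standard_normal((20, 3)), t=0.0)
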