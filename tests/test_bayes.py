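import numpy as np
import pytest

from gwpred import (
    GenotypeMatrix,
    GibbsConfig,
    posterior_predict,
    run_gibbs,
    simulate_genotypes,
    simulate_trait,
)

ALL_MODELS = ["BRR", "BL", "BayesA", "BayesB", "BayesCpi"]


def panel(dosage):
    dosage = np.asarray(dosage, dtype=float)
    n, p = dosage.shape
    return GenotypeMatrix(
        [f"s{i}" for i in range(n)],
        [f"m{j}" for j in range(p)],
        ["1"] * p,
        np.arange(1, p + 1),
        dosage,
    )


def mc_se(samples):
    """Batch-means Monte-Carlo standard error (accounts for autocorrelation)."""
    nb = 25
    b = len(samples) // nb
    means = samples[: nb * b].reshape(nb, b).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(nb)


class TestConfig:
    def test_kept_sample_arithmetic(self):
        cfg = GibbsConfig(n_iter=10_000, burn_in=1_000, thin=10)
        assert cfg.n_kept == 900

    @pytest.mark.parametrize(
        "kw", [dict(burn_in=50_000), dict(thin=0), dict(pi0=1.5), dict(df_a=0.0)]
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            GibbsConfig(n_iter=30_000, **kw)

    def test_study_scale_preset(self):
        cfg = GibbsConfig.study_scale("BayesA")
        assert (cfg.n_iter, cfg.burn_in, cfg.thin) == (1_000_000, 100_000, 50)


class TestBrrConjugate:
    def test_single_marker_matches_ridge_closed_form(self):
        rng = np.random.default_rng(0)
        n = 60
        x = rng.binomial(2, 0.5, n).astype(float)
        a_true, s2e, s2a = 0.8, 1.0, 0.25
        y = 1.0 + x * a_true + rng.normal(0, np.sqrt(s2e), n)
        G = panel(x[:, None])
        cfg = GibbsConfig(
            model="BRR",
            n_iter=30_000,
            burn_in=5_000,
            thin=10,
            seed=1,
            fix_marker_var=s2a,
            fix_resid_var=s2e,
            save_effect_samples=True,
        )
        ps = run_gibbs(y, G, cfg)
        # conjugate posterior mean on the centered design, intercept profiled out
        w = x - 2 * G.allele_freq[0]
        yc = y - y.mean()
        expected = (w @ yc / s2e) / (w @ w / s2e + 1 / s2a)
        se = mc_se(ps.effect_samples[:, 0])
        assert abs(ps.add_effects[0] - expected) < 3 * se


class TestDegenerateAndIdentities:
    def test_bayesb_all_null_prior(self, small_panel, small_trait):
        y, _ = small_trait
        cfg = GibbsConfig(model="BayesB", pi0=1.0, n_iter=3000, burn_in=500, thin=5, seed=2)
        ps = run_gibbs(y, small_panel, cfg)
        assert np.all(np.abs(ps.add_effects) < 1e-3 * y.value.std())
        np.testing.assert_allclose(ps.fitted_genetic_values, 0.0, atol=1e-12)

    def test_chain_reproducibility(self, small_panel, small_trait):
        y, _ = small_trait
        cfg = GibbsConfig(model="BayesCpi", n_iter=2000, burn_in=500, thin=5, seed=9)
        a = run_gibbs(y, small_panel, cfg)
        b = run_gibbs(y, small_panel, cfg)
        np.testing.assert_array_equal(a.add_effects, b.add_effects)
        assert a.mu == b.mu and a.resid_var == b.resid_var

    def test_non_finite_phenotype_rejected(self, small_panel):
        y = np.zeros(small_panel.n_samples)
        y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            run_gibbs(y, small_panel, GibbsConfig(n_iter=1000, burn_in=100))


class TestOlsAgreement:
    @pytest.mark.parametrize("model", ALL_MODELS)
    def test_posterior_mean_matches_ols_when_n_dominates(self, model):
        rng = np.random.default_rng(3)
        n, p = 200, 3
        X = rng.binomial(2, 0.4, (n, p)).astype(float)
        beta = np.array([0.5, -0.3, 0.2])
        y = X @ beta + rng.normal(0, 0.3, n)
        G = panel(X)
        cfg = GibbsConfig(
            model=model,
            n_iter=20_000,
            burn_in=4_000,
            thin=4,
            seed=4,
            pi0=0.05,  # mixture models: nearly always included
            save_effect_samples=True,
        )
        ps = run_gibbs(y, G, cfg)
        Xc = np.column_stack([np.ones(n), X])
        ols = np.linalg.lstsq(Xc, y, rcond=None)[0][1:]
        for j in range(p):
            se = max(mc_se(ps.effect_samples[:, j]), 1e-4)
            assert abs(ps.add_effects[j] - ols[j]) < 3 * se + 0.02


def test_mixture_models_rank_qtl_above_background(sparse_panel):
    G, y, truth = sparse_panel
    qtl = set(truth.qtl_indices.tolist())
    bg = [j for j in range(G.n_markers) if j not in qtl]
    for model in ("BayesB", "BayesCpi"):
        cfg = GibbsConfig(model=model, n_iter=4000, burn_in=1000, thin=3, seed=5)
        ps = run_gibbs(y, G, cfg)
        assert ps.inclusion_prob[list(qtl)].mean() > ps.inclusion_prob[bg].mean()


class TestPosteriorPredict:
    def make_summary(self, small_panel, small_trait, **overrides):
        y, _ = small_trait
        cfg = GibbsConfig(model="BRR", n_iter=2000, burn_in=500, thin=5, seed=6)
        return run_gibbs(y, small_panel, cfg)

    def test_training_set_consistency(self, small_panel, small_trait):
        ps = self.make_summary(small_panel, small_trait)
        pred = posterior_predict(ps, small_panel)
        np.testing.assert_allclose(pred, ps.mu + ps.fitted_genetic_values, atol=1e-10)

    def test_zero_effects_predict_mu(self, small_panel, small_trait):
        ps = self.make_summary(small_panel, small_trait)
        ps.add_effects = np.zeros_like(ps.add_effects)
        pred = posterior_predict(ps, small_panel)
        np.testing.assert_allclose(pred, ps.mu)

    def test_effect_linearity(self, small_panel, small_trait):
        ps = self.make_summary(small_panel, small_trait)
        base = posterior_predict(ps, small_panel)
        j = 0
        contrib = base - ps.mu
        single = np.zeros_like(ps.add_effects)
        single[j] = ps.add_effects[j]
        ps2_effects = ps.add_effects.copy()
        ps.add_effects = single
        one = posterior_predict(ps, small_panel) - ps.mu
        ps.add_effects = 2 * single
        two = posterior_predict(ps, small_panel) - ps.mu
        np.testing.assert_allclose(two, 2 * one, atol=1e-12)
        ps.add_effects = ps2_effects

    def test_marker_mismatch_rejected(self, small_panel, small_trait):
        ps = self.make_summary(small_panel, small_trait)
        G2 = small_panel.subset_markers(np.arange(small_panel.n_markers - 1))
        with pytest.raises(ValueError, match="marker mismatch"):
            posterior_predict(ps, G2)
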