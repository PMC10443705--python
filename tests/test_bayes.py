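import numpy as np
import pytest
from scipy import stats as sps

from gpsel import (
    BayesianAlphabetRegressor,
    EffectBlock,
    MCMCConfig,
    default_hyperparams,
    gibbs_fit,
)
from gpsel.bayes import predict as bayes_predict


@pytest.fixture(scope="module")
def ridge_problem():
    rng = np.random.default_rng(0)
    n, q = 80, 30
    X = rng.standard_normal((n, q))
    beta = rng.standard_normal(q) * 0.3
    y = X @ beta + rng.standard_normal(n) * 0.5
    return X, y


class TestOracles:
    def test_fixed_variance_brr_matches_ridge(self, ridge_problem):
        """With both variances frozen the BRR posterior mean is the
        closed-form ridge solution."""
        X, y = ridge_problem
        s2e, s2b = 0.25, 0.09
        s = gibbs_fit(
            y,
            [EffectBlock("m", "BRR", X=X, hyper={"fixed_var": s2b})],
            MCMCConfig(12000, 2000, 1, seed=3),
            fix_sigma2_e=s2e,
        )
        ridge = np.linalg.solve(X.T @ X + (s2e / s2b) * np.eye(X.shape[1]), X.T @ y)
        assert np.abs(s.blocks["m"]["beta_mean"] - ridge).max() < 0.02

    def test_bayesc_pi_one_matches_brr(self, ridge_problem):
        X, y = ridge_problem
        cfg = MCMCConfig(8000, 2000, 2, seed=5)
        brr = gibbs_fit(y, [EffectBlock("m", "BRR", X=X)], cfg)
        bc = gibbs_fit(
            y, [EffectBlock("m", "BayesC", X=X, hyper={"pi_fixed": 1.0})], cfg
        )
        assert np.corrcoef(brr.fitted_values, bc.fitted_values)[0, 1] > 0.999
        assert np.abs(brr.fitted_values - bc.fitted_values).max() < 0.15

    def test_rkhs_linear_kernel_equals_brr(self, ridge_problem):
        """GBLUP == RR-BLUP: an RKHS block with K = Z Z'/c reproduces the
        BRR fit on Z."""
        X, y = ridge_problem
        K = X @ X.T / X.shape[1]
        cfg = MCMCConfig(8000, 2000, 2, seed=7)
        brr = gibbs_fit(y, [EffectBlock("m", "BRR", X=X)], cfg)
        rk = gibbs_fit(y, [EffectBlock("k", "RKHS", K=K)], cfg)
        assert np.corrcoef(brr.fitted_values, rk.fitted_values)[0, 1] > 0.999


class TestSamplerContract:
    def test_seeded_determinism(self, ridge_problem):
        X, y = ridge_problem
        cfg = MCMCConfig(400, 100, 2, seed=11)
        a = gibbs_fit(y, [EffectBlock("m", "BayesA", X=X)], cfg)
        b = gibbs_fit(y, [EffectBlock("m", "BayesA", X=X)], cfg)
        assert np.array_equal(a.blocks["m"]["beta_mean"], b.blocks["m"]["beta_mean"])
        assert np.array_equal(a.sigma2_e_chain, b.sigma2_e_chain)

    @pytest.mark.parametrize("kind", ["BRR", "BayesA", "BayesC", "BL"])
    def test_variance_chains_nonnegative(self, ridge_problem, kind):
        X, y = ridge_problem
        s = gibbs_fit(y, [EffectBlock("m", kind, X=X)], MCMCConfig(600, 100, 2, seed=1))
        assert np.all(s.sigma2_e_chain > 0)
        assert np.all(s.blocks["m"]["var_chain"] >= 0)
        assert np.all(np.isfinite(s.log_density))

    def test_residual_chain_stationary_on_null_data(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((60, 20))
        y = rng.standard_normal(60)
        s = gibbs_fit(y, [EffectBlock("m", "BRR", X=X)], MCMCConfig(2000, 500, 1, seed=2))
        chain = s.sigma2_e_chain
        # no monotone trend: rank correlation with iteration index ~ 0
        rho = sps.spearmanr(np.arange(len(chain)), chain).statistic
        assert abs(rho) < 0.25

    def test_burnin_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)

    def test_non_psd_kernel_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="PSD"):
            EffectBlock("k", "RKHS", K=K)

    def test_nonfinite_target_rejected(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError, match="non-finite"):
            gibbs_fit(np.array([1.0, np.nan, 0.0, 2.0]),
                      [EffectBlock("m", "BRR", X=X)], MCMCConfig(10, 1, 1))


class TestPrediction:
    def test_training_rows_reproduce_fitted_values(self, ridge_problem):
        X, y = ridge_problem
        n = len(y)
        blocks = [
            EffectBlock("mu", "FIXED", X=np.ones((n, 1))),
            EffectBlock("m", "BRR", X=X),
        ]
        s = gibbs_fit(y, blocks, MCMCConfig(500, 100, 1, seed=4))
        pred = bayes_predict(s, {"mu": np.ones((n, 1)), "m": X})
        assert np.abs(pred - s.fitted_values).max() < 1e-8

    def test_zero_marker_block_predicts_fixed_mean(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(30) + 5
        blocks = [
            EffectBlock("mu", "FIXED", X=np.ones((30, 1))),
            EffectBlock("m", "BRR", X=np.zeros((30, 8))),
        ]
        s = gibbs_fit(y, blocks, MCMCConfig(800, 200, 1, seed=6))
        pred = bayes_predict(s, {"mu": np.ones((5, 1)), "m": np.zeros((5, 8))})
        assert np.allclose(pred, pred[0])
        assert pred[0] == pytest.approx(y.mean(), abs=0.2)

    def test_block_mismatch_rejected(self, ridge_problem):
        X, y = ridge_problem
        s = gibbs_fit(y, [EffectBlock("m", "BRR", X=X)], MCMCConfig(50, 10, 1, seed=0))
        with pytest.raises(ValueError, match="missing new data"):
            bayes_predict(s, {})
        with pytest.raises(ValueError, match="columns"):
            bayes_predict(s, {"m": X[:, :3]})


class TestHyperparams:
    def test_df_always_five_and_expectation_rule(self):
        rng = np.random.default_rng(7)
        y = rng.standard_normal(200)  # var ~ 1
        X = rng.standard_normal((200, 40))
        h = default_hyperparams(y, EffectBlock("m", "BRR", X=X), n_random_blocks=1)
        assert h["df"] == 5
        # E[sigma2] * sum col var should equal r2 * var(y) = 0.5 var(y)
        exp_share = h["scale"] * 5 / 3 * np.sum(X.var(axis=0))
        assert exp_share == pytest.approx(0.5 * y.var(), rel=1e-10)

    def test_two_blocks_split_the_share(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(100)
        X = rng.standard_normal((100, 10))
        h1 = default_hyperparams(y, EffectBlock("m", "BRR", X=X), 1)
        h2 = default_hyperparams(y, EffectBlock("m", "BRR", X=X), 2)
        assert h2["scale"] == pytest.approx(h1["scale"] / 2)

    def test_bayesc_prior_beta_5_45(self):
        rng = np.random.default_rng(9)
        h = default_hyperparams(
            rng.standard_normal(50), EffectBlock("m", "BayesC", X=rng.standard_normal((50, 5))), 1
        )
        assert (h["pi_a"], h["pi_b"]) == (5.0, 45.0)


def test_posterior_summary_export(ridge_problem, tmp_path):
    X, y = ridge_problem
    s = gibbs_fit(y, [EffectBlock("m", "BRR", X=X)], MCMCConfig(100, 20, 1, seed=0))
    s.save(tmp_path, chains=True)
    import json
    import pandas as pd

    eff = pd.read_csv(tmp_path / "posterior_effects.tsv", sep="\t")
    assert len(eff) == X.shape[1]
    vc = json.loads((tmp_path / "posterior_variances.json").read_text())
    assert vc["sigma2_e"] > 0 and "m" in vc["blocks"]
    chains = pd.read_csv(tmp_path / "posterior_chains.tsv", sep="\t")
    assert {"sigma2_e", "var_m"} <= set(chains.columns)


class TestEstimatorFrontEnd:
    def test_sklearn_contract(self, ridge_problem):
        from sklearn.base import clone

        X, y = ridge_problem
        est = BayesianAlphabetRegressor("brr", n_iter=300, burn_in=50, seed=1)
        clone(est)  # get_params/set_params round-trip
        est.fit(X, y)
        assert est.predict(X).shape == y.shape
        assert 0 <= est.h2_ <= 1
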