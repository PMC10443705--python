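import numpy as np
import pytest
from sklearn.metrics.pairwise import laplacian_kernel, polynomial_kernel, rbf_kernel

from gpsel import ApproxKernelFeatures, KernelSpec
from gpsel.features import (
    AnovaFSelector,
    GroupEncoder,
    PolynomialExpander,
    QuantileScaler,
    SafeRobustScaler,
    ZScoreScaler,
    drop_degenerate_columns,
)


class TestApproxKernel:
    @pytest.mark.parametrize(
        "kind, exact",
        [
            ("rbf", rbf_kernel),
            ("laplacian", laplacian_kernel),
            ("poly2", lambda A, B, gamma: polynomial_kernel(A, B, degree=2, gamma=gamma, coef0=1.0)),
        ],
    )
    def test_full_landmarks_reproduce_exact_kernel(self, kind, exact):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((50, 8))
        ak = ApproxKernelFeatures(KernelSpec(kind, 0.2, 50, 0)).fit(Z)
        F = ak.transform(Z)
        assert np.abs(F @ F.T - exact(Z, Z, gamma=0.2)).max() < 1e-6

    def test_identical_rows_map_identically(self):
        Z = np.vstack([np.ones((2, 4)), np.zeros((3, 4))])
        F = ApproxKernelFeatures(KernelSpec("rbf", 0.5, 5, 0)).fit(Z).transform(Z)
        assert np.allclose(F[0], F[1])

    def test_validation(self):
        with pytest.raises(ValueError, match="bandwidth"):
            KernelSpec("rbf", gamma=-1.0)
        with pytest.raises(ValueError, match="landmark"):
            ApproxKernelFeatures(KernelSpec("rbf", 1.0, 100, 0)).fit(np.zeros((10, 2)))

    def test_poly2_on_1d_inputs(self):
        z = np.linspace(-1, 1, 20).reshape(-1, 1)
        F = ApproxKernelFeatures(KernelSpec("poly2", 0.7, 20, 1)).fit(z).transform(z)
        K = (0.7 * z @ z.T + 1.0) ** 2
        assert np.abs(F @ F.T - K).max() < 1e-6


class TestScalers:
    def test_quantile_uniform_is_even_rank_map(self):
        x = np.array([[3.0], [1.0], [2.0], [5.0], [4.0]])
        t = QuantileScaler("uniform").fit(x).transform(x).ravel()
        assert np.array_equal(np.argsort(t), np.argsort(x.ravel()))
        assert np.allclose(np.sort(t), np.linspace(0, 1, 5))

    def test_quantile_normal_moments(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(size=(1000, 1))
        t = QuantileScaler("normal").fit(x).transform(x)
        assert abs(t.mean()) < 0.1
        assert abs(t.std() - 1) < 0.1

    def test_quantile_monotone_and_clipped(self):
        x = np.arange(20.0).reshape(-1, 1)
        qs = QuantileScaler("uniform").fit(x)
        t = qs.transform(np.array([[5.0], [15.0], [100.0]])).ravel()
        assert t[0] <= t[1] <= t[2] <= 1.0

    def test_zscore_sample_convention(self):
        t = ZScoreScaler().fit(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(t.transform(np.array([[1.0], [2.0], [3.0]])).ravel(), [-1, 0, 1])

    def test_robust_hand_computation(self):
        x = np.array([[1.0], [2.0], [100.0]])
        t = SafeRobustScaler().fit(x).transform(x).ravel()
        assert t == pytest.approx([-1 / 49.5, 0.0, 98 / 49.5])

    def test_constant_columns_warn_and_zero(self):
        x = np.ones((5, 1))
        with pytest.warns(UserWarning):
            z = ZScoreScaler().fit(x)
        assert np.allclose(z.transform(x), 0)
        with pytest.warns(UserWarning):
            r = SafeRobustScaler().fit(x)
        assert np.allclose(r.transform(x), 0)


class TestPolynomial:
    @pytest.mark.parametrize("q, degree, expected", [(2, 2, 5), (2, 1, 2), (1, 3, 3), (3, 3, 19)])
    def test_column_counts(self, q, degree, expected):
        X = np.random.default_rng(0).standard_normal((10, q))
        out = PolynomialExpander(degree).fit(X).transform(X)
        assert out.shape[1] == expected

    def test_degree_one_is_identity(self):
        X = np.random.default_rng(0).standard_normal((6, 3))
        assert np.allclose(PolynomialExpander(1).fit(X).transform(X), X)

    def test_invalid_degree(self):
        with pytest.raises(ValueError, match="degree"):
            PolynomialExpander(4)


class TestAnovaF:
    def test_perfect_feature_ranked_first(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(40)
        X = np.column_stack([rng.standard_normal((40, 3)), y])
        sel = AnovaFSelector(1, "regression").fit(X, y)
        assert sel.support_.tolist() == [3]

    def test_null_feature_f_near_one(self):
        rng = np.random.default_rng(3)
        meds = []
        for s in range(50):
            r = np.random.default_rng(s)
            y = r.standard_normal(30)
            X = r.standard_normal((30, 1))
            meds.append(AnovaFSelector(1, "regression").fit(X, y).scores_[0])
        # median of F(1, 28) is ~0.46; just check the null stays small
        assert 0.1 < np.median(meds) < 1.5

    def test_classification_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 15)
        x = rng.standard_normal(30) + y
        F = AnovaFSelector(1, "classification").fit(x.reshape(-1, 1), y).scores_[0]
        from scipy import stats as sps

        t = sps.ttest_ind(x[y == 0], x[y == 1]).statistic
        assert F == pytest.approx(t**2, rel=1e-10)

    def test_k_too_large_keeps_all_with_warning(self):
        X = np.random.default_rng(5).standard_normal((10, 3))
        with pytest.warns(UserWarning, match="keeping all"):
            sel = AnovaFSelector(7, "regression").fit(X, X[:, 0])
        assert len(sel.support_) == 3


class TestGroups:
    def test_onehot_row_sums(self):
        g = np.array(["a", "b", "c", "a"])
        H = GroupEncoder("onehot").fit(g).transform(g)
        assert H.shape == (4, 3)
        assert np.all(H.sum(axis=1) == 1)

    def test_unseen_level_gives_zero_row(self):
        enc = GroupEncoder("onehot").fit(np.array(["a", "b", "a", "b"]))
        with pytest.warns(UserWarning, match="unseen"):
            H = enc.transform(np.array(["z"]))
        assert np.all(H == 0)

    def test_single_level_factor_dropped(self):
        with pytest.warns(UserWarning, match="single-level"):
            enc = GroupEncoder("onehot").fit(np.array(["a", "a", "a"]))
        assert enc.transform(np.array(["a"])).shape == (1, 0)

    def test_pca_k_captures_between_group_variance(self):
        g = np.repeat(["a", "b", "c"], 10)
        H = GroupEncoder("pca_k", k=2).fit(g).transform(g)
        assert H.shape == (30, 2)
        # 3 levels have rank-2 centered indicators: within-group constant
        for lv in ("a", "b", "c"):
            assert np.allclose(H[g == lv].std(axis=0), 0, atol=1e-10)


def test_drop_degenerate_columns():
    X = np.column_stack([np.ones(5), np.arange(5.0)])
    out, kept, mask = drop_degenerate_columns(X, ["const", "var"])
    assert kept == ["var"]
    assert out.shape == (5, 1)
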