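import numpy as np
import pytest
from scipy import stats as sps

from gpsel import (
    FeatureScores,
    GenotypeMatrix,
    MarkerSelector,
    VanRadenEncoder,
    allele_stats,
    grm_vanraden,
    lmm_association_scan,
    multisurf_minibatched,
    multisurf_reference,
    pca_covariates,
    select_by_maf,
    select_top_k,
)
from gpsel.genotypes import MarkerStats


def _stats(mafs: dict) -> MarkerStats:
    markers = list(mafs)
    p = np.array([mafs[m] for m in markers])
    return MarkerStats(markers, p, np.minimum(p, 1 - p),
                       np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1))


class TestSelection:
    def test_maf_ranking(self):
        assert select_by_maf(_stats({"a": 0.1, "b": 0.5, "c": 0.3}), 2) == ["b", "c"]

    def test_k_equals_m_preserves_input_order(self):
        assert select_by_maf(_stats({"z": 0.2, "a": 0.4}), 2) == ["z", "a"]

    def test_tie_break_by_identifier(self):
        sel = select_by_maf(_stats({"b": 0.3, "a": 0.3, "c": 0.3}), 2)
        assert sorted(sel) == ["a", "b"]

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            select_by_maf(_stats({"a": 0.1}), 2)

    def test_top_k_by_lowest_pvalue(self):
        from gpsel.selectors import LmmScanResult

        res = LmmScanResult(["a", "b", "c"], np.zeros(3), np.ones(3), np.zeros(3),
                            np.array([0.9, 1e-6, 0.04]), 1.0, 1.0)
        assert select_top_k(res, 2) == ["b", "c"]
        assert select_top_k(res, 0) == []

    def test_nan_scores_never_selected(self):
        fs = FeatureScores(["a", "b", "c"], np.array([np.nan, 1.0, 2.0]), True, "x")
        assert select_top_k(fs, 2) == ["b", "c"]
        with pytest.raises(ValueError, match="scorable"):
            select_top_k(fs, 3)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(5)
    n = 30
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 4))
    X[:, 0] = y * 3 + rng.standard_normal(n) * 0.1  # separating feature
    return X, y


class TestMultiSURF:

    def test_informative_feature_outranks_noise(self, planted):
        X, y = planted
        s = multisurf_reference(X, y, "classification")
        assert s.scores[0] > s.scores[1:].max()

    @pytest.mark.parametrize("task", ["classification", "regression"])
    def test_minibatch_equals_reference(self, task):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((50, 20))
        y = X[:, 3] + rng.standard_normal(50) * 0.5
        if task == "classification":
            y = (y > np.median(y)).astype(int)
        ref = multisurf_reference(X, y, task)
        for bs, seed in [(64, 0), (7, 3), (2, 11)]:
            mb = multisurf_minibatched(X, y, task, batch_size=bs, seed=seed)
            assert np.abs(ref.scores - mb.scores).max() < 1e-12

    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        a = multisurf_minibatched(X, y, "regression", 4, seed=2)
        b = multisurf_minibatched(X, y, "regression", 4, seed=2)
        assert np.array_equal(a.scores, b.scores)

    def test_duplicate_features_score_equally(self, planted):
        X, y = planted
        X2 = np.column_stack([X, X[:, 0]])
        s = multisurf_reference(X2, y, "classification")
        assert abs(s.scores[0] - s.scores[-1]) < 1e-12

    def test_permuted_target_removes_advantage(self, planted):
        X, y = planted
        base = multisurf_reference(X, y, "classification")
        advantage = base.scores[0] - np.mean(base.scores[1:])
        perm_adv = []
        for s in range(20):
            yp = np.random.default_rng(s).permutation(y)
            sp = multisurf_reference(X, yp, "classification")
            perm_adv.append(sp.scores[0] - np.mean(sp.scores[1:]))
        assert np.mean(perm_adv) < advantage / 2

    def test_input_validation(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="constant target"):
            multisurf_reference(X, np.ones(5), "regression")
        with pytest.raises(ValueError, match="single-class"):
            multisurf_reference(X, np.ones(5), "classification")
        with pytest.raises(ValueError, match="batch_size"):
            multisurf_minibatched(X, np.arange(5.0), "regression", batch_size=1)


class TestPcaCovariates:
    def test_zero_mean_and_reconstruction(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((30, 6))
        S = pca_covariates(Z, 3)
        assert np.allclose(S.mean(axis=0), 0, atol=1e-10)
        # full-rank reconstruction through sklearn PCA
        from sklearn.decomposition import PCA

        p = PCA(svd_solver="full").fit(Z)
        assert np.allclose(p.inverse_transform(p.transform(Z)), Z, atol=1e-8)

    def test_pc1_separates_two_families(self, small_populations):
        from sklearn.metrics import silhouette_score

        pop = small_populations["unbalanced"]
        idx = np.flatnonzero(pop.family < 2)
        G = pop.genotypes().subset_samples(idx)
        Z = VanRadenEncoder().fit_transform(G)
        s = pca_covariates(Z, 1)
        assert silhouette_score(s, pop.family[idx]) > 0

    def test_rank_guard(self):
        Z = np.ones((5, 3))
        with pytest.raises(ValueError, match="rank"):
            pca_covariates(Z, 2)


class TestLmmScan:
    def test_identity_kinship_matches_ols(self):
        rng = np.random.default_rng(1)
        n, m = 120, 40
        X = rng.binomial(2, 0.4, (n, m))
        y = rng.standard_normal(n)
        G = GenotypeMatrix([f"s{i}" for i in range(n)], [f"m{j}" for j in range(m)], X)
        scan = lmm_association_scan(G, y, None, np.eye(n))
        ols = np.array([sps.linregress(X[:, j], y).pvalue for j in range(m)])
        assert np.nanmax(np.abs(scan.pvalue - ols)) < 1e-8

    def test_large_effect_qtl_top_ranked(self):
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(40 + s)
            X = rng.binomial(2, 0.3, (300, 120))
            g = X[:, 11].astype(float)
            y = np.sqrt(0.25 / g.var()) * g + rng.standard_normal(300)
            G = GenotypeMatrix([f"s{i}" for i in range(300)],
                               [f"m{j}" for j in range(120)], X)
            enc = VanRadenEncoder().fit(G)
            K = grm_vanraden(enc.transform(G), enc.stats_)
            scan = lmm_association_scan(G, y, None, K)
            hits += int(np.nanargmin(scan.pvalue) == 11)
        assert hits >= 4

    def test_variance_components_nonnegative_and_pvalues_in_unit(self):
        rng = np.random.default_rng(2)
        X = rng.binomial(2, 0.5, (80, 30))
        y = rng.standard_normal(80)
        G = GenotypeMatrix([f"s{i}" for i in range(80)], [f"m{j}" for j in range(30)], X)
        enc = VanRadenEncoder().fit(G)
        K = grm_vanraden(enc.transform(G), enc.stats_)
        scan = lmm_association_scan(G, y, None, K)
        assert scan.sigma2_g >= 0 and scan.sigma2_e >= 0
        ok = np.isfinite(scan.pvalue)
        assert np.all((scan.pvalue[ok] >= 0) & (scan.pvalue[ok] <= 1))

    def test_singular_covariates_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.binomial(2, 0.5, (30, 5))
        G = GenotypeMatrix([f"s{i}" for i in range(30)], [f"m{j}" for j in range(5)], X)
        C = np.ones((30, 1))  # duplicates the intercept
        with pytest.raises(ValueError, match="[Ss]ingular"):
            lmm_association_scan(G, rng.standard_normal(30), C, np.eye(30))


class TestMarkerSelector:
    @pytest.mark.parametrize("method", ["maf", "multisurf", "lmm"])
    def test_fit_transform_and_json_roundtrip(self, method, mixed_dataset):
        sel = MarkerSelector(method, k=20, seed=1).fit(
            mixed_dataset.G, mixed_dataset.y
        )
        sub = sel.transform(mixed_dataset.G)
        assert sub.n_markers == 20
        restored = MarkerSelector.from_json(sel.to_json())
        assert restored.selected_ == sel.selected_

    def test_repeated_fit_identical(self, mixed_dataset):
        a = MarkerSelector("lmm", k=15, seed=3).fit(mixed_dataset.G, mixed_dataset.y)
        b = MarkerSelector("lmm", k=15, seed=3).fit(mixed_dataset.G, mixed_dataset.y)
        assert a.selected_ == b.selected_
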