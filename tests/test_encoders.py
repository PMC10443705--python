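import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpsel import (
    GenotypeMatrix,
    NOIAAdditiveEncoder,
    NOIADominanceEncoder,
    OneHotDosageEncoder,
    VanRadenEncoder,
    allele_stats,
    distance_matrix,
    epistasis_matrices,
    grm_vanraden,
    noia_kernels,
)


def _gm(dosages):
    d = np.asarray(dosages)
    return GenotypeMatrix(
        [f"s{i}" for i in range(d.shape[0])], [f"m{j}" for j in range(d.shape[1])], d
    )


def _from_freqs(p00, p01, p11, n=40):
    """Build a single-marker population realising the genotype frequencies."""
    counts = np.round(np.array([p00, p01, p11]) * n).astype(int)
    col = np.repeat([0, 1, 2], counts)
    return _gm(col.reshape(-1, 1))


class TestOneHot:
    def test_indicator_examples(self):
        X = OneHotDosageEncoder().fit_transform(_gm([[0, 2], [1, 1]]))
        assert X.tolist() == [[1, 0, 0, 0, 0, 1], [0, 1, 0, 0, 1, 0]]

    def test_row_sums_equal_marker_count(self):
        G = _gm(np.random.default_rng(0).integers(0, 3, (10, 7)))
        X = OneHotDosageEncoder().fit_transform(G)
        assert np.all(X.sum(axis=1) == 7)

    def test_missing_rejected_with_coordinates(self):
        G = GenotypeMatrix(["a"], ["mk"], np.array([[-1]]))
        with pytest.raises(ValueError, match="sample a, marker mk"):
            OneHotDosageEncoder().fit(G)


class TestVanRaden:
    def test_centering_values(self):
        # p=0.5 marker: dosage 2 -> 1, dosage 0 -> -1; p=0.25: dosage 1 -> 0.5
        G = _gm([[2, 1], [0, 1], [2, 0], [0, 0]])
        Z = VanRadenEncoder().fit_transform(G)
        assert Z[0, 0] == pytest.approx(1.0)
        assert Z[1, 0] == pytest.approx(-1.0)
        assert Z[0, 1] == pytest.approx(0.5)  # 1 - 2*0.25
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-10)

    def test_frozen_stats_transform_new_samples(self):
        G = _gm([[0], [2], [2], [0]])
        enc = VanRadenEncoder().fit(G)
        Znew = enc.transform(_gm([[1]]))
        assert Znew[0, 0] == pytest.approx(1 - 2 * 0.5)

    def test_marker_mismatch_errors(self):
        enc = VanRadenEncoder().fit(_gm([[0], [2]]))
        other = GenotypeMatrix(["x"], ["other"], np.array([[1]]))
        with pytest.raises(ValueError, match="marker set mismatch"):
            enc.transform(other)

    def test_fit_transform_idempotent_on_training_data(self):
        G = _gm(np.random.default_rng(1).integers(0, 3, (20, 10)))
        enc = VanRadenEncoder().fit(G)
        assert np.array_equal(enc.transform(G), enc.fit(G).transform(G))


class TestNOIA:
    def test_additive_codes_symmetric_freqs(self):
        G = _from_freqs(0.25, 0.5, 0.25)
        HA = NOIAAdditiveEncoder().fit_transform(G)
        codes = {g: HA[np.flatnonzero(G.dosages[:, 0] == g)[0], 0] for g in (0, 1, 2)}
        assert codes[0] == pytest.approx(-1)
        assert codes[1] == pytest.approx(0)
        assert codes[2] == pytest.approx(1)
        assert HA[:, 0].sum() == pytest.approx(0, abs=1e-10)

    def test_dominance_codes_symmetric_freqs(self):
        G = _from_freqs(0.25, 0.5, 0.25)
        HD = NOIADominanceEncoder().fit_transform(G)
        codes = {g: HD[np.flatnonzero(G.dosages[:, 0] == g)[0], 0] for g in (0, 1, 2)}
        assert codes[0] == pytest.approx(-0.5)
        assert codes[1] == pytest.approx(0.5)
        assert codes[2] == pytest.approx(-0.5)

    def test_dominance_dropped_without_heterozygotes(self):
        G = _from_freqs(0.5, 0.0, 0.5)
        with pytest.warns(UserWarning, match="dominance"):
            enc = NOIADominanceEncoder().fit(G)
        assert enc.dropped_ == ["m0"]
        assert enc.fit(G).transform(G).shape[1] == 0

    @settings(deadline=None, max_examples=60)
    @given(st.integers(1, 10_000))
    def test_orthogonality_random_frequencies(self, seed):
        """Frequency-weighted means of HA and HD and their cross-product
        vanish for arbitrary genotype frequencies."""
        rng = np.random.default_rng(seed)
        f = rng.dirichlet([1.0, 1.0, 1.0])
        if f[1] < 0.02 or min(f[0] + f[2], 1 - abs(f[0] - f[2])) < 0.02:
            return  # no dominance contrast: column legitimately dropped
        counts = np.maximum(np.round(f * 200).astype(int), 1)
        col = np.repeat([0, 1, 2], counts)
        G = _gm(col.reshape(-1, 1))
        HA = NOIAAdditiveEncoder().fit_transform(G)
        HD = NOIADominanceEncoder().fit_transform(G)
        assert abs(HA[:, 0].mean()) < 1e-10
        assert abs(HD[:, 0].mean()) < 1e-10
        assert abs(np.mean(HA[:, 0] * HD[:, 0])) < 1e-10


class TestRelationshipMatrices:
    def test_grm_two_sample_hand_value(self):
        G = _gm([[0], [2]])
        enc = VanRadenEncoder().fit(G)
        K = grm_vanraden(enc.transform(G), enc.stats_)
        assert np.allclose(K.values, [[2, -2], [-2, 2]])

    def test_grm_monomorphic_rejected(self):
        G = _gm([[2], [2]])
        enc = VanRadenEncoder().fit(G)
        with pytest.raises(ValueError, match="monomorphic"):
            grm_vanraden(enc.transform(G), enc.stats_)

    def test_distance_metrics(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        Dm = distance_matrix(Z, "manhattan")
        De = distance_matrix(Z, "euclidean")
        assert Dm.values[0, 1] == pytest.approx(2)
        assert De.values[0, 1] == pytest.approx(np.sqrt(2))
        assert Dm.values[0, 2] == 0
        assert np.all(np.diag(Dm.values) == 0)

    def test_distance_triangle_inequality(self):
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((15, 6))
        for metric in ("manhattan", "euclidean"):
            D = distance_matrix(Z, metric).values
            for i in range(15):
                for j in range(15):
                    for k in range(15):
                        assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_epistasis_normalisation_and_psd(self):
        rng = np.random.default_rng(3)
        G = _gm(rng.integers(0, 3, (30, 50)))
        HA = NOIAAdditiveEncoder().fit_transform(G)
        HD = NOIADominanceEncoder().fit_transform(G)
        GA, GD = noia_kernels(HA, HD)
        epi = epistasis_matrices(GA, GD)
        assert set(epi) == {"epi_AA", "epi_AD", "epi_DD"}
        for K in epi.values():
            assert np.mean(np.diag(K.values)) == pytest.approx(1.0)
            ev = np.linalg.eigvalsh(K.values)
            assert ev.min() >= -1e-8 * ev.max()

    def test_epistasis_identity_fixed_point(self):
        from gpsel.encoders import RelationshipMatrix

        I = RelationshipMatrix(np.eye(4), "noia_A", list("abcd"))
        epi = epistasis_matrices(I, I)
        assert np.allclose(epi["epi_AA"].values, np.eye(4))
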