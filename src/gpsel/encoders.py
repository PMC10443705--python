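"""Marker encodings and genomic relationship / similarity matrices.

Encodings
---------
* one-hot: each marker expands to three indicator columns (dosage 0/1/2).
* Van Raden centering: ``Z[i,j] = dosage[i,j] - 2 p_j`` with allele
  frequencies frozen on the training set; this is the centering applied
  before GRM and distance computation.  Optional per-marker variance
  standardisation (divide by sqrt(2 p q)) is exposed as a flag.
* NOIA additive/dominance: the orthogonal parameterisation under observed
  genotype frequencies.  With genotype frequencies (p00, p01, p11):

  additive codes   a(g) = g - (p01 + 2 p11)
  dominance codes  d(0) = -2 p01 p11 / d,  d(1) = 4 p00 p11 / d,
                   d(2) = -2 p00 p01 / d,  d = p00 + p11 - (p00 - p11)^2

  Both are frequency-weighted mean zero and mutually orthogonal, so the
  additive and dominance variance components are separable.

Relationship matrices
---------------------
Van Raden GRM ``Z Z' / (2 sum p q)``, Manhattan/Euclidean distances on the
centered dosages, NOIA additive/dominance kernels, and epistasis kernels as
Hadamard products of the NOIA kernels (AA, AD, DD), each rescaled to mean
diagonal one.

All encoders are scikit-learn transformers: statistics are frozen at fit
time and re-applied verbatim at transform time, so there is no information
flow from prediction-time samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import pairwise_distances

from .genotypes import GenotypeMatrix, MarkerStats, allele_stats

RELATIONSHIP_KINDS = ("vanraden", "manhattan", "euclidean", "epi_AA", "epi_AD", "epi_DD")


@dataclass
class RelationshipMatrix:
    """Symmetric samples x samples relationship or distance matrix."""

    values: np.ndarray
    kind: str
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in RELATIONSHIP_KINDS and self.kind not in ("noia_A", "noia_D"):
            raise ValueError(f"unknown relationship kind {self.kind!r}")
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")


def _as_genotype(X) -> GenotypeMatrix:
    if isinstance(X, GenotypeMatrix):
        return X
    X = np.asarray(X)
    return GenotypeMatrix(
        [f"s{i}" for i in range(X.shape[0])],
        [f"m{j}" for j in range(X.shape[1])],
        X,
    )


def _check_complete(G: GenotypeMatrix) -> np.ndarray:
    if G.missing_mask().any():
        i, j = np.argwhere(G.missing_mask())[0]
        raise ValueError(
            f"missing genotype at sample {G.samples[i]}, marker {G.markers[j]}; "
            "impute first (GenotypeMatrix.impute_mode)"
        )
    return G.dosages


class OneHotDosageEncoder(BaseEstimator, TransformerMixin):
    """Expand each marker into three 0/1/2 indicator columns (n x 3m)."""

    def fit(self, X, y=None):
        G = _as_genotype(X)
        _check_complete(G)
        self.markers_ = list(G.markers)
        self.feature_names_ = [f"{m}:{g}" for m in G.markers for g in (0, 1, 2)]
        return self

    def transform(self, X):
        G = _as_genotype(X)
        d = _check_complete(G)
        n, m = d.shape
        out = np.zeros((n, 3 * m))
        for g in (0, 1, 2):
            out[:, g::3] = d == g
        return out


class VanRadenEncoder(BaseEstimator, TransformerMixin):
    """Center dosages by twice the training allele frequency.

    ``standardize=True`` additionally divides each column by
    ``sqrt(2 p (1 - p))``.  Default is centering only.
    """

    def __init__(self, standardize: bool = False):
        self.standardize = standardize

    def fit(self, X, y=None):
        G = _as_genotype(X)
        _check_complete(G)
        stats = allele_stats(G)
        if stats.undefined.any():
            raise ValueError("cannot fit on all-missing markers")
        self.markers_ = list(G.markers)
        self.stats_ = stats
        return self

    def transform(self, X):
        G = _as_genotype(X)
        d = _check_complete(G)
        if list(G.markers) != self.markers_:
            missing = set(G.markers) - set(self.markers_)
            raise ValueError(
                f"marker set mismatch with fitted stats (unknown: {sorted(missing)[:5]})"
                if missing
                else "marker order differs from fitted stats"
            )
        Z = d - 2.0 * self.stats_.p
        if self.standardize:
            denom = np.sqrt(2.0 * self.stats_.p * (1.0 - self.stats_.p))
            denom[denom == 0] = 1.0
            Z = Z / denom
        return Z


class NOIAAdditiveEncoder(BaseEstimator, TransformerMixin):
    """NOIA additive codes: dosage centered by the observed mean dosage."""

    def fit(self, X, y=None):
        G = _as_genotype(X)
        _check_complete(G)
        stats = allele_stats(G)
        if stats.undefined.any():
            raise ValueError("cannot fit on all-missing markers")
        self.markers_ = list(G.markers)
        # mean dosage under observed genotype frequencies = p01 + 2 p11
        self.offset_ = stats.genotype_freqs[:, 1] + 2.0 * stats.genotype_freqs[:, 2]
        return self

    def transform(self, X):
        G = _as_genotype(X)
        d = _check_complete(G)
        if list(G.markers) != self.markers_:
            raise ValueError("marker set mismatch with fitted stats")
        return d - self.offset_


class NOIADominanceEncoder(BaseEstimator, TransformerMixin):
    """NOIA dominance codes, orthogonal to the additive codes.

    Markers whose denominator ``p00 + p11 - (p00 - p11)^2`` falls below
    ``tol`` carry no dominance contrast (fixed or heterozygote-free); their
    columns are dropped with a warning and recorded in ``dropped_``.
    """

    def __init__(self, tol: float = 1e-8):
        self.tol = tol

    def fit(self, X, y=None):
        G = _as_genotype(X)
        _check_complete(G)
        stats = allele_stats(G)
        if stats.undefined.any():
            raise ValueError("cannot fit on all-missing markers")
        f = stats.genotype_freqs
        p00, p01, p11 = f[:, 0], f[:, 1], f[:, 2]
        d = p00 + p11 - (p00 - p11) ** 2
        # no heterozygotes means no dominance contrast even when d > 0
        keep = (d > self.tol) & (p01 > self.tol)
        self.markers_ = list(G.markers)
        self.kept_markers_ = [m for m, k in zip(G.markers, keep) if k]
        self.dropped_ = [m for m, k in zip(G.markers, keep) if not k]
        if self.dropped_:
            warnings.warn(
                f"dropped {len(self.dropped_)} marker(s) without dominance "
                f"contrast: {self.dropped_[:5]}",
                stacklevel=2,
            )
        self.keep_ = keep
        with np.errstate(divide="ignore", invalid="ignore"):
            codes = np.stack(
                [-2.0 * p01 * p11 / d, 4.0 * p00 * p11 / d, -2.0 * p00 * p01 / d]
            )
        self.codes_ = codes[:, keep]  # (3, m_kept)
        return self

    def transform(self, X):
        G = _as_genotype(X)
        d = _check_complete(G)
        if list(G.markers) != self.markers_:
            raise ValueError("marker set mismatch with fitted stats")
        dk = d[:, self.keep_]
        out = np.empty(dk.shape)
        for g in (0, 1, 2):
            mask = dk == g
            out[mask] = np.broadcast_to(self.codes_[g], dk.shape)[mask]
        return out


# ---------------------------------------------------------------------------
# Relationship matrices


def grm_vanraden(Z: np.ndarray, stats: MarkerStats, samples: list[str] | None = None) -> RelationshipMatrix:
    """Van Raden genomic relationship matrix ``Z Z' / (2 sum p(1-p))``."""
    Z = np.asarray(Z, dtype=float)
    denom = 2.0 * np.nansum(stats.p * (1.0 - stats.p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: Van Raden denominator is zero")
    G = Z @ Z.T / denom
    G = (G + G.T) / 2.0
    if samples is None:
        samples = [f"s{i}" for i in range(G.shape[0])]
    return RelationshipMatrix(G, "vanraden", samples)


def distance_matrix(Z: np.ndarray, metric: str, samples: list[str] | None = None) -> RelationshipMatrix:
    """Pairwise Manhattan or Euclidean distances on Van Raden-centered rows."""
    if metric not in ("manhattan", "euclidean"):
        raise ValueError(f"metric must be manhattan or euclidean, got {metric!r}")
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] == 0:
        raise ValueError("empty marker set")
    D = pairwise_distances(Z, metric=metric)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    if samples is None:
        samples = [f"s{i}" for i in range(D.shape[0])]
    return RelationshipMatrix(D, metric, samples)


def _trace_normalised_kernel(H: np.ndarray, kind: str, samples: list[str]) -> RelationshipMatrix:
    K = H @ H.T
    md = np.mean(np.diag(K))
    if md <= 0:
        raise ValueError("degenerate kernel: zero mean diagonal")
    return RelationshipMatrix((K + K.T) / (2.0 * md), kind, samples)


def noia_kernels(HA: np.ndarray, HD: np.ndarray, samples: list[str] | None = None):
    """Additive and dominance NOIA kernels, trace-mean normalised."""
    if samples is None:
        samples = [f"s{i}" for i in range(HA.shape[0])]
    GA = _trace_normalised_kernel(np.asarray(HA, float), "noia_A", samples)
    GD = _trace_normalised_kernel(np.asarray(HD, float), "noia_D", samples)
    return GA, GD


def epistasis_matrices(GA: RelationshipMatrix, GD: RelationshipMatrix) -> dict[str, RelationshipMatrix]:
    """Epistasis similarity kernels as Hadamard products of NOIA kernels.

    Each product (AA, AD, DD) is rescaled by its own mean diagonal so the
    mean diagonal is exactly one; by the Schur product theorem each remains
    positive semi-definite.
    """
    A, D = GA.values, GD.values
    if A.shape != D.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {D.shape}")
    out = {}
    for kind, M in (("epi_AA", A * A), ("epi_AD", A * D), ("epi_DD", D * D)):
        md = np.mean(np.diag(M))
        if md <= 0:
            raise ValueError(f"degenerate {kind} kernel")
        out[kind] = RelationshipMatrix((M + M.T) / (2.0 * md), kind, GA.samples)
    return out
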