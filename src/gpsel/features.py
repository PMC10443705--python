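"""Candidate feature blocks and their transforms.

The pipeline assembles up to six named blocks — markers, marker_distance,
marker_nonlinear, groups, covariates, interactions — each fitted on
training rows only and frozen for transform.  This module provides the
block-level machinery: approximate (Nystroem) kernel features on Van Raden
pre-scaled markers, quantile / robust / z-score scaling, polynomial
covariate expansion, ANOVA f-score per-block reduction, and grouping-factor
encodings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif, f_regression
from sklearn.kernel_approximation import Nystroem
from sklearn.preprocessing import PolynomialFeatures, QuantileTransformer, RobustScaler

KERNEL_KINDS = ("rbf", "laplacian", "poly2")


@dataclass
class KernelSpec:
    """Approximate-kernel configuration.

    gamma=None uses 1 / (q * var(Z)) computed at fit time (the scale-free
    default); poly2 always has degree 2 with coef0 = 1.
    """

    kind: str = "rbf"
    gamma: float | None = None
    n_components: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"kernel kind must be one of {KERNEL_KINDS}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("kernel bandwidth must be positive")


@dataclass
class FeatureBlock:
    """A named numeric feature set with its fitted transformer."""

    name: str
    matrix: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    transformer: object | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.isfinite(self.matrix).all():
            raise ValueError(f"block {self.name!r} contains NaN/Inf")
        if not self.feature_names:
            self.feature_names = [f"{self.name}{j}" for j in range(self.matrix.shape[1])]


class ApproxKernelFeatures(BaseEstimator, TransformerMixin):
    """Nystroem landmark approximation of an RBF/Laplacian/poly2 kernel.

    Landmark rows are sampled without replacement (seeded); features are
    the cross-kernel to the landmarks whitened by the landmark kernel's
    inverse square root, so with landmarks = all training rows the feature
    Gram matrix reproduces the exact kernel.
    """

    def __init__(self, spec: KernelSpec | None = None):
        self.spec = spec or KernelSpec()

    def fit(self, Z, y=None):
        Z = np.asarray(Z, dtype=float)
        n, q = Z.shape
        spec = self.spec
        if spec.n_components > n:
            raise ValueError(f"landmark count {spec.n_components} exceeds n_train={n}")
        gamma = spec.gamma
        if gamma is None:
            v = Z.var()
            gamma = 1.0 / (q * v) if v > 0 else 1.0 / q
        self.gamma_ = gamma
        kernel = {"rbf": "rbf", "laplacian": "laplacian", "poly2": "polynomial"}[spec.kind]
        self.nystroem_ = Nystroem(
            kernel=kernel,
            gamma=gamma,
            degree=2,
            coef0=1.0,
            n_components=spec.n_components,
            random_state=spec.seed,
        ).fit(Z)
        return self

    def transform(self, Z):
        return self.nystroem_.transform(np.asarray(Z, dtype=float))


def approx_kernel_features(Z, spec: KernelSpec) -> FeatureBlock:
    """Fit-and-transform convenience for the marker_nonlinear block."""
    t = ApproxKernelFeatures(spec).fit(Z)
    return FeatureBlock("marker_nonlinear", t.transform(Z), transformer=t)


class QuantileScaler(BaseEstimator, TransformerMixin):
    """Per-column rank map to a normal or uniform target distribution.

    1000 reference quantiles with linear interpolation; new data is mapped
    through the fitted empirical quantiles and clipped to the fitted range.
    Constant columns map to the target distribution's median.
    """

    def __init__(self, output: str = "normal"):
        if output not in ("normal", "uniform"):
            raise ValueError("output must be 'normal' or 'uniform'")
        self.output = output

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        const = np.ptp(X, axis=0) == 0
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant column(s) map to the median", stacklevel=2
            )
        self.qt_ = QuantileTransformer(
            n_quantiles=min(1000, X.shape[0]),
            output_distribution=self.output,
            subsample=1_000_000,
        ).fit(X)
        return self

    def transform(self, X):
        return self.qt_.transform(np.asarray(X, dtype=float))


def quantile_scale(F, output: str = "normal") -> FeatureBlock:
    t = QuantileScaler(output).fit(F)
    return FeatureBlock("quantile", t.transform(F), transformer=t)


class ZScoreScaler(BaseEstimator, TransformerMixin):
    """(x - mean) / sd with the n-1 (sample) convention; constant columns
    become zeros."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        if np.any(sd == 0):
            warnings.warn("constant column(s) scaled to zeros", stacklevel=2)
        self.sd_ = np.where(sd == 0, 1.0, sd)
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) / self.sd_


class SafeRobustScaler(BaseEstimator, TransformerMixin):
    """(x - median) / IQR with zero-IQR columns mapped to zeros."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.center_ = np.median(X, axis=0)
        q75, q25 = np.percentile(X, [75, 25], axis=0)
        iqr = q75 - q25
        if np.any(iqr == 0):
            warnings.warn("zero-IQR column(s) scaled to zeros", stacklevel=2)
        self.scale_ = np.where(iqr == 0, 1.0, iqr)
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.center_) / self.scale_


COVARIATE_SCALERS = {"zscore": ZScoreScaler, "robust": SafeRobustScaler, "quantile": QuantileScaler}


def scale_covariates(C, method: str = "zscore") -> FeatureBlock:
    """Scale numeric covariates by z-score, robust (median/IQR) or quantile map."""
    if method not in COVARIATE_SCALERS:
        raise ValueError(f"unknown covariate scaler {method!r}")
    t = COVARIATE_SCALERS[method]().fit(np.asarray(C, float))
    return FeatureBlock("covariates", t.transform(C), transformer=t)


class PolynomialExpander(BaseEstimator, TransformerMixin):
    """Monomials of the (scaled) covariates up to total degree 1-3, no bias."""

    def __init__(self, degree: int = 1):
        if degree not in (1, 2, 3):
            raise ValueError("polynomial degree must be 1, 2 or 3")
        self.degree = degree

    def fit(self, X, y=None):
        self.poly_ = PolynomialFeatures(degree=self.degree, include_bias=False).fit(
            np.asarray(X, float)
        )
        return self

    def transform(self, X):
        return self.poly_.transform(np.asarray(X, float))


def polynomial_expand(C, degree: int = 1) -> FeatureBlock:
    t = PolynomialExpander(degree).fit(C)
    return FeatureBlock("covariates_poly", t.transform(C), transformer=t)


class AnovaFSelector(BaseEstimator, TransformerMixin):
    """Keep the k features with largest univariate ANOVA F against y.

    Regression uses the linear F = r^2 (n-2) / (1 - r^2); classification
    the one-way between-class F.  NaN scores rank last; ties break toward
    the earlier column.  k > q keeps everything with a warning.
    """

    def __init__(self, k: int = 100, task: str = "regression"):
        self.k = k
        self.task = task

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        q = X.shape[1]
        k = self.k
        if k > q:
            warnings.warn(f"k={k} > {q} features: keeping all", stacklevel=2)
            k = q
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.task == "regression":
                F, _ = f_regression(X, np.asarray(y, float))
            else:
                F, _ = f_classif(X, y)
        F = np.where(np.isnan(F), -np.inf, F)
        order = np.argsort(-F, kind="stable")[:k]
        self.support_ = np.sort(order)
        self.scores_ = F
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.support_]


def anova_f_select(F, y, k: int, task: str = "regression") -> FeatureBlock:
    t = AnovaFSelector(k, task).fit(np.asarray(F, float), y)
    return FeatureBlock("anova_selected", t.transform(F), transformer=t)


class GroupEncoder(BaseEstimator, TransformerMixin):
    """Grouping factors as one-hot indicators or their first k PCs.

    Levels are frozen at fit; unseen levels at transform map to an all-zero
    indicator row (with a warning).  Single-level factors encode to nothing.
    """

    def __init__(self, mode: str = "onehot", k: int = 2):
        if mode not in ("onehot", "pca_k"):
            raise ValueError("mode must be 'onehot' or 'pca_k'")
        self.mode = mode
        self.k = k

    def fit(self, groups, y=None):
        g = np.asarray(groups)
        if g.ndim == 1:
            g = g[:, None]
        self.levels_ = [np.unique(g[:, c]) for c in range(g.shape[1])]
        dropped = [c for c, lv in enumerate(self.levels_) if len(lv) < 2]
        if dropped:
            warnings.warn(f"single-level factor column(s) {dropped} dropped", stacklevel=2)
        H = self._indicators(g)
        if self.mode == "pca_k":
            k = min(self.k, max(1, np.linalg.matrix_rank(H - H.mean(0))))
            self.pca_ = PCA(n_components=k, svd_solver="full").fit(H)
        return self

    def _indicators(self, g):
        cols = []
        for c, levels in enumerate(self.levels_):
            if len(levels) < 2:
                continue
            known = np.isin(g[:, c], levels)
            if not known.all():
                warnings.warn(
                    f"{int((~known).sum())} sample(s) with unseen level in factor {c}",
                    stacklevel=2,
                )
            cols.append((g[:, c][:, None] == levels[None, :]).astype(float))
        if not cols:
            return np.zeros((g.shape[0], 0))
        return np.hstack(cols)

    def transform(self, groups):
        g = np.asarray(groups)
        if g.ndim == 1:
            g = g[:, None]
        H = self._indicators(g)
        if self.mode == "pca_k":
            return self.pca_.transform(H)
        return H


def group_features(groups, mode: str = "onehot", k: int = 2) -> FeatureBlock:
    t = GroupEncoder(mode, k).fit(groups)
    return FeatureBlock("groups", t.transform(groups), transformer=t)


def drop_degenerate_columns(X: np.ndarray, names: list[str] | None = None):
    """Drop constant columns post-assembly; returns (matrix, kept names)."""
    X = np.asarray(X, dtype=float)
    keep = np.ptp(X, axis=0) > 0
    if names is None:
        names = [f"c{j}" for j in range(X.shape[1])]
    kept = [nm for nm, k in zip(names, keep) if k]
    return X[:, keep], kept, keep
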