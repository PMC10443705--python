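"""Marker ranking and selection.

Three selectors rank markers before model fitting:

* minor-allele frequency (closest to 0.5 best),
* MultiSURF relevance (Relief-family scorer with an adaptive per-instance
  neighbourhood threshold and dead-band), in a brute-force reference form
  and a minibatched form that is exactly equivalent when the batch covers
  all samples,
* a kinship-corrected linear-mixed-model association scan run in two
  stages: variance components are estimated once on the null model
  (restricted maximum likelihood on the kinship eigen-rotated system), then
  each marker gets a generalised-least-squares Wald test holding the
  variance ratio fixed — the EMMAX approximation.

All selectors are pure functions of the training data and seed, and fitted
selector objects carry their chosen marker lists so held-out samples can
never influence selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .encoders import RelationshipMatrix, VanRadenEncoder, grm_vanraden
from .genotypes import GenotypeMatrix, MarkerStats, allele_stats


@dataclass
class FeatureScores:
    """Per-marker relevance scores with the direction of preference."""

    markers: list[str]
    scores: np.ndarray
    higher_is_better: bool
    method: str


@dataclass
class LmmScanResult:
    """Per-marker mixed-model association statistics.

    ``sigma2_g``/``sigma2_e`` are the null-model genetic and residual
    variance components; the per-marker tests hold their ratio fixed.
    """

    markers: list[str]
    beta: np.ndarray
    se: np.ndarray
    wald: np.ndarray
    pvalue: np.ndarray
    sigma2_g: float
    sigma2_e: float
    covariates: str = "intercept"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "marker": self.markers,
                "beta": self.beta,
                "se": self.se,
                "wald": self.wald,
                "pvalue": self.pvalue,
            }
        )


def _ranked_subset(markers: list[str], key: np.ndarray, k: int) -> list[str]:
    """Top-k marker ids by descending key; ties break toward the smaller
    identifier; the selected set is returned in input order."""
    order = sorted(range(len(markers)), key=lambda j: (-key[j], markers[j]))
    chosen = set(order[:k])
    return [m for j, m in enumerate(markers) if j in chosen]


def select_by_maf(stats: MarkerStats, k: int) -> list[str]:
    """The k markers with minor-allele frequency closest to 0.5."""
    m = len(stats.markers)
    if k > m:
        raise ValueError(f"k={k} exceeds {m} markers")
    maf = np.where(np.isnan(stats.maf), -np.inf, stats.maf)
    return _ranked_subset(stats.markers, maf, k)


def select_top_k(scores, k: int) -> list[str]:
    """Top-k markers from FeatureScores or LmmScanResult.

    NaN-scored markers are never selected.  k=0 returns an empty list
    (the marker block is dropped entirely).
    """
    if isinstance(scores, LmmScanResult):
        key = -scores.pvalue  # lowest p best
        markers = scores.markers
    else:
        key = scores.scores if scores.higher_is_better else -scores.scores
        markers = scores.markers
    key = np.where(np.isnan(key), -np.inf, key)
    scorable = int(np.sum(np.isfinite(key)))
    if k > scorable:
        raise ValueError(f"k={k} exceeds {scorable} scorable markers")
    return _ranked_subset(markers, key, k)


# ---------------------------------------------------------------------------
# MultiSURF


def _relief_prepare(X: np.ndarray, y: np.ndarray, task: str):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < 3:
        raise ValueError("MultiSURF needs at least 3 instances")
    if np.isnan(X).any():
        raise ValueError("MultiSURF input contains missing values")
    if task == "classification":
        if len(np.unique(y)) < 2:
            raise ValueError("single-class target")
    elif task == "regression":
        y = y.astype(float)
        if np.ptp(y) == 0:
            raise ValueError("constant target in regression mode")
    else:
        raise ValueError(f"unknown task {task!r}")
    rng = np.ptp(X, axis=0)
    rng[rng == 0] = 1.0  # constant features contribute zero diff
    return X, y, rng


def _multisurf_accumulate(X, y, rng, task, targets):
    """Shared scoring core: accumulate updates for the given target rows.

    Neighbour statistics for every target are always computed against the
    whole dataset, so partitioning the targets into batches cannot change
    the result.
    """
    n, m = X.shape
    if task == "classification":
        classes, counts = np.unique(y, return_counts=True)
        prior = dict(zip(classes, counts / n))
        score = np.zeros(m)
        n_updates = 0
    else:
        ndY = 0.0
        ndF = np.zeros(m)
        ndYdF = np.zeros(m)
        n_updates = 0
        score = None
    for i in targets:
        diffs = np.abs(X - X[i]) / rng  # (n, m)
        dist = diffs.sum(axis=1)
        others = np.arange(n) != i
        d_others = dist[others]
        T = d_others.mean()
        D = d_others.std() / 2.0
        neigh = np.flatnonzero(others & (dist < T - D))
        if neigh.size == 0:
            continue
        if task == "classification":
            for j in neigh:
                if y[j] == y[i]:
                    score -= diffs[j]
                else:
                    score += (prior[y[j]] / (1.0 - prior[y[i]])) * diffs[j]
            n_updates += neigh.size
        else:
            yr = np.ptp(np.append(y[neigh], y[i]))
            w = np.abs(y[neigh] - y[i]) / yr if yr > 0 else np.zeros(neigh.size)
            ndY += w.sum()
            ndF += diffs[neigh].sum(axis=0)
            ndYdF += w @ diffs[neigh]
            n_updates += neigh.size
    if task == "classification":
        return score, n_updates
    return (ndY, ndF, ndYdF), n_updates


def _relief_finalise(acc, n_updates, task, m):
    if n_updates == 0:
        return np.zeros(m)
    if task == "classification":
        return acc / n_updates
    ndY, ndF, ndYdF = acc
    # RReliefF combination: P(diff feature | diff target) minus
    # P(diff feature | same target), via the probability-weighted counts.
    hit_w = n_updates - ndY
    s_diff = ndYdF / ndY if ndY > 0 else np.zeros(m)
    s_same = (ndF - ndYdF) / hit_w if hit_w > 0 else np.zeros(m)
    return s_diff - s_same


def multisurf_reference(X, y, task: str = "regression") -> FeatureScores:
    """Brute-force full-data MultiSURF: the oracle the minibatched
    implementation must reproduce exactly."""
    X, y, rng = _relief_prepare(np.asarray(X, float), y, task)
    n, m = X.shape
    acc, n_updates = _multisurf_accumulate(X, y, rng, task, range(n))
    scores = _relief_finalise(acc, n_updates, task, m)
    names = [f"f{j}" for j in range(m)]
    return FeatureScores(names, scores, True, "multisurf")


def multisurf_minibatched(
    X, y, task: str = "regression", batch_size: int = 32, seed: int = 0
) -> FeatureScores:
    """Minibatched MultiSURF.

    Target instances are processed in shuffled minibatches purely to bound
    the working-set size; each target's threshold, dead-band and neighbour
    set are computed against the full dataset, so with ``batch_size >= n``
    (indeed, for any batch size) the scores equal the reference within
    floating-point associativity.
    """
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    X, y, rng = _relief_prepare(np.asarray(X, float), y, task)
    n, m = X.shape
    order = np.random.default_rng(seed).permutation(n)
    if task == "classification":
        score = np.zeros(m)
        n_updates = 0
        for start in range(0, n, batch_size):
            acc, nu = _multisurf_accumulate(X, y, rng, task, order[start : start + batch_size])
            score += acc
            n_updates += nu
        scores = _relief_finalise(score, n_updates, task, m)
    else:
        ndY, ndF, ndYdF, n_updates = 0.0, np.zeros(m), np.zeros(m), 0
        for start in range(0, n, batch_size):
            (a, b, c), nu = _multisurf_accumulate(X, y, rng, task, order[start : start + batch_size])
            ndY += a
            ndF += b
            ndYdF += c
            n_updates += nu
        scores = _relief_finalise((ndY, ndF, ndYdF), n_updates, task, m)
    names = [f"f{j}" for j in range(m)]
    return FeatureScores(names, scores, True, "multisurf_minibatch")


# ---------------------------------------------------------------------------
# PCA covariates


def pca_covariates(Z: np.ndarray, k: int) -> np.ndarray:
    """First k principal-component scores of the centered marker matrix.

    Components are ordered by decreasing explained variance; each is signed
    so its largest-magnitude loading is positive.
    """
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    rank = np.linalg.matrix_rank(Z - Z.mean(axis=0))
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    for c in range(k):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1
    return scores


# ---------------------------------------------------------------------------
# LMM association scan (two-stage, EMMAX-style)


def _reml_neg_loglik(log_delta, S, Uty, UtW):
    """Negative REML log-likelihood profiled over the variance ratio
    delta = sigma2_g / sigma2_e, on the eigen-rotated system."""
    delta = np.exp(log_delta)
    v = delta * S + 1.0
    n, c = UtW.shape
    w = 1.0 / v
    WtVW = UtW.T @ (UtW * w[:, None])
    WtVy = UtW.T @ (Uty * w)
    try:
        alpha = np.linalg.solve(WtVW, WtVy)
    except np.linalg.LinAlgError:
        return np.inf
    r = Uty - UtW @ alpha
    rss = float(r @ (r * w))
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - c)
    sign, logdet_WtVW = np.linalg.slogdet(WtVW)
    if sign <= 0:
        return np.inf
    ll = -0.5 * ((n - c) * np.log(sigma2) + np.sum(np.log(v)) + logdet_WtVW + (n - c))
    return -ll


def fit_null_lmm(y, W, K: np.ndarray):
    """REML fit of y = W a + u + e with u ~ N(0, s2g K), e ~ N(0, s2e I).

    Returns (sigma2_g, sigma2_e, eigvals, U) with K = U diag(eigvals) U'.
    """
    y = np.asarray(y, float)
    W = np.asarray(W, float)
    K = np.asarray(K, float)
    S, U = np.linalg.eigh((K + K.T) / 2.0)
    if S.min() < -1e-6 * max(S.max(), 1.0):
        raise ValueError("kinship matrix is not positive semi-definite")
    S = np.clip(S, 0.0, None)
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("singular covariate design")
    Uty = U.T @ y
    UtW = U.T @ W
    # coarse grid then local refinement keeps the 1-D profile robust
    grid = np.linspace(-10, 10, 41)
    vals = [_reml_neg_loglik(g, S, Uty, UtW) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(g0 - 1.0, g0 + 1.0),
        args=(S, Uty, UtW),
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(np.exp(res.x))
    v = delta * S + 1.0
    w = 1.0 / v
    WtVW = UtW.T @ (UtW * w[:, None])
    alpha = np.linalg.solve(WtVW, UtW.T @ (Uty * w))
    r = Uty - UtW @ alpha
    n, c = UtW.shape
    sigma2_e = float(r @ (r * w)) / (n - c)
    return delta * sigma2_e, sigma2_e, S, U


def lmm_association_scan(
    G: GenotypeMatrix | np.ndarray,
    y,
    covariates: np.ndarray | None = None,
    K: RelationshipMatrix | np.ndarray | None = None,
) -> LmmScanResult:
    """Two-stage kinship-corrected association scan.

    Stage 1 estimates the null-model variance components by REML on the
    eigen-rotated system; stage 2 tests each marker by generalised least
    squares with the variance ratio held fixed.  The per-marker statistic
    is the squared t ratio (Wald) with a Student-t reference, so with an
    identity kinship and intercept-only design the p-values coincide with
    ordinary per-marker t-tests.
    """
    if isinstance(G, GenotypeMatrix):
        Gm = G.impute_mode()
        markers = list(Gm.markers)
        X = Gm.dosages.astype(float)
        samples = list(Gm.samples)
    else:
        X = np.asarray(G, float)
        markers = [f"m{j}" for j in range(X.shape[1])]
        samples = [f"s{i}" for i in range(X.shape[0])]
    y = np.asarray(y, float)
    n = X.shape[0]
    W = np.column_stack([np.ones(n)] + ([np.asarray(covariates, float).reshape(n, -1)] if covariates is not None else []))
    cov_desc = "intercept" + ("" if covariates is None else f"+{W.shape[1] - 1}cov")
    if K is None:
        if not isinstance(G, GenotypeMatrix):
            raise ValueError("K required when G is a plain matrix")
        enc = VanRadenEncoder().fit(Gm)
        K = grm_vanraden(enc.transform(Gm), enc.stats_, samples)
    Kv = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, float)

    sigma2_g, sigma2_e, S, U = fit_null_lmm(y, W, Kv)
    delta = sigma2_g / sigma2_e if sigma2_e > 0 else 0.0
    w = 1.0 / (delta * S + 1.0)
    sw = np.sqrt(w)
    ys = (U.T @ y) * sw
    Ws = (U.T @ W) * sw[:, None]
    Xs = (U.T @ X) * sw[:, None]
    # project out covariates, then closed-form per-marker GLS
    Q, _ = np.linalg.qr(Ws)
    yp = ys - Q @ (Q.T @ ys)
    Xp = Xs - Q @ (Q.T @ Xs)
    xtx = np.einsum("ij,ij->j", Xp, Xp)
    xty = Xp.T @ yp
    dof = n - W.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = xty / xtx
        rss = float(yp @ yp) - beta * xty
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / xtx)
        tstat = beta / se
    bad = (xtx <= 1e-12) | ~np.isfinite(tstat)
    tstat = np.where(bad, np.nan, tstat)
    beta = np.where(bad, np.nan, beta)
    se = np.where(bad, np.nan, se)
    pvalue = 2.0 * sps.t.sf(np.abs(tstat), dof)
    pvalue = np.where(bad, np.nan, pvalue)
    return LmmScanResult(markers, beta, se, tstat**2, pvalue, sigma2_g, sigma2_e, cov_desc)


# ---------------------------------------------------------------------------
# Selector estimator used by the pipeline search


class MarkerSelector(BaseEstimator):
    """Select markers by MAF, MultiSURF relevance, or the LMM scan.

    Fitting stores the chosen marker list; ``transform`` subsets a
    GenotypeMatrix to those markers, making test-fold leakage structurally
    impossible.
    """

    def __init__(self, method: str = "maf", k: int = 100, seed: int = 0,
                 batch_size: int = 64, n_pcs: int = 3):
        self.method = method
        self.k = k
        self.seed = seed
        self.batch_size = batch_size
        self.n_pcs = n_pcs

    def fit(self, G: GenotypeMatrix, y=None, groups=None):
        G = G.impute_mode()
        k = min(self.k, G.n_markers)
        stats = allele_stats(G)
        if self.method == "maf":
            self.selected_ = select_by_maf(stats, k)
        elif self.method == "multisurf":
            scores = multisurf_minibatched(
                G.dosages.astype(float), y, "regression", self.batch_size, self.seed
            )
            scores.markers = list(G.markers)
            self.selected_ = select_top_k(scores, min(k, int(np.sum(np.isfinite(scores.scores)))))
        elif self.method == "lmm":
            enc = VanRadenEncoder().fit(G)
            Z = enc.transform(G)
            cov = []
            n_pcs = min(self.n_pcs, max(0, np.linalg.matrix_rank(Z - Z.mean(0)) - 1))
            if n_pcs > 0:
                cov.append(pca_covariates(Z, n_pcs))
            if groups is not None:
                g = np.asarray(groups)
                levels = np.unique(g)[:-1]  # drop last to avoid collinearity
                cov.append((g[:, None] == levels[None, :]).astype(float))
            C = np.column_stack(cov) if cov else None
            K = grm_vanraden(Z, enc.stats_, list(G.samples))
            scan = lmm_association_scan(G, y, C, K)
            n_ok = int(np.sum(np.isfinite(scan.pvalue)))
            self.selected_ = select_top_k(scan, min(k, n_ok))
            self.scan_ = scan
        else:
            raise ValueError(f"unknown selector method {self.method!r}")
        return self

    def transform(self, G: GenotypeMatrix) -> GenotypeMatrix:
        return G.subset_markers(self.selected_)

    def to_json(self) -> str:
        return json.dumps(
            {"method": self.method, "k": self.k, "seed": self.seed,
             "selected": list(self.selected_)}
        )

    @classmethod
    def from_json(cls, s: str) -> "MarkerSelector":
        d = json.loads(s)
        sel = cls(method=d["method"], k=d["k"], seed=d["seed"])
        sel.selected_ = list(d["selected"])
        return sel
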