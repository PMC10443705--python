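"""Gibbs-sampling engine for multi-block Bayesian genomic prediction.

Implements the Bayesian-alphabet whole-genome regressions — Bayesian ridge
(BRR), BayesA, BayesC, Bayesian LASSO (BL) — plus flat-prior fixed effects
and RKHS kernel random effects, over an arbitrary list of effect blocks:

    y = sum_b f_b + e,   e ~ N(0, sigma2_e I)

Marker blocks place their prior on per-column effects; an RKHS block with
kernel K contributes g ~ N(0, sigma2_u K) and is handled by rotating onto
the kernel eigenbasis once, after which its coefficients update like a
ridge block.  With a linear kernel K = Z Z' / c this is exactly GBLUP, and
equals BRR on Z (the RR-BLUP duality) — a key internal consistency check.

Conditionals (single-site updates with residual bookkeeping):

* FIXED:  beta_j | . ~ N(rhs/c, sigma2_e/c), c = x'x (flat prior)
* BRR:    common sigma2_beta ~ scaled-inv-chi2
* BayesA: marker-specific sigma2_j ~ scaled-inv-chi2(df+1, .)
* BayesC: Bernoulli inclusion from marginal likelihoods, common slab
          variance, pi ~ Beta
* BL:     Park & Casella: beta_j ~ N(0, sigma2_e tau2_j), 1/tau2_j
          inverse-Gaussian, lambda^2 ~ Gamma
* sigma2_e ~ scaled-inv-chi2 (with the BL prior quadratic form included)

Scaled-inv-chi2(df, S) is parameterised so a draw is df*S/chi2(df) with
mean S*df/(df-2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import _gibbs

EFFECT_KINDS = ("FIXED", "BRR", "BayesA", "BayesC", "BL", "RKHS")
EIG_FLOOR = 1e-8


@dataclass
class EffectBlock:
    """One fixed or random effect term.

    ``X`` is the (n x q) design matrix for coefficient kinds; ``K`` the
    (n x n) kernel for RKHS.  ``hyper`` overrides default prior
    hyperparameters (df, scale, pi_a/pi_b/pi_fixed for BayesC, fixed_var
    to freeze the block variance).
    """

    name: str
    kind: str
    X: np.ndarray | None = None
    K: np.ndarray | None = None
    hyper: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == "RKHS":
            if self.K is None:
                raise ValueError(f"RKHS block {self.name!r} needs a kernel")
            K = np.asarray(self.K, float)
            if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-8):
                raise ValueError(f"RKHS kernel {self.name!r} must be square symmetric")
            ev = np.linalg.eigvalsh((K + K.T) / 2)
            if ev.min() < -1e-6 * max(ev.max(), 1.0):
                raise ValueError(f"RKHS kernel {self.name!r} is not PSD")
            self.K = K
        else:
            if self.X is None:
                raise ValueError(f"block {self.name!r} needs a design matrix")
            self.X = np.asarray(self.X, float)
            if self.kind == "FIXED":
                if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
                    raise ValueError(f"FIXED design {self.name!r} is rank-deficient")


@dataclass
class MCMCConfig:
    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior means/SDs per block, variance chains and fitted values."""

    blocks: dict
    sigma2_e_mean: float
    sigma2_e_chain: np.ndarray
    fitted_values: np.ndarray
    var_g_chain: np.ndarray
    log_density: np.ndarray
    config: MCMCConfig

    @property
    def h2_chain(self) -> np.ndarray:
        """Per-iteration genomic heritability var(g)/(var(g)+sigma2_e)."""
        return self.var_g_chain / (self.var_g_chain + self.sigma2_e_chain)

    @property
    def h2_mean(self) -> float:
        return float(np.mean(self.h2_chain))

    def effects_frame(self):
        """Per-effect posterior means/SDs as a tidy table (writable as TSV)."""
        import pandas as pd

        rows = []
        for name, info in self.blocks.items():
            for j, (m, s) in enumerate(zip(info["beta_mean"], info["beta_sd"])):
                rows.append({"block": name, "kind": info["kind"], "index": j,
                             "mean": m, "sd": s})
        return pd.DataFrame(rows)

    def variance_components(self) -> dict:
        """Variance-component posterior means plus config, JSON-serialisable."""
        out = {
            "sigma2_e": self.sigma2_e_mean,
            "h2": self.h2_mean,
            "config": {"n_iter": self.config.n_iter, "burn_in": self.config.burn_in,
                       "thin": self.config.thin, "seed": self.config.seed},
            "blocks": {},
        }
        for name, info in self.blocks.items():
            if info["kind"] != "FIXED":
                out["blocks"][name] = {"kind": info["kind"], "var_mean": info["var_mean"]}
        return out

    def save(self, outdir, prefix: str = "posterior", chains: bool = False) -> None:
        """Write effects TSV + variance-component JSON (+ chains TSV)."""
        import json
        from pathlib import Path

        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.effects_frame().to_csv(outdir / f"{prefix}_effects.tsv", sep="\t", index=False)
        (outdir / f"{prefix}_variances.json").write_text(
            json.dumps(self.variance_components(), indent=2)
        )
        if chains:
            cols = {"sigma2_e": self.sigma2_e_chain, "var_g": self.var_g_chain,
                    "log_density": self.log_density}
            for name, info in self.blocks.items():
                if "var_chain" in info:
                    cols[f"var_{name}"] = info["var_chain"]
            pd.DataFrame(cols).to_csv(outdir / f"{prefix}_chains.tsv", sep="\t", index=False)


def default_hyperparams(y, block: EffectBlock, n_random_blocks: int = 1, r2: float = 0.5) -> dict:
    """BGLR-style prior rule: df = 5 everywhere; scales set so each random
    block's prior expected variance contribution is r2/n_random_blocks of
    var(y)."""
    y = np.asarray(y, float)
    vy = float(y.var())
    if vy <= 0:
        raise ValueError("zero-variance target")
    df = 5.0
    target = r2 * vy / max(n_random_blocks, 1)
    h = {"df": df}
    if block.kind == "FIXED":
        return {}
    if block.kind == "RKHS":
        md = float(np.mean(np.diag(block.K)))
        h["scale"] = target / max(md, 1e-12) * (df - 2.0) / df
        return h
    ssx = float(np.sum(block.X.var(axis=0)))
    ssx = max(ssx, 1e-12)
    if block.kind in ("BRR", "BayesA"):
        h["scale"] = target / ssx * (df - 2.0) / df
    elif block.kind == "BayesC":
        h.update(pi_a=5.0, pi_b=45.0)
        pi0 = h["pi_a"] / (h["pi_a"] + h["pi_b"])
        h["scale"] = target / (ssx * pi0) * (df - 2.0) / df
    elif block.kind == "BL":
        sigma2_e0 = (1.0 - r2) * vy
        lam2_0 = 2.0 * sigma2_e0 * ssx / target
        h.update(lambda2_shape=1.1, lambda2_rate=1.1 / lam2_0)
    return h


class _BlockState:
    def __init__(self, block: EffectBlock, y, n_random: int, r2: float):
        self.name = block.name
        self.kind = block.kind
        hyper = default_hyperparams(y, block, n_random, r2)
        hyper.update(block.hyper)
        self.hyper = hyper
        if block.kind == "RKHS":
            S, U = np.linalg.eigh((block.K + block.K.T) / 2)
            keep = S > EIG_FLOOR * max(S.max(), 1e-300)
            self.eigvals = S[keep]
            self.U = U[:, keep]
            X = self.U * np.sqrt(self.eigvals)
        else:
            X = block.X
        self.X = np.ascontiguousarray(X, dtype=np.float64)
        self.Xt = np.ascontiguousarray(X.T, dtype=np.float64)
        self.xtx = np.einsum("ij,ij->j", self.X, self.X)
        q = self.X.shape[1]
        self.beta = np.zeros(q)
        self.fixed_var = hyper.get("fixed_var")
        if self.kind in ("BRR", "RKHS"):
            self.s2 = self.fixed_var if self.fixed_var else hyper["scale"] * hyper["df"] / (hyper["df"] - 2)
        elif self.kind == "BayesA":
            s0 = hyper["scale"] * hyper["df"] / (hyper["df"] - 2)
            self.s2j = np.full(q, s0)
        elif self.kind == "BayesC":
            self.s2 = self.fixed_var or hyper["scale"] * hyper["df"] / (hyper["df"] - 2)
            self.pi = hyper.get("pi_fixed", hyper.get("pi_a", 5.0) / (hyper.get("pi_a", 5.0) + hyper.get("pi_b", 45.0)))
            self.delta = np.zeros(q, dtype=np.int64)
        elif self.kind == "BL":
            self.lam2 = hyper["lambda2_shape"] / hyper["lambda2_rate"]
            self.tau2 = np.full(q, 1.0)


def gibbs_fit(y, blocks: list[EffectBlock], cfg: MCMCConfig | None = None,
              r2: float = 0.5, df_e: float = 5.0,
              fix_sigma2_e: float | None = None) -> PosteriorSummary:
    """Run the Gibbs sampler and return posterior summaries.

    ``fix_sigma2_e`` freezes the residual variance (used by the ridge
    oracle checks); a block can likewise freeze its own variance via
    ``hyper={"fixed_var": v}``.
    """
    cfg = cfg or MCMCConfig()
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values on training rows")
    n = len(y)
    n_random = sum(1 for b in blocks if b.kind != "FIXED")
    states = [_BlockState(b, y, n_random, r2) for b in blocks]

    rng = np.random.default_rng(cfg.seed)
    _gibbs.seed_rng(int(cfg.seed) % (2**31 - 1) + 1)

    vy = float(y.var()) if y.var() > 0 else 1.0
    sigma2_e = fix_sigma2_e if fix_sigma2_e is not None else 0.5 * vy
    scale_e = 0.5 * vy * (df_e - 2.0) / df_e

    e = y.copy()
    n_keep = (cfg.n_iter - cfg.burn_in + cfg.thin - 1) // cfg.thin
    sigma2_e_chain = np.zeros(n_keep)
    var_g_chain = np.zeros(n_keep)
    logdens = np.zeros(n_keep)
    var_chains = {s.name: np.zeros(n_keep) for s in states if s.kind != "FIXED"}
    beta_sum = {s.name: np.zeros_like(s.beta) for s in states}
    beta_sq = {s.name: np.zeros_like(s.beta) for s in states}
    extras = {s.name: {} for s in states}
    for s in states:
        if s.kind == "BayesC":
            extras[s.name]["pi_chain"] = np.zeros(n_keep)
            extras[s.name]["delta_sum"] = np.zeros(len(s.beta))

    kidx = 0
    for t in range(cfg.n_iter):
        for s in states:
            if s.kind == "FIXED":
                _gibbs.update_fixed(s.Xt, s.xtx, s.beta, e, sigma2_e)
            elif s.kind in ("BRR", "RKHS"):
                _gibbs.update_gaussian(s.Xt, s.xtx, s.beta, e, sigma2_e,
                                       np.full(len(s.beta), s.s2))
                if s.fixed_var is None:
                    h = s.hyper
                    q = len(s.beta)
                    s.s2 = (h["df"] * h["scale"] + float(s.beta @ s.beta)) / rng.chisquare(h["df"] + q)
            elif s.kind == "BayesA":
                _gibbs.update_gaussian(s.Xt, s.xtx, s.beta, e, sigma2_e, s.s2j)
                h = s.hyper
                s.s2j = (h["df"] * h["scale"] + s.beta**2) / rng.chisquare(h["df"] + 1.0, size=len(s.beta))
            elif s.kind == "BayesC":
                pi = min(max(s.pi, 1e-12), 1.0)
                logit_pi = np.inf if pi >= 1.0 else math.log(pi / (1.0 - pi))
                n_in = _gibbs.update_bayesc(s.Xt, s.xtx, s.beta, s.delta, e,
                                            sigma2_e, s.s2, logit_pi)
                h = s.hyper
                if s.fixed_var is None:
                    ssb = float(s.beta @ s.beta)
                    s.s2 = (h["df"] * h["scale"] + ssb) / rng.chisquare(h["df"] + max(n_in, 0))
                if "pi_fixed" not in h:
                    q = len(s.beta)
                    s.pi = rng.beta(h["pi_a"] + n_in, h["pi_b"] + q - n_in)
            elif s.kind == "BL":
                _gibbs.update_gaussian(s.Xt, s.xtx, s.beta, e, sigma2_e, sigma2_e * s.tau2)
                h = s.hyper
                b2 = np.maximum(s.beta**2, 1e-12)
                mu = np.sqrt(s.lam2 * sigma2_e / b2)
                mu = np.minimum(mu, 1e8)
                inv_tau2 = rng.wald(mu, s.lam2)
                s.tau2 = 1.0 / np.maximum(inv_tau2, 1e-12)
                q = len(s.beta)
                rate = h["lambda2_rate"] + float(np.sum(s.tau2)) / 2.0
                s.lam2 = rng.gamma(h["lambda2_shape"] + q, 1.0 / rate)

        if fix_sigma2_e is None:
            ss = float(e @ e)
            df_tot = df_e + n
            for s in states:
                if s.kind == "BL":
                    ss += float(np.sum(s.beta**2 / s.tau2))
                    df_tot += len(s.beta)
            sigma2_e = (df_e * scale_e + ss) / rng.chisquare(df_tot)
        if not np.isfinite(sigma2_e) or sigma2_e <= 0 or not np.isfinite(e).all():
            raise FloatingPointError(
                f"divergent sampler state at iteration {t}: sigma2_e={sigma2_e}"
            )

        if t >= cfg.burn_in and (t - cfg.burn_in) % cfg.thin == 0:
            fit = y - e
            fixed_fit = np.zeros(n)
            for s in states:
                if s.kind == "FIXED":
                    fixed_fit += s.X @ s.beta
            g = fit - fixed_fit
            var_g_chain[kidx] = g.var()
            sigma2_e_chain[kidx] = sigma2_e
            logdens[kidx] = -0.5 * (n * np.log(2 * np.pi * sigma2_e) + float(e @ e) / sigma2_e)
            for s in states:
                beta_sum[s.name] += s.beta
                beta_sq[s.name] += s.beta**2
                if s.kind in ("BRR", "RKHS", "BayesC"):
                    var_chains[s.name][kidx] = s.s2
                elif s.kind == "BayesA":
                    var_chains[s.name][kidx] = s.s2j.mean()
                elif s.kind == "BL":
                    var_chains[s.name][kidx] = sigma2_e * s.tau2.mean()
                if s.kind == "BayesC":
                    extras[s.name]["pi_chain"][kidx] = s.pi
                    extras[s.name]["delta_sum"] += s.delta
            kidx += 1

    out_blocks = {}
    for s in states:
        bm = beta_sum[s.name] / n_keep
        bsd = np.sqrt(np.maximum(beta_sq[s.name] / n_keep - bm**2, 0.0))
        info = {
            "kind": s.kind,
            "beta_mean": bm,
            "beta_sd": bsd,
        }
        if s.kind != "FIXED":
            info["var_chain"] = var_chains[s.name]
            info["var_mean"] = float(var_chains[s.name].mean())
        if s.kind == "RKHS":
            info["U"] = s.U
            info["eigvals"] = s.eigvals
            info["g_mean"] = s.U @ (np.sqrt(s.eigvals) * bm)
        if s.kind == "BayesC":
            info["pi_mean"] = float(extras[s.name]["pi_chain"].mean())
            info["inclusion_prob"] = extras[s.name]["delta_sum"] / n_keep
        out_blocks[s.name] = info

    fitted = np.zeros(n)
    for s in states:
        fitted += s.X @ (beta_sum[s.name] / n_keep)
    return PosteriorSummary(
        out_blocks, float(sigma2_e_chain.mean()), sigma2_e_chain, fitted,
        var_g_chain, logdens, cfg,
    )


def predict(summary: PosteriorSummary, new_blocks: dict) -> np.ndarray:
    """Posterior-mean prediction for new samples.

    ``new_blocks`` maps block name -> design matrix for coefficient blocks,
    or the cross-kernel K(new, train) for RKHS blocks (for which the
    prediction is K_new,train K_train^+ g_train via the eigen floor
    pseudo-inverse).
    """
    unknown = set(new_blocks) - set(summary.blocks)
    if unknown:
        raise ValueError(f"blocks not present at fit time: {sorted(unknown)}")
    yhat = None
    for name, info in summary.blocks.items():
        if name not in new_blocks:
            raise ValueError(f"missing new data for block {name!r}")
        M = np.asarray(new_blocks[name], float)
        if info["kind"] == "RKHS":
            # K+ g = U D^-1 U' (U sqrt(D) beta) = U beta/sqrt(D)
            contrib = M @ (info["U"] @ (info["beta_mean"] / np.sqrt(info["eigvals"])))
        else:
            if M.shape[1] != len(info["beta_mean"]):
                raise ValueError(f"block {name!r}: {M.shape[1]} columns vs "
                                 f"{len(info['beta_mean'])} fitted effects")
            contrib = M @ info["beta_mean"]
        yhat = contrib if yhat is None else yhat + contrib
    return yhat


class BayesianAlphabetRegressor(BaseEstimator, RegressorMixin):
    """scikit-learn front-end: one marker block plus an intercept.

    prior: 'brr' | 'bayesa' | 'bayesc' | 'bl'.  Heritability estimate
    (posterior mean of var(g)/(var(g)+sigma2_e)) is exposed as ``h2_``.
    """

    _PRIOR = {"brr": "BRR", "bayesa": "BayesA", "bayesc": "BayesC", "bl": "BL"}

    def __init__(self, prior: str = "brr", n_iter: int = 3000, burn_in: int = 500,
                 thin: int = 5, seed: int = 0, r2: float = 0.5):
        self.prior = prior
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.r2 = r2

    def fit(self, X, y):
        X = np.asarray(X, float)
        n = X.shape[0]
        blocks = [
            EffectBlock("intercept", "FIXED", X=np.ones((n, 1))),
            EffectBlock("markers", self._PRIOR[self.prior.lower()], X=X),
        ]
        cfg = MCMCConfig(self.n_iter, self.burn_in, self.thin, self.seed)
        self.summary_ = gibbs_fit(np.asarray(y, float), blocks, cfg, r2=self.r2)
        self.h2_ = self.summary_.h2_mean
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        return predict(
            self.summary_,
            {"intercept": np.ones((X.shape[0], 1)), "markers": X},
        )
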