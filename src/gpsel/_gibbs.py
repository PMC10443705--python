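"""Numba-compiled single-site Gibbs updates with residual bookkeeping.

Each updater sweeps the coefficients of one effect block, drawing from the
full conditional and patching the shared residual vector in place.  Design
matrices are passed transposed (q x n, C-ordered) so each coefficient's
column is contiguous.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def update_fixed(Xt, xtx, beta, e, sigma2e):
    """Flat-prior (fixed-effect) coefficients: beta_j | . ~ N(rhs/c, s2e/c)."""
    q, n = Xt.shape
    for j in range(q):
        if xtx[j] <= 0.0:
            continue
        rhs = 0.0
        for i in range(n):
            rhs += Xt[j, i] * e[i]
        rhs += xtx[j] * beta[j]
        c = xtx[j]
        newb = rhs / c + np.sqrt(sigma2e / c) * np.random.standard_normal()
        diff = beta[j] - newb
        for i in range(n):
            e[i] += Xt[j, i] * diff
        beta[j] = newb


@njit(cache=True)
def update_gaussian(Xt, xtx, beta, e, sigma2e, s2b):
    """Gaussian-prior coefficients with per-coefficient prior variance s2b.

    Covers BRR (common variance), BayesA (marker-specific), Bayesian LASSO
    (s2b_j = sigma2e * tau2_j) and eigen-rotated RKHS blocks.
    """
    q, n = Xt.shape
    for j in range(q):
        if xtx[j] <= 0.0 or s2b[j] <= 0.0:
            if beta[j] != 0.0:
                for i in range(n):
                    e[i] += Xt[j, i] * beta[j]
                beta[j] = 0.0
            continue
        rhs = 0.0
        for i in range(n):
            rhs += Xt[j, i] * e[i]
        rhs += xtx[j] * beta[j]
        c = xtx[j] + sigma2e / s2b[j]
        newb = rhs / c + np.sqrt(sigma2e / c) * np.random.standard_normal()
        diff = beta[j] - newb
        for i in range(n):
            e[i] += Xt[j, i] * diff
        beta[j] = newb


@njit(cache=True)
def update_bayesc(Xt, xtx, beta, delta, e, sigma2e, s2b, logit_pi):
    """Spike-and-slab coefficients: Bernoulli inclusion from the marginal
    likelihood ratio, then a Gaussian slab draw for included markers.

    Returns the number of included markers.
    """
    q, n = Xt.shape
    n_in = 0
    for j in range(q):
        if xtx[j] <= 0.0:
            delta[j] = 0
            continue
        r = 0.0
        for i in range(n):
            r += Xt[j, i] * e[i]
        r += xtx[j] * beta[j]
        v0 = xtx[j] * sigma2e
        v1 = v0 + xtx[j] * xtx[j] * s2b
        logodds = logit_pi + 0.5 * (np.log(v0 / v1) + r * r * (1.0 / v0 - 1.0 / v1))
        if logodds > 35.0:
            p = 1.0
        elif logodds < -35.0:
            p = 0.0
        else:
            p = 1.0 / (1.0 + np.exp(-logodds))
        if np.random.random() < p:
            c = xtx[j] + sigma2e / s2b
            newb = r / c + np.sqrt(sigma2e / c) * np.random.standard_normal()
            delta[j] = 1
            n_in += 1
        else:
            newb = 0.0
            delta[j] = 0
        diff = beta[j] - newb
        if diff != 0.0:
            for i in range(n):
                e[i] += Xt[j, i] * diff
        beta[j] = newb
    return n_in


@njit(cache=True)
def sample_scaled_inv_chi2(df, scale):
    """Draw from scaled-inv-chi2(df, scale): df*scale / chi2(df)."""
    return df * scale / np.random.chisquare(df)
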