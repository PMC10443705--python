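"""Joint preprocessing x model search by cross-validated trial evaluation.

Each trial is a :class:`~gpsel.pipeline.TrialConfig` sampled from the
joint space (feature blocks, selector, encoder, kernels, scalers, target
transform, model hyperparameters).  Trials are scored by k-fold
cross-validation — every transform and selector fitted on training folds
only — with Pearson correlation on the original target scale as the
default metric.  Two built-in samplers are provided: pure random and a
TPE-style sampler (independent 1-D Parzen estimators over a good/bad split
of past trials, candidates scored by density ratio), so the package needs
no external optimisation dependency.

``compare_families`` runs the search once per model family on identical
folds and tabulates the best cross-validated score per family per dataset
— the harness for the LMM-vs-ML comparison on the two simulated designs.
"""

from __future__ import annotations

import time
import warnings
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import models
from .pipeline import Dataset, GenomicPipeline, TrialConfig


def cv_folds(n_or_samples, k: int, grouping=None, seed: int = 0):
    """Seeded k-fold partition; grouped mode keeps each group intact.

    Returns a list of (train_idx, val_idx) pairs.  Grouped folds are built
    by shuffling the groups and assigning them to folds greedily by
    descending size (balancing fold sizes); requires >= k groups.
    """
    n = n_or_samples if isinstance(n_or_samples, (int, np.integer)) else len(n_or_samples)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    if grouping is None:
        perm = rng.permutation(n)
        return [
            (np.sort(np.setdiff1d(perm, chunk)), np.sort(chunk))
            for chunk in np.array_split(perm, k)
        ]
    g = np.asarray(grouping)
    levels = np.unique(g)
    if len(levels) < k:
        raise ValueError(f"{len(levels)} groups < k={k} folds")
    sizes = {lv: int((g == lv).sum()) for lv in levels}
    shuffled = list(rng.permutation(levels))
    shuffled.sort(key=lambda lv: -sizes[lv])
    fold_of = {}
    load = [0] * k
    for lv in shuffled:
        f = int(np.argmin(load))
        fold_of[lv] = f
        load[f] += sizes[lv]
    folds = []
    assign = np.array([fold_of[x] for x in g])
    for f in range(k):
        val = np.flatnonzero(assign == f)
        folds.append((np.flatnonzero(assign != f), val))
    return folds


@dataclass
class TrialResult:
    config: TrialConfig
    fold_scores: list[float]
    mean_score: float
    wall_time: float
    error: str | None = None


def _score(y_true, y_pred, metric: str) -> float:
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if metric == "accuracy":
        return float(np.mean(y_true == y_pred))
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        warnings.warn("degenerate predictions: correlation undefined, scoring 0", stacklevel=2)
        return 0.0
    if metric == "spearman":
        return float(sps.spearmanr(y_true, y_pred).statistic)
    return float(sps.pearsonr(y_true, y_pred).statistic)


def evaluate_trial(config: TrialConfig, data: Dataset, folds, metric: str = "pearson") -> TrialResult:
    """Cross-validate one config: fit on training rows only, score held-out."""
    t0 = time.time()
    scores = []
    for train_idx, val_idx in folds:
        pipe = GenomicPipeline(config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pipe.fit(data.subset(train_idx))
            pred = pipe.predict(data.subset(val_idx))
        scores.append(_score(data.y[val_idx], pred, metric))
    return TrialResult(config, scores, float(np.mean(scores)), time.time() - t0)


# ---------------------------------------------------------------------------
# Joint search space


_SELECTOR_KS = (50, 100, 200, 500)


def sample_config(family: str, data: Dataset, rng: np.random.Generator,
                  task: str = "regression") -> TrialConfig:
    """Draw one point from the joint preprocessing x model space."""
    m = data.G.n_markers
    bayes = family in models.BAYES_FAMILIES
    cfg = TrialConfig(family=family, task=task, seed=int(rng.integers(2**31 - 1)))
    cfg.selector_method = str(rng.choice(["none", "maf", "multisurf", "lmm"]))
    cfg.selector_k = int(min(m, rng.choice(_SELECTOR_KS)))
    if bayes:
        cfg.encoder = str(rng.choice(["vanraden", "noia", "noia_ad"]))
        if cfg.encoder == "noia_ad" and rng.random() < 0.5:
            cfg.use_epistasis = True
            cfg.selector_k = min(cfg.selector_k, 200)  # kernels on reduced marker set
            if cfg.selector_method == "none":
                cfg.selector_method = "maf"
    else:
        cfg.encoder = str(rng.choice(["vanraden", "onehot", "noia", "pca"]))
        cfg.pca_k = int(rng.integers(3, 21))
    if family != "knn" and rng.random() < 0.3:
        cfg.distance_block = True
        cfg.distance_metric = str(rng.choice(["vanraden", "manhattan", "euclidean"]))
    if family not in models.TREE_FAMILIES and family != "svr" and rng.random() < 0.3:
        cfg.nonlinear_block = True
        cfg.kernel_kind = str(rng.choice(["rbf", "laplacian", "poly2"]))
    if not bayes and family not in models.TREE_FAMILIES and family != "svr" and family != "knn":
        cfg.interactions_block = bool(rng.random() < 0.15)
        cfg.interaction_kernel = str(rng.choice(["rbf", "laplacian", "poly2"]))
    if family in models.TREE_FAMILIES:
        cfg.target_transform = "identity"
    else:
        cfg.target_transform = str(rng.choice(["identity", "zscore", "quantile_normal"]))
    if not bayes:
        cfg.model_params = models.default_space(family, task).sample(rng)
    # the marker block itself may be dropped in favour of the other sets
    if (cfg.distance_block or cfg.nonlinear_block) and rng.random() < 0.15:
        cfg.marker_block = False
    if not cfg.marker_block and not cfg.distance_block and not cfg.nonlinear_block:
        cfg.marker_block = True
    return cfg


def _flatten(cfg: TrialConfig) -> dict:
    d = asdict(cfg)
    params = d.pop("model_params")
    d.pop("seed")
    for k, v in params.items():
        d[f"mp:{k}"] = v
    return d


_LOG_PARAMS = {"mp:C", "mp:gamma", "mp:epsilon", "mp:alpha", "mp:learning_rate", "mp:reg_lambda"}


def _parzen_logpdf(values: np.ndarray, x: float) -> float:
    sd = np.std(values)
    bw = max(1.06 * sd * len(values) ** -0.2, 1e-3 * max(abs(x), 1.0))
    return float(np.log(np.mean(sps.norm.pdf(x, loc=values, scale=bw)) + 1e-300))


def _tpe_score(cand: dict, good: list[dict], bad: list[dict]) -> float:
    total = 0.0
    for key, val in cand.items():
        gv = [d[key] for d in good if key in d]
        bv = [d[key] for d in bad if key in d]
        if len(gv) < 2 or len(bv) < 2:
            continue
        if isinstance(val, (bool, str)):
            pg = (sum(1 for v in gv if v == val) + 0.5) / (len(gv) + 1)
            pb = (sum(1 for v in bv if v == val) + 0.5) / (len(bv) + 1)
            total += np.log(pg) - np.log(pb)
        elif isinstance(val, (int, float, np.integer, np.floating)):
            x, ga, ba = float(val), np.asarray(gv, float), np.asarray(bv, float)
            if key in _LOG_PARAMS:
                x, ga, ba = np.log(x), np.log(ga), np.log(ba)
            total += _parzen_logpdf(ga, x) - _parzen_logpdf(ba, x)
    return total


def _suggest_tpe(family, data, rng, task, history: list[TrialResult], n_candidates=20):
    ok = [t for t in history if t.error is None]
    if len(ok) < 8:
        return sample_config(family, data, rng, task)
    order = sorted(ok, key=lambda t: -t.mean_score)
    n_good = max(2, len(order) // 4)
    good = [_flatten(t.config) for t in order[:n_good]]
    bad = [_flatten(t.config) for t in order[n_good:]]
    cands = [sample_config(family, data, rng, task) for _ in range(n_candidates)]
    scores = [_tpe_score(_flatten(c), good, bad) for c in cands]
    return cands[int(np.argmax(scores))]


def optimise(
    data: Dataset,
    family: str,
    n_trials: int = 25,
    sampler: str = "tpe",
    seed: int = 0,
    task: str = "regression",
    folds=None,
    metric: str = "pearson",
    mcmc_iter: int | None = None,
):
    """Sequential search over the joint space for one model family.

    Returns (best TrialResult, all TrialResults, pipeline refit on all data
    with the best config).  Ties go to the earliest trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if sampler not in ("random", "tpe"):
        raise ValueError("sampler must be 'random' or 'tpe'")
    if folds is None:
        folds = cv_folds(data.n, 5, seed=seed)
    rng = np.random.default_rng(seed)
    history: list[TrialResult] = []
    for _ in range(n_trials):
        if sampler == "tpe":
            cfg = _suggest_tpe(family, data, rng, task, history)
        else:
            cfg = sample_config(family, data, rng, task)
        if mcmc_iter is not None:
            cfg.mcmc_iter = mcmc_iter
            cfg.mcmc_burn_in = max(mcmc_iter // 4, 50)
        try:
            history.append(evaluate_trial(cfg, data, folds, metric))
        except Exception as exc:  # a failed trial is recorded, not fatal
            history.append(TrialResult(cfg, [], -np.inf, 0.0, error=f"{type(exc).__name__}: {exc}"))
    ok = [t for t in history if t.error is None]
    if not ok:
        raise RuntimeError(
            "all trials failed: " + "; ".join(t.error for t in history[:5])
        )
    best = max(ok, key=lambda t: t.mean_score)  # max is stable: earliest wins ties
    final = GenomicPipeline(best.config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(data)
    return best, history, final


def compare_families(
    datasets: dict[str, Dataset],
    families: list[str],
    n_trials_each: int = 25,
    seed: int = 0,
    k: int = 5,
    sampler: str = "tpe",
    grouped: dict[str, bool] | None = None,
    metric: str = "pearson",
    mcmc_iter: int | None = None,
) -> pd.DataFrame:
    """Optimise every family on every dataset over identical folds.

    Returns one row per family x dataset with the best cross-validated
    score — the comparison report for the two simulated designs.  Failures
    are recorded per row; partial results are retained.
    """
    if len(families) < 2:
        raise ValueError("need at least two families to compare")
    grouped = grouped or {}
    rows = []
    for dname, data in datasets.items():
        use_groups = grouped.get(dname, False) and data.groups is not None
        folds = cv_folds(data.n, k, grouping=data.groups if use_groups else None, seed=seed)
        for family in families:
            fseed = (seed * 10007 + zlib.crc32(family.encode()) % 9973
                     + zlib.crc32(dname.encode()) % 997) % (2**31 - 1)
            try:
                best, history, _ = optimise(
                    data, family, n_trials_each, sampler=sampler, seed=fseed,
                    folds=folds, metric=metric, mcmc_iter=mcmc_iter,
                )
                rows.append(
                    {
                        "dataset": dname,
                        "family": family,
                        "score": best.mean_score,
                        "n_trials": len(history),
                        "n_failed": sum(1 for t in history if t.error is not None),
                        "best_config": best.config.to_json(),
                        "error": None,
                    }
                )
            except Exception as exc:
                rows.append(
                    {
                        "dataset": dname, "family": family, "score": np.nan,
                        "n_trials": n_trials_each, "n_failed": n_trials_each,
                        "best_config": None, "error": f"{type(exc).__name__}: {exc}",
                    }
                )
    return pd.DataFrame(rows)


def lmm_ml_gap(comparison: pd.DataFrame) -> pd.DataFrame:
    """Per-dataset mean score of Bayesian LMM families minus ML families."""
    df = comparison.dropna(subset=["score"]).copy()
    df["class"] = np.where(df["family"].isin(models.BAYES_FAMILIES), "lmm", "ml")
    wide = df.groupby(["dataset", "class"])["score"].mean().unstack()
    wide["lmm_minus_ml"] = wide.get("lmm") - wide.get("ml")
    return wide
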