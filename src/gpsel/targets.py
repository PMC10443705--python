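"""Target transforms, the cumulative-distribution ordinal classifier, and
pairwise ranking utilities.

Regression targets may be z-scored or quantile-mapped to a standard normal
or uniform [0, 1] distribution, with exact inverse transforms so model
predictions are reported in original units.  Ranking tasks can instead use
an ordinal scheme (one binary classifier per threshold, score = sum of
exceedance probabilities) or a pairwise scheme in which a scorer is trained
to classify whether one sample outranks another under a logistic
(RankNet-style) loss.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.preprocessing import QuantileTransformer

TARGET_KINDS = ("identity", "zscore", "quantile_normal", "quantile_uniform")


class TargetTransform(BaseEstimator):
    """Invertible 1-D target transform with frozen fit statistics.

    kind:
        identity            y unchanged
        zscore              (y - mean) / sd  (population sd)
        quantile_normal     rank-map to N(0, 1)
        quantile_uniform    rank-map to U(0, 1)
    """

    def __init__(self, kind: str = "identity"):
        self.kind = kind

    def fit(self, y):
        y = np.asarray(y, dtype=float).ravel()
        if self.kind not in TARGET_KINDS:
            raise ValueError(f"unknown target transform {self.kind!r}")
        if self.kind != "identity":
            if np.ptp(y) == 0:
                raise ValueError(f"constant target cannot be {self.kind}-transformed")
        if self.kind.startswith("quantile") and len(np.unique(y)) < 3:
            raise ValueError("quantile transforms need >= 3 distinct values")
        if self.kind == "zscore":
            self.mean_ = float(y.mean())
            self.sd_ = float(y.std(ddof=1)) if len(y) > 1 else 1.0
        elif self.kind.startswith("quantile"):
            dist = "normal" if self.kind.endswith("normal") else "uniform"
            self.qt_ = QuantileTransformer(
                n_quantiles=min(1000, len(y)), output_distribution=dist,
                subsample=1_000_000,
            ).fit(y.reshape(-1, 1))
        return self

    def transform(self, y):
        y = np.asarray(y, dtype=float).ravel()
        if self.kind == "identity":
            return y.copy()
        if self.kind == "zscore":
            return (y - self.mean_) / self.sd_
        return self.qt_.transform(y.reshape(-1, 1)).ravel()

    def fit_transform(self, y):
        return self.fit(y).transform(y)

    def inverse_transform(self, t):
        t = np.asarray(t, dtype=float).ravel()
        if self.kind == "identity":
            return t.copy()
        if self.kind == "zscore":
            return t * self.sd_ + self.mean_
        return self.qt_.inverse_transform(t.reshape(-1, 1)).ravel()

    def to_json(self) -> str:
        d = {"kind": self.kind}
        if self.kind == "zscore":
            d.update(mean=self.mean_, sd=self.sd_)
        elif self.kind.startswith("quantile"):
            d.update(
                quantiles=self.qt_.quantiles_.ravel().tolist(),
                references=self.qt_.references_.tolist(),
            )
        return json.dumps(d)


def fit_transform_target(y, kind: str):
    """Transform y and return (transformed, fitted TargetTransform)."""
    tt = TargetTransform(kind).fit(y)
    return tt.transform(y), tt


# ---------------------------------------------------------------------------
# Ordinal (cumulative-distribution) classification


class OrdinalClassifier(BaseEstimator):
    """Rank scorer built from cumulative binary classifiers.

    Thresholds are placed at evenly spaced empirical quantiles of the
    training target; one classifier per threshold t_k learns 1{y > t_k},
    and the predicted score is the sum of exceedance probabilities, a
    monotone estimate of each sample's rank.  Thresholds whose labels are
    single-class carry no information and are dropped with a warning.
    """

    def __init__(self, base_classifier=None, n_thresholds: int | None = None):
        self.base_classifier = base_classifier
        self.n_thresholds = n_thresholds

    def fit(self, X, y):
        from sklearn.linear_model import LogisticRegression

        y = np.asarray(y, dtype=float).ravel()
        n_distinct = len(np.unique(y))
        K = self.n_thresholds or min(10, n_distinct - 1)
        if K < 1:
            raise ValueError("need at least one threshold (>= 2 distinct y)")
        base = self.base_classifier or LogisticRegression(max_iter=1000)
        qs = np.linspace(0, 1, K + 2)[1:-1]
        thresholds = np.quantile(y, qs)
        self.thresholds_ = []
        self.classifiers_ = []
        dropped = 0
        for t in thresholds:
            lab = (y > t).astype(int)
            if len(np.unique(lab)) < 2:
                dropped += 1
                continue
            clf = clone(base)
            clf.fit(X, lab)
            self.thresholds_.append(float(t))
            self.classifiers_.append(clf)
        if dropped:
            warnings.warn(f"dropped {dropped} single-class threshold(s)", stacklevel=2)
        if not self.classifiers_:
            raise ValueError("no usable thresholds")
        return self

    def predict(self, X):
        """Rank score in [0, K]: sum of P(y > t_k | x) over thresholds."""
        score = np.zeros(np.asarray(X).shape[0])
        for clf in self.classifiers_:
            score += clf.predict_proba(X)[:, 1]
        return score


# ---------------------------------------------------------------------------
# Pairwise (RankNet-style) ranking


@dataclass
class PairDataset:
    """Ordered index pairs (i < j) with label 1 if y_i > y_j; ties dropped."""

    pairs: np.ndarray  # (P, 2) int
    labels: np.ndarray  # (P,) in {0, 1}
    n_ties_dropped: int = 0


def make_pairs(y, max_pairs: int | None = None, seed: int = 0) -> PairDataset:
    """All distinct-value index pairs, optionally subsampled."""
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 2:
        raise ValueError("need at least two samples")
    ii, jj = np.triu_indices(n, k=1)
    tie = y[ii] == y[jj]
    if tie.all():
        raise ValueError("all target values tied: no ranking signal")
    pairs = np.column_stack([ii[~tie], jj[~tie]])
    labels = (y[pairs[:, 0]] > y[pairs[:, 1]]).astype(int)
    n_ties = int(tie.sum())
    if max_pairs is not None and len(pairs) > max_pairs:
        idx = np.random.default_rng(seed).choice(len(pairs), max_pairs, replace=False)
        idx.sort()
        pairs, labels = pairs[idx], labels[idx]
    return PairDataset(pairs, labels, n_ties)


def ranknet_loss(s_i, s_j, label):
    """Logistic pairwise loss and its gradient w.r.t. the score difference.

    P(i beats j) = sigmoid(s_i - s_j); loss is binary cross-entropy and the
    gradient d loss / d (s_i - s_j) = P - label.  Stabilised via log1p/exp
    so extreme score gaps stay finite.
    """
    d = np.asarray(s_i, dtype=float) - np.asarray(s_j, dtype=float)
    label = np.asarray(label, dtype=float)
    # log(1 + exp(-d)) computed stably
    loss_pos = np.where(d > 0, np.log1p(np.exp(-np.abs(d))), np.abs(d) + np.log1p(np.exp(-np.abs(d))))
    loss = label * loss_pos + (1.0 - label) * (d + loss_pos)
    P = 1.0 / (1.0 + np.exp(-np.clip(d, -500, 500)))
    grad = P - label
    return loss, grad


class PairwiseRanker(BaseEstimator):
    """Gradient-boosted pairwise ranker trained on the logistic pair loss.

    The canonical consumer of the pairwise scheme: an XGBoost scorer with
    objective ``rank:pairwise``.  ``fit`` consumes the raw target; pairs
    are formed internally by the booster.  Predictions are rank scores
    (arbitrary scale, monotone in predicted rank).
    """

    def __init__(self, seed: int = 0, **xgb_params):
        self.seed = seed
        self.xgb_params = xgb_params

    def fit(self, X, y):
        import xgboost as xgb

        params = dict(
            objective="rank:pairwise",
            n_estimators=200,
            max_depth=4,
            learning_rate=0.1,
            random_state=self.seed,
            n_jobs=1,
        )
        params.update(self.xgb_params)
        self.model_ = xgb.XGBRanker(**params)
        self.model_.fit(X, np.argsort(np.argsort(y)), qid=np.zeros(len(y), dtype=int))
        return self

    def predict(self, X):
        return self.model_.predict(X)
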