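"""Model zoo: a uniform contract over the non-Bayesian model families.

Each family exposes a hyperparameter-space descriptor (finite bounds,
types) consumed by the search, and ``build`` turns a sampled point into a
seeded estimator honouring fit/predict.  Underlying implementations are
library-backed (scikit-learn, XGBoost); the contract, bounds and family
constraints are owned here.

NGB ("natural gradient boosting") is an experimental internal family:
gradient boosting of a Gaussian likelihood in which each stage fits the
natural gradient of the negative log-likelihood (for the mean parameter
this is the raw residual rescaled by the current variance estimate's
Fisher information, i.e. unscaled by sigma^-2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.linear_model import Lars, LassoLars, SGDRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

FAMILIES = (
    "knn", "random_forest", "extra_trees", "svr", "sgd_linear",
    "lars", "lasso_lars", "xgb", "ngb",
)
TREE_FAMILIES = {"random_forest", "extra_trees", "xgb", "ngb"}
BAYES_FAMILIES = ("brr", "bayesa", "bayesc", "bl")


@dataclass
class ParamSpec:
    name: str
    kind: str  # categorical | int | float | log-float
    low: float | None = None
    high: float | None = None
    choices: list | None = None

    def validate(self, value):
        if self.kind == "categorical":
            if value not in self.choices:
                raise ValueError(f"{self.name}={value!r} not in {self.choices}")
        else:
            if not (self.low <= value <= self.high):
                raise ValueError(f"{self.name}={value} outside [{self.low}, {self.high}]")
            if self.kind == "int" and int(value) != value:
                raise ValueError(f"{self.name} must be an integer")

    def sample(self, rng: np.random.Generator):
        if self.kind == "categorical":
            return self.choices[rng.integers(len(self.choices))]
        if self.kind == "int":
            return int(rng.integers(int(self.low), int(self.high) + 1))
        if self.kind == "log-float":
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        return float(rng.uniform(self.low, self.high))


@dataclass
class EstimatorSpec:
    family: str
    params: list[ParamSpec]
    tasks: tuple = ("regression", "ranking")

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.family,
                "tasks": list(self.tasks),
                "params": [vars(p) for p in self.params],
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "EstimatorSpec":
        d = json.loads(s)
        return cls(d["family"], [ParamSpec(**p) for p in d["params"]], tuple(d["tasks"]))

    def sample(self, rng: np.random.Generator) -> dict:
        return {p.name: p.sample(rng) for p in self.params}


_SPACES: dict[str, list[ParamSpec]] = {
    "knn": [
        ParamSpec("n_neighbors", "int", 1, 50),
        ParamSpec("weights", "categorical", choices=["uniform", "distance"]),
    ],
    "random_forest": [
        ParamSpec("n_estimators", "int", 100, 1000),
        ParamSpec("max_depth", "int", 2, 20),
        ParamSpec("max_features", "float", 0.1, 1.0),
    ],
    "extra_trees": [
        ParamSpec("n_estimators", "int", 100, 1000),
        ParamSpec("max_depth", "int", 2, 20),
        ParamSpec("max_features", "float", 0.1, 1.0),
    ],
    "svr": [
        ParamSpec("C", "log-float", 1e-3, 1e3),
        ParamSpec("gamma", "log-float", 1e-5, 1.0),
        ParamSpec("epsilon", "log-float", 1e-3, 1.0),
    ],
    "sgd_linear": [
        ParamSpec("penalty", "categorical", choices=["l1", "l2", "elasticnet"]),
        ParamSpec("alpha", "log-float", 1e-8, 1.0),
        ParamSpec("l1_ratio", "float", 0.0, 1.0),
    ],
    "lars": [ParamSpec("n_nonzero_coefs", "int", 1, 200)],
    "lasso_lars": [ParamSpec("alpha", "log-float", 1e-6, 1.0)],
    "xgb": [
        ParamSpec("learning_rate", "log-float", 1e-3, 0.5),
        ParamSpec("max_depth", "int", 2, 10),
        ParamSpec("subsample", "float", 0.5, 1.0),
        ParamSpec("n_estimators", "int", 50, 500),
        ParamSpec("reg_lambda", "log-float", 1e-3, 10.0),
    ],
    "ngb": [
        ParamSpec("n_estimators", "int", 50, 300),
        ParamSpec("learning_rate", "log-float", 0.01, 0.5),
        ParamSpec("max_depth", "int", 2, 4),
    ],
}
# LARS path solvers have no native ranking analogue; exclude from ranking.
_TASKS = {f: ("regression",) if f in ("lars", "lasso_lars") else ("regression", "ranking")
          for f in FAMILIES}


def default_space(family: str, task: str = "regression") -> EstimatorSpec:
    """The documented default hyperparameter space for one family."""
    if family not in _SPACES:
        raise ValueError(f"unknown family {family!r} (choose from {FAMILIES})")
    if task not in _TASKS[family]:
        raise ValueError(f"family {family!r} does not support task {task!r}")
    return EstimatorSpec(family, list(_SPACES[family]), _TASKS[family])


class NGBRegressor(BaseEstimator, RegressorMixin):
    """Gaussian-likelihood natural-gradient boosting (experimental).

    Boosts the mean and log-scale of a Normal predictive distribution with
    shallow regression trees; each stage fits the natural gradient
    (Fisher-preconditioned) of the negative log-likelihood, which for the
    Gaussian is (mu - y) for the mean and (1 - z^2)/2 for the log-scale.
    Prediction returns the mean.
    """

    def __init__(self, n_estimators: int = 200, learning_rate: float = 0.1,
                 max_depth: int = 3, random_state: int = 0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        self.mu0_ = float(y.mean())
        self.logs0_ = float(np.log(max(y.std(), 1e-8)))
        mu = np.full(len(y), self.mu0_)
        logs = np.full(len(y), self.logs0_)
        self.trees_mu_ = []
        self.trees_logs_ = []
        rs = np.random.RandomState(self.random_state)
        for _ in range(self.n_estimators):
            z = (y - mu) / np.exp(logs)
            ng_mu = mu - y                   # natural gradient wrt mean
            ng_logs = (1.0 - z**2) / 2.0     # natural gradient wrt log-scale
            t_mu = DecisionTreeRegressor(
                max_depth=self.max_depth, random_state=rs.randint(2**31 - 1)
            ).fit(X, ng_mu)
            t_ls = DecisionTreeRegressor(
                max_depth=self.max_depth, random_state=rs.randint(2**31 - 1)
            ).fit(X, ng_logs)
            mu -= self.learning_rate * t_mu.predict(X)
            logs -= self.learning_rate * t_ls.predict(X)
            logs = np.clip(logs, self.logs0_ - 10, self.logs0_ + 10)
            self.trees_mu_.append(t_mu)
            self.trees_logs_.append(t_ls)
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        mu = np.full(X.shape[0], self.mu0_)
        for t in self.trees_mu_:
            mu -= self.learning_rate * t.predict(X)
        return mu


def build(family: str, params: dict | None = None, seed: int = 0,
          task: str = "regression"):
    """Instantiate a seeded estimator for one family at one parameter point.

    Parameters are validated against the family's space descriptor.
    Ranking tasks reuse the regression estimators; pairing/ordinal target
    handling happens upstream (see the targets module).
    """
    spec = default_space(family, task)
    params = dict(params or {})
    known = {p.name: p for p in spec.params}
    for name, value in params.items():
        if name not in known:
            raise ValueError(f"unknown parameter {name!r} for family {family!r}")
        known[name].validate(value)

    if family == "knn":
        return KNeighborsRegressor(
            n_neighbors=params.get("n_neighbors", 5),
            weights=params.get("weights", "uniform"),
        )
    if family in ("random_forest", "extra_trees"):
        cls = RandomForestRegressor if family == "random_forest" else ExtraTreesRegressor
        return cls(
            n_estimators=params.get("n_estimators", 300),
            max_depth=params.get("max_depth", None),
            max_features=params.get("max_features", 1.0),
            random_state=seed,
            n_jobs=1,
        )
    if family == "svr":
        return SVR(
            C=params.get("C", 1.0),
            gamma=params.get("gamma", "scale"),
            epsilon=params.get("epsilon", 0.1),
        )
    if family == "sgd_linear":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        # SGD is scale-sensitive; standardise internally so the estimator
        # behaves sanely on raw dosages too
        return make_pipeline(StandardScaler(), SGDRegressor(
            penalty=params.get("penalty", "l2"),
            alpha=params.get("alpha", 1e-4),
            l1_ratio=params.get("l1_ratio", 0.15),
            max_iter=5000,
            tol=1e-10,
            learning_rate="adaptive",
            eta0=0.001,
            random_state=seed,
        ))
    if family == "lars":
        return Lars(n_nonzero_coefs=params.get("n_nonzero_coefs", 100))
    if family == "lasso_lars":
        return LassoLars(alpha=params.get("alpha", 1e-3))
    if family == "xgb":
        import xgboost as xgb

        return xgb.XGBRegressor(
            learning_rate=params.get("learning_rate", 0.1),
            max_depth=params.get("max_depth", 4),
            subsample=params.get("subsample", 1.0),
            n_estimators=params.get("n_estimators", 200),
            reg_lambda=params.get("reg_lambda", 1.0),
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    if family == "ngb":
        return NGBRegressor(
            n_estimators=params.get("n_estimators", 200),
            learning_rate=params.get("learning_rate", 0.1),
            max_depth=params.get("max_depth", 3),
            random_state=seed,
        )
    raise ValueError(f"unknown family {family!r}")
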