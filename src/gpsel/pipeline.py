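"""End-to-end genomic-prediction pipeline.

A :class:`TrialConfig` is one point in the joint preprocessing x model
space: which feature blocks are on, how markers are selected and encoded,
kernel and scaler choices, the target transform, and the model family with
its hyperparameters.  :class:`GenomicPipeline` realises a config as a
scikit-learn-style estimator: ``fit`` freezes every transform on the
training samples only, ``predict`` maps new samples through the frozen
state and returns predictions in original target units.

Family constraints on assembly (enforced here and in :func:`assemble`):

* tree families (random forest, extra trees, XGB, NGB) receive raw,
  unscaled features and no nonlinear or interaction blocks — trees handle
  interactions natively and ignore input range;
* SVM families skip nonlinear/interaction blocks (the SVM kernel covers
  them);
* k-nearest-neighbour models exclude distance-matrix features;
* Bayesian families receive block-structured effects: markers, nonlinear
  features, groups and interactions as separate random effects, covariates
  as fixed effects, and (optionally) NOIA additive/dominance designs with
  epistasis similarity matrices as RKHS kernel effects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import pairwise_distances

from . import models
from .bayes import EffectBlock, MCMCConfig, gibbs_fit, predict as bayes_predict
from .encoders import (
    NOIAAdditiveEncoder,
    NOIADominanceEncoder,
    OneHotDosageEncoder,
    VanRadenEncoder,
    epistasis_matrices,
    noia_kernels,
)
from .features import (
    AnovaFSelector,
    ApproxKernelFeatures,
    COVARIATE_SCALERS,
    GroupEncoder,
    KernelSpec,
    PolynomialExpander,
    QuantileScaler,
    drop_degenerate_columns,
)
from .genotypes import GenotypeMatrix
from .selectors import MarkerSelector
from .targets import PairwiseRanker, TargetTransform

BLOCK_ORDER = ("markers", "marker_distance", "marker_nonlinear", "groups",
               "covariates", "interactions")


@dataclass
class Dataset:
    """Aligned genotypes, target and optional covariates/grouping factor."""

    G: GenotypeMatrix
    y: np.ndarray | None = None
    covariates: np.ndarray | None = None
    groups: np.ndarray | None = None

    def __post_init__(self):
        n = self.G.n_samples
        if self.y is not None:
            self.y = np.asarray(self.y, float)
            if len(self.y) != n:
                raise ValueError("y length mismatch")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, float).reshape(n, -1)
        if self.groups is not None:
            self.groups = np.asarray(self.groups)

    @property
    def n(self) -> int:
        return self.G.n_samples

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(
            self.G.subset_samples(idx),
            None if self.y is None else self.y[idx],
            None if self.covariates is None else self.covariates[idx],
            None if self.groups is None else self.groups[idx],
        )


@dataclass
class TrialConfig:
    """One serialisable point in the preprocessing x model space."""

    family: str = "brr"
    task: str = "regression"
    # marker block
    marker_block: bool = True
    selector_method: str = "none"  # none | maf | multisurf | lmm
    selector_k: int = 200
    encoder: str = "vanraden"  # onehot | vanraden | noia | noia_ad | pca
    pca_k: int = 10
    # distance block
    distance_block: bool = False
    distance_metric: str = "vanraden"  # vanraden | manhattan | euclidean
    distance_k: int = 50
    # nonlinear block
    nonlinear_block: bool = False
    kernel_kind: str = "rbf"
    kernel_components: int = 50
    nonlinear_k: int = 50
    # groups / covariates
    groups_mode: str = "onehot"
    groups_k: int = 3
    covariate_scaler: str = "zscore"
    poly_degree: int = 1
    # interactions
    interactions_block: bool = False
    interaction_kernel: str = "rbf"
    # bayes extras
    use_epistasis: bool = False
    mcmc_iter: int = 1200
    mcmc_burn_in: int = 300
    mcmc_thin: int = 3
    # target + model
    target_transform: str = "identity"
    rank_scheme: str = "regression"  # regression | ordinal | pairwise
    model_params: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=str)

    @classmethod
    def from_json(cls, s: str) -> "TrialConfig":
        return cls(**json.loads(s))


def assemble(blocks: dict[str, np.ndarray], family: str) -> tuple[np.ndarray, list[str]]:
    """Concatenate feature blocks in canonical order under family rules.

    Disallowed blocks are silently excluded (logged via warning); an empty
    result raises ``empty feature space``.
    """
    drop = set()
    if family == "knn":
        drop.add("marker_distance")
    if family in models.TREE_FAMILIES:
        drop.update({"marker_nonlinear", "interactions"})
    if family == "svr":
        drop.update({"marker_nonlinear", "interactions"})
    parts, names = [], []
    for name in BLOCK_ORDER:
        if name not in blocks:
            continue
        if name in drop:
            warnings.warn(f"block {name!r} excluded for family {family!r}", stacklevel=2)
            continue
        M = np.asarray(blocks[name], float)
        if M.size == 0:
            continue
        parts.append(M)
        names.extend(f"{name}:{j}" for j in range(M.shape[1]))
    if not parts:
        raise ValueError("empty feature space: all blocks dropped")
    return np.hstack(parts), names


class GenomicPipeline(BaseEstimator):
    """Fit one TrialConfig end to end on a Dataset."""

    def __init__(self, config: TrialConfig | None = None):
        self.config = config or TrialConfig()

    # -- block builders -----------------------------------------------------

    def _fit_marker_state(self, data: Dataset):
        cfg = self.config
        G = data.G.impute_mode()
        self.selector_ = None
        if cfg.selector_method != "none":
            self.selector_ = MarkerSelector(
                cfg.selector_method, min(cfg.selector_k, G.n_markers), seed=cfg.seed
            ).fit(G, data.y, groups=data.groups)
            G = self.selector_.transform(G)
        self.train_markers_G_ = G
        self.vr_ = VanRadenEncoder().fit(G)
        self.Ztrain_ = self.vr_.transform(G)
        return G

    def _select_markers(self, data: Dataset) -> GenotypeMatrix:
        G = data.G.impute_mode()
        if self.selector_ is not None:
            G = self.selector_.transform(G)
        return G

    def _marker_features(self, G: GenotypeMatrix, fit: bool):
        cfg = self.config
        if cfg.encoder == "onehot":
            if fit:
                self.marker_enc_ = OneHotDosageEncoder().fit(G)
            return self.marker_enc_.transform(G)
        if cfg.encoder == "vanraden":
            return self.vr_.transform(G)
        if cfg.encoder == "noia":
            if fit:
                self.marker_enc_ = NOIAAdditiveEncoder().fit(G)
            return self.marker_enc_.transform(G)
        if cfg.encoder == "noia_ad":
            if fit:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    self.marker_enc_ = NOIAAdditiveEncoder().fit(G)
                    self.marker_dom_ = NOIADominanceEncoder().fit(G)
            return np.hstack([self.marker_enc_.transform(G), self.marker_dom_.transform(G)])
        if cfg.encoder == "pca":
            Z = self.vr_.transform(G)
            if fit:
                from sklearn.decomposition import PCA

                k = min(cfg.pca_k, min(Z.shape) - 1)
                self.marker_enc_ = PCA(n_components=max(k, 1), svd_solver="full").fit(Z)
            return self.marker_enc_.transform(Z)
        raise ValueError(f"unknown encoder {self.config.encoder!r}")

    def _distance_features(self, Z: np.ndarray, fit: bool, y=None):
        """Each sample's row of the distance/similarity matrix, columns
        anchored to the training samples."""
        cfg = self.config
        if cfg.distance_metric == "vanraden":
            denom = 2.0 * np.sum(self.vr_.stats_.p * (1 - self.vr_.stats_.p))
            F = Z @ self.Ztrain_.T / max(denom, 1e-12)
        else:
            F = pairwise_distances(Z, self.Ztrain_, metric=cfg.distance_metric)
        if self.config.family in models.TREE_FAMILIES:
            return F  # trees take raw features
        if fit:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.dist_scaler_ = QuantileScaler("normal").fit(F)
                self.dist_sel_ = AnovaFSelector(cfg.distance_k, "regression").fit(
                    self.dist_scaler_.transform(F), y
                )
        return self.dist_sel_.transform(self.dist_scaler_.transform(F))

    def _nonlinear_features(self, Z: np.ndarray, fit: bool, y=None):
        cfg = self.config
        if fit:
            spec = KernelSpec(cfg.kernel_kind, None,
                              min(cfg.kernel_components, Z.shape[0]), cfg.seed)
            self.kernel_ = ApproxKernelFeatures(spec).fit(Z)
            F = self.kernel_.transform(Z)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.nl_scaler_ = QuantileScaler("normal").fit(F)
                self.nl_sel_ = AnovaFSelector(cfg.nonlinear_k, "regression").fit(
                    self.nl_scaler_.transform(F), y
                )
        F = self.kernel_.transform(Z)
        return self.nl_sel_.transform(self.nl_scaler_.transform(F))

    def _group_features(self, groups, fit: bool):
        if fit:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.group_enc_ = GroupEncoder(self.config.groups_mode, self.config.groups_k).fit(groups)
        return self.group_enc_.transform(groups)

    def _covariate_features(self, C, fit: bool):
        cfg = self.config
        raw = cfg.family in models.TREE_FAMILIES
        if fit:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if raw:
                    self.cov_scaler_ = None
                else:
                    self.cov_scaler_ = COVARIATE_SCALERS[cfg.covariate_scaler]().fit(C)
                base = C if raw else self.cov_scaler_.transform(C)
                self.cov_poly_ = None
                if cfg.poly_degree > 1 and not raw:
                    self.cov_poly_ = PolynomialExpander(cfg.poly_degree).fit(base)
        base = C if self.cov_scaler_ is None else self.cov_scaler_.transform(C)
        if self.cov_poly_ is not None:
            base = self.cov_poly_.transform(base)
        return base

    def _build_blocks(self, data: Dataset, fit: bool) -> dict[str, np.ndarray]:
        cfg = self.config
        G = self._select_markers(data) if not fit else self._fit_marker_state(data)
        Z = self.vr_.transform(G)
        blocks: dict[str, np.ndarray] = {}
        if cfg.marker_block:
            blocks["markers"] = self._marker_features(G, fit)
        if cfg.distance_block:
            blocks["marker_distance"] = self._distance_features(Z, fit, data.y)
        if cfg.nonlinear_block:
            blocks["marker_nonlinear"] = self._nonlinear_features(Z, fit, data.y)
        if data.groups is not None:
            blocks["groups"] = self._group_features(data.groups, fit)
        if data.covariates is not None:
            blocks["covariates"] = self._covariate_features(data.covariates, fit)
        return blocks

    # -- generic (single-matrix) path ---------------------------------------

    def _assemble_matrix(self, data: Dataset, fit: bool) -> np.ndarray:
        cfg = self.config
        blocks = self._build_blocks(data, fit)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X, names = assemble(blocks, cfg.family)
        if cfg.interactions_block and cfg.family not in models.TREE_FAMILIES and cfg.family != "svr":
            if fit:
                spec = KernelSpec(cfg.interaction_kernel, None,
                                  min(50, X.shape[0]), cfg.seed)
                self.inter_kernel_ = ApproxKernelFeatures(spec).fit(X)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    self.inter_scaler_ = QuantileScaler("normal").fit(
                        self.inter_kernel_.transform(X)
                    )
            F = self.inter_scaler_.transform(self.inter_kernel_.transform(X))
            X = np.hstack([X, F])
        if fit:
            _, _, self.keep_cols_ = drop_degenerate_columns(X)
            if not self.keep_cols_.any():
                raise ValueError("empty feature space: all columns degenerate")
        return X[:, self.keep_cols_]

    # -- Bayesian (block-structured) path ------------------------------------

    def _bayes_blocks(self, data: Dataset, fit: bool):
        cfg = self.config
        prior = {"brr": "BRR", "bayesa": "BayesA", "bayesc": "BayesC", "bl": "BL"}[cfg.family]
        blocks = self._build_blocks(data, fit)
        n = data.n
        eff, newd = [], {}
        eff.append(EffectBlock("intercept", "FIXED", X=np.ones((n, 1))))
        newd["intercept"] = np.ones((n, 1))
        if "markers" in blocks:
            eff.append(EffectBlock("markers", prior, X=blocks["markers"]))
            newd["markers"] = blocks["markers"]
        if "marker_distance" in blocks:
            eff.append(EffectBlock("marker_distance", "BRR", X=blocks["marker_distance"]))
            newd["marker_distance"] = blocks["marker_distance"]
        if "marker_nonlinear" in blocks:
            eff.append(EffectBlock("marker_nonlinear", "BRR", X=blocks["marker_nonlinear"]))
            newd["marker_nonlinear"] = blocks["marker_nonlinear"]
        if "groups" in blocks and blocks["groups"].shape[1] > 0:
            eff.append(EffectBlock("groups", "BRR", X=blocks["groups"]))
            newd["groups"] = blocks["groups"]
        if "covariates" in blocks:
            eff.append(EffectBlock("covariates", "FIXED", X=blocks["covariates"]))
            newd["covariates"] = blocks["covariates"]
        if cfg.use_epistasis:
            G = self.train_markers_G_ if fit else self._select_markers(data)
            if fit:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    self.epi_add_ = NOIAAdditiveEncoder().fit(G)
                    self.epi_dom_ = NOIADominanceEncoder().fit(G)
                HA, HD = self.epi_add_.transform(G), self.epi_dom_.transform(G)
                self.epi_HA_, self.epi_HD_ = HA, HD
                GA, GD = noia_kernels(HA, HD, list(G.samples))
                self.epi_cA_ = np.mean(np.einsum("ij,ij->i", HA, HA))
                self.epi_cD_ = np.mean(np.einsum("ij,ij->i", HD, HD))
                epi = epistasis_matrices(GA, GD)
                self.epi_norm_ = {k: np.mean(np.diag(
                    {"epi_AA": GA.values * GA.values,
                     "epi_AD": GA.values * GD.values,
                     "epi_DD": GD.values * GD.values}[k])) for k in epi}
                for k, Kmat in epi.items():
                    eff.append(EffectBlock(k, "RKHS", K=Kmat.values))
                    newd[k] = Kmat.values
            else:
                HA, HD = self.epi_add_.transform(G), self.epi_dom_.transform(G)
                cA = HA @ self.epi_HA_.T / self.epi_cA_
                cD = HD @ self.epi_HD_.T / self.epi_cD_
                newd["epi_AA"] = cA * cA / self.epi_norm_["epi_AA"]
                newd["epi_AD"] = cA * cD / self.epi_norm_["epi_AD"]
                newd["epi_DD"] = cD * cD / self.epi_norm_["epi_DD"]
        return eff, newd

    # -- public API ----------------------------------------------------------

    def fit(self, data: Dataset):
        cfg = self.config
        if data.y is None:
            raise ValueError("training data needs a target")
        self.target_transform_ = TargetTransform(cfg.target_transform).fit(data.y)
        yt = self.target_transform_.transform(data.y)
        if cfg.family in models.BAYES_FAMILIES:
            eff, _ = self._bayes_blocks(data, fit=True)
            mcfg = MCMCConfig(cfg.mcmc_iter, cfg.mcmc_burn_in, cfg.mcmc_thin, cfg.seed)
            self.summary_ = gibbs_fit(yt, eff, mcfg)
        else:
            X = self._assemble_matrix(data, fit=True)
            if cfg.task == "ranking" and cfg.rank_scheme == "pairwise":
                if cfg.family != "xgb":
                    raise ValueError("pairwise ranking is only offered for xgb")
                self.model_ = PairwiseRanker(seed=cfg.seed).fit(X, yt)
            elif cfg.task == "ranking" and cfg.rank_scheme == "ordinal":
                from .targets import OrdinalClassifier

                self.model_ = OrdinalClassifier().fit(X, yt)
            else:
                self.model_ = models.build(cfg.family, cfg.model_params, cfg.seed, "regression")
                self.model_.fit(X, yt)
        return self

    def predict(self, data: Dataset) -> np.ndarray:
        cfg = self.config
        if cfg.family in models.BAYES_FAMILIES:
            _, newd = self._bayes_blocks(data, fit=False)
            pred = bayes_predict(self.summary_, newd)
        else:
            X = self._assemble_matrix(data, fit=False)
            pred = self.model_.predict(X)
        if cfg.task == "ranking" and cfg.rank_scheme in ("ordinal", "pairwise"):
            return pred  # rank scores have no original-unit inverse
        return self.target_transform_.inverse_transform(pred)
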