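"""The network-based classifier: per-class correlation networks whose nodes
carry regression predictors, and classification by reconstruction error.

For each class (sensitive, resistant) an undirected graph is built over the
selected genes: an edge joins two genes when the absolute Pearson correlation
of their expression vectors *within that class* exceeds a threshold. Each
node then gets a regression model predicting its expression from its
neighbors' expression — ridge regression (global penalty lambda, default
1e-3) or epsilon-SVR with an RBF kernel whose (C, gamma, epsilon-tube) are
grid-searched per node by inner cross-validation. A degree-0 node falls back
to its training-class mean.

A test sample x is reconstructed by both networks; the predicted class is the
one with the smaller mean squared reconstruction error over the m' genes
(exact ties resolve to resistant). The model thus classifies by *which
class's co-expression structure explains the sample better*, not by marginal
expression shifts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from ._utils import child_seed, logger
from .errors import DomainError, NBCError, TrainingError
from .feature_selection import DEFAULT_TERMS, FeatureSet
from .io_formats import GeneList
from .labeling import CLASSES, RESISTANT, SENSITIVE

DEFAULT_RIDGE_LAMBDA = 1e-3
DEFAULT_CORR_THRESHOLD = 0.76
#: outer tuning grid for the correlation threshold: 0.40 to 0.94 in steps of 0.06
DEFAULT_CORR_GRID = tuple(round(0.40 + 0.06 * i, 2) for i in range(10))
#: per-node SVR search space: C, gamma in {0.1, 1, 10}, epsilon-tube fixed at 0.1
DEFAULT_SVR_GRID = {"C": (0.1, 1.0, 10.0), "gamma": (0.1, 1.0, 10.0), "epsilon": (0.1,)}


@dataclass(frozen=True)
class RidgePredictor:
    """Linear per-node predictor: e_k ≈ coef · e_neighbors + intercept."""

    neighbors: tuple[str, ...]
    coef: np.ndarray
    intercept: float

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray, lam: float, neighbors) -> "RidgePredictor":
        model = Ridge(alpha=lam).fit(X, y)
        return cls(tuple(neighbors), np.asarray(model.coef_, float), float(model.intercept_))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "kind": "ridge",
            "neighbors": list(self.neighbors),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RidgePredictor":
        return cls(tuple(d["neighbors"]), np.asarray(d["coef"], float), float(d["intercept"]))


@dataclass(frozen=True)
class SVRPredictor:
    """RBF epsilon-SVR per-node predictor stored in dual form.

    Prediction is computed from the support vectors directly,
    f(x) = sum_i alpha_i * exp(-gamma ||sv_i - x||^2) + b, which makes the
    predictor JSON-serializable and bit-reproducible after a round trip.
    """

    neighbors: tuple[str, ...]
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    C: float
    epsilon: float

    @classmethod
    def fit(cls, X, y, C, gamma, epsilon, neighbors) -> "SVRPredictor":
        model = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon).fit(X, y)
        return cls(
            tuple(neighbors),
            np.asarray(model.support_vectors_, float),
            np.asarray(model.dual_coef_, float).ravel(),
            float(model.intercept_[0]),
            float(gamma),
            float(C),
            float(epsilon),
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if self.support_vectors.size == 0:  # all residuals inside the tube
            return np.full(X.shape[0], self.intercept)
        K = np.exp(-self.gamma * cdist(X, self.support_vectors, "sqeuclidean"))
        return K @ self.dual_coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "kind": "svr",
            "neighbors": list(self.neighbors),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "C": self.C,
            "epsilon": self.epsilon,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVRPredictor":
        return cls(
            tuple(d["neighbors"]),
            np.asarray(d["support_vectors"], float),
            np.asarray(d["dual_coef"], float),
            float(d["intercept"]),
            float(d["gamma"]),
            float(d["C"]),
            float(d["epsilon"]),
        )


_PREDICTOR_KINDS = {"ridge": RidgePredictor, "svr": SVRPredictor}


@dataclass
class ClassNetwork:
    """Correlation graph for one class plus one fitted predictor per node."""

    class_label: str
    genes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    corr_threshold: float
    predictors: dict[str, RidgePredictor | SVRPredictor] = field(default_factory=dict)
    fallback_means: dict[str, float] = field(default_factory=dict)

    def neighbors(self, gene: str) -> list[str]:
        """Neighbors of ``gene`` in this class's graph, in gene order."""
        adjacent = {b if a == gene else a for a, b in self.edges if gene in (a, b)}
        return [g for g in self.genes if g in adjacent]

    def degree(self, gene: str) -> int:
        return len(self.neighbors(gene))

    def predict_expression(self, x) -> np.ndarray:
        """Reconstruct an expression vector aligned to ``self.genes``.

        y_k is the node-k predictor applied to x restricted to k's neighbors;
        degree-0 nodes return their training-class mean.
        """
        x = np.asarray(x, dtype=float)
        if x.shape != (len(self.genes),):
            raise NBCError(
                f"expected a vector of length {len(self.genes)}, got shape {x.shape}"
            )
        if not self.predictors and not self.fallback_means:
            raise TrainingError("network has no fitted predictors")
        pos = {g: i for i, g in enumerate(self.genes)}
        y = np.empty(len(self.genes))
        for k, gene in enumerate(self.genes):
            if gene in self.predictors:
                pred = self.predictors[gene]
                xn = x[[pos[g] for g in pred.neighbors]]
                y[k] = float(pred.predict(xn.reshape(1, -1))[0])
            else:
                y[k] = self.fallback_means[gene]
        return y

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Reconstruct many samples at once (rows aligned to ``self.genes``)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.genes):
            raise NBCError(f"expected an (n, {len(self.genes)}) matrix, got {X.shape}")
        pos = {g: i for i, g in enumerate(self.genes)}
        Y = np.empty_like(X)
        for k, gene in enumerate(self.genes):
            if gene in self.predictors:
                pred = self.predictors[gene]
                Y[:, k] = pred.predict(X[:, [pos[g] for g in pred.neighbors]])
            else:
                Y[:, k] = self.fallback_means[gene]
        return Y

    def to_dict(self) -> dict:
        return {
            "class_label": self.class_label,
            "genes": list(self.genes),
            "edges": sorted(map(list, self.edges)),
            "corr_threshold": self.corr_threshold,
            "predictors": {g: p.to_dict() for g, p in self.predictors.items()},
            "fallback_means": self.fallback_means,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassNetwork":
        predictors = {
            g: _PREDICTOR_KINDS[p["kind"]].from_dict(p) for g, p in d["predictors"].items()
        }
        return cls(
            class_label=d["class_label"],
            genes=tuple(d["genes"]),
            edges=frozenset(tuple(e) for e in d["edges"]),
            corr_threshold=float(d["corr_threshold"]),
            predictors=predictors,
            fallback_means={g: float(v) for g, v in d["fallback_means"].items()},
        )


@dataclass(frozen=True)
class PredictionResult:
    predicted_class: str
    mse_sensitive: float
    mse_resistant: float
    per_gene_errors: pd.DataFrame  # columns: eps_sensitive, eps_resistant


@dataclass
class NBCModel:
    """A fitted pair of class networks sharing one gene list and threshold."""

    sensitive_net: ClassNetwork
    resistant_net: ClassNetwork
    feature_set: FeatureSet
    predictor_kind: Literal["ridge", "svr"]
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sensitive_net.genes != self.resistant_net.genes:
            raise NBCError("the two class networks must share an identical gene list")
        if self.sensitive_net.corr_threshold != self.resistant_net.corr_threshold:
            raise NBCError("the two class networks must share the correlation threshold")

    @property
    def genes(self) -> tuple[str, ...]:
        return self.sensitive_net.genes

    def classify(self, x) -> PredictionResult:
        """MSE rule: the class whose network reconstructs ``x`` better wins.

        An exact MSE tie resolves to resistant (fixed, documented rule).
        """
        x = np.asarray(x, dtype=float)
        y_s = self.sensitive_net.predict_expression(x)
        y_r = self.resistant_net.predict_expression(x)
        eps_s = (x - y_s) ** 2
        eps_r = (x - y_r) ** 2
        mse_s = float(eps_s.mean())
        mse_r = float(eps_r.mean())
        per_gene = pd.DataFrame(
            {"eps_sensitive": eps_s, "eps_resistant": eps_r}, index=list(self.genes)
        )
        predicted = SENSITIVE if mse_s < mse_r else RESISTANT
        return PredictionResult(predicted, mse_s, mse_r, per_gene)

    def mse_matrix(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample reconstruction MSE under each network, vectorized."""
        X = np.asarray(X, dtype=float)
        mse_s = ((X - self.sensitive_net.predict_matrix(X)) ** 2).mean(axis=1)
        mse_r = ((X - self.resistant_net.predict_matrix(X)) ** 2).mean(axis=1)
        return mse_s, mse_r

    def decision_score(self, x) -> float:
        """Margin of the MSE rule: mse_resistant − mse_sensitive.

        Positive scores favor the sensitive class; used for ROC curves.
        """
        res = self.classify(x)
        return res.mse_resistant - res.mse_sensitive

    def save(self, path) -> None:
        doc = {
            "format": "nbclass-model",
            "version": 1,
            "predictor_kind": self.predictor_kind,
            "hyperparams": self.hyperparams,
            "feature_set": {
                "genes": list(self.feature_set.genes),
                "method": self.feature_set.method,
            },
            "sensitive_net": self.sensitive_net.to_dict(),
            "resistant_net": self.resistant_net.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "NBCModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "nbclass-model":
            raise NBCError(f"{path}: not a serialized model archive")
        fs = FeatureSet(genes=tuple(doc["feature_set"]["genes"]), method=doc["feature_set"]["method"])
        return cls(
            sensitive_net=ClassNetwork.from_dict(doc["sensitive_net"]),
            resistant_net=ClassNetwork.from_dict(doc["resistant_net"]),
            feature_set=fs,
            predictor_kind=doc["predictor_kind"],
            hyperparams=doc["hyperparams"],
        )


def build_class_network(
    class_expr: pd.DataFrame, corr_threshold: float, class_label: str = SENSITIVE
) -> ClassNetwork:
    """Edge (i, j) present iff |Pearson r(e_i, e_j)| > corr_threshold.

    ``class_expr`` is samples x genes for one class's training cell lines.
    Correlation with a constant vector is defined as 0 (no edge), so
    zero-variance genes end up isolated.
    """
    if not 0 < corr_threshold < 1:
        raise DomainError(f"corr_threshold must be in (0, 1), got {corr_threshold}")
    if class_expr.shape[0] < 3:
        raise TrainingError(
            f"need at least 3 samples in the {class_label} class to estimate "
            f"correlations, got {class_expr.shape[0]}"
        )
    genes = tuple(class_expr.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(class_expr.to_numpy(), rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    edges = set()
    m = len(genes)
    for i in range(m):
        for j in range(i + 1, m):
            if abs(corr[i, j]) > corr_threshold:
                edges.add((genes[i], genes[j]))
    return ClassNetwork(
        class_label=class_label,
        genes=genes,
        edges=frozenset(edges),
        corr_threshold=corr_threshold,
    )


def fit_ridge_predictors(
    network: ClassNetwork, class_expr: pd.DataFrame, lam: float = DEFAULT_RIDGE_LAMBDA
) -> ClassNetwork:
    """Fit one intercept-including ridge model per node from its neighbors."""
    X = class_expr[list(network.genes)]
    predictors: dict[str, RidgePredictor] = {}
    fallback: dict[str, float] = {}
    for gene in network.genes:
        nbrs = network.neighbors(gene)
        if nbrs:
            predictors[gene] = RidgePredictor.fit(
                X[nbrs].to_numpy(), X[gene].to_numpy(), lam, nbrs
            )
        else:
            fallback[gene] = float(X[gene].mean())
    network.predictors = predictors
    network.fallback_means = fallback
    return network


def fit_svr_predictors(
    network: ClassNetwork,
    class_expr: pd.DataFrame,
    grid: dict | None = None,
    inner_folds: int = 5,
    seed: int = 0,
) -> ClassNetwork:
    """Per-node RBF-SVR with a grid search over (C, gamma, epsilon-tube).

    Each grid point is scored by ``inner_folds``-fold CV mean squared error on
    the class's training samples using one shared seeded split; ties break
    toward the smallest C then the smallest gamma. The winner is refit on all
    class samples. If the class has fewer samples than folds, the fold count
    is reduced with a warning.
    """
    grid = grid or DEFAULT_SVR_GRID
    n = class_expr.shape[0]
    if n < 2:
        raise TrainingError("need at least 2 samples to fit SVR predictors")
    folds = min(inner_folds, n)
    if folds < inner_folds:
        logger.warning(
            "class %s has %d samples < %d folds; using %d-fold per-node search",
            network.class_label, n, inner_folds, folds,
        )
    combos = [
        (C, g, e)
        for C in sorted(grid["C"])
        for g in sorted(grid["gamma"])
        for e in sorted(grid["epsilon"])
    ]
    splitter = KFold(n_splits=folds, shuffle=True, random_state=child_seed(seed, 0xC5))
    splits = list(splitter.split(np.arange(n)))
    X = class_expr[list(network.genes)]
    predictors: dict[str, SVRPredictor] = {}
    fallback: dict[str, float] = {}
    for gene in network.genes:
        nbrs = network.neighbors(gene)
        if not nbrs:
            fallback[gene] = float(X[gene].mean())
            continue
        A = X[nbrs].to_numpy()
        y = X[gene].to_numpy()
        if len(combos) == 1:
            best = combos[0]
        else:
            best, best_mse = None, np.inf
            for C, g, e in combos:
                errs = []
                for tr, va in splits:
                    model = SVR(kernel="rbf", C=C, gamma=g, epsilon=e).fit(A[tr], y[tr])
                    errs.append(float(np.mean((model.predict(A[va]) - y[va]) ** 2)))
                mse = float(np.mean(errs))
                if mse < best_mse:  # strict: first (smallest C, gamma) wins ties
                    best, best_mse = (C, g, e), mse
        predictors[gene] = SVRPredictor.fit(A, y, *best, neighbors=nbrs)
    network.predictors = predictors
    network.fallback_means = fallback
    return network


def fit_nbc(
    features: pd.DataFrame,
    labels,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    predictor: Literal["ridge", "svr"] = "ridge",
    ridge_lambda: float = DEFAULT_RIDGE_LAMBDA,
    svr_grid: dict | None = None,
    inner_folds: int = 5,
    seed: int = 0,
    feature_set: FeatureSet | None = None,
) -> NBCModel:
    """Build and fit both class networks on already-selected features.

    ``features`` is samples x genes restricted to the selected gene set;
    ``labels`` maps each sample to resistant/sensitive.
    """
    if predictor not in _PREDICTOR_KINDS:
        raise DomainError(f"unknown predictor kind {predictor!r}")
    lab = np.asarray(labels, dtype=object)
    nets = {}
    for cls in CLASSES:
        class_expr = features.loc[lab == cls]
        net = build_class_network(class_expr, corr_threshold, class_label=cls)
        if predictor == "ridge":
            net = fit_ridge_predictors(net, class_expr, lam=ridge_lambda)
        else:
            net = fit_svr_predictors(
                net, class_expr, grid=svr_grid, inner_folds=inner_folds,
                seed=child_seed(seed, 0 if cls == RESISTANT else 1),
            )
        nets[cls] = net
    fs = feature_set or FeatureSet(genes=tuple(features.columns), method="preselected")
    hyper = {"corr_threshold": corr_threshold}
    if predictor == "ridge":
        hyper["ridge_lambda"] = ridge_lambda
    else:
        hyper["svr_grid"] = {k: list(v) for k, v in (svr_grid or DEFAULT_SVR_GRID).items()}
    return NBCModel(
        sensitive_net=nets[SENSITIVE],
        resistant_net=nets[RESISTANT],
        feature_set=fs,
        predictor_kind=predictor,
        hyperparams=hyper,
    )


class NBCClassifier:
    """Estimator wrapper: feature selection + network fitting + MSE rule.

    Follows the fit/predict convention so it can plug into the evaluation
    protocol. When ``n_features`` is set, chi-square selection runs inside
    ``fit`` on the training portion only, which keeps nested cross-validation
    free of feature-selection leakage.
    """

    def __init__(
        self,
        corr_threshold: float = DEFAULT_CORR_THRESHOLD,
        predictor: Literal["ridge", "svr"] = "ridge",
        ridge_lambda: float = DEFAULT_RIDGE_LAMBDA,
        n_features: int | None = None,
        chi2_bins: int = DEFAULT_TERMS,
        candidates: GeneList | None = None,
        svr_grid: dict | None = None,
        inner_folds: int = 5,
        seed: int = 0,
    ):
        self.corr_threshold = corr_threshold
        self.predictor = predictor
        self.ridge_lambda = ridge_lambda
        self.n_features = n_features
        self.chi2_bins = chi2_bins
        self.candidates = candidates
        self.svr_grid = svr_grid
        self.inner_folds = inner_folds
        self.seed = seed
        self.model_: NBCModel | None = None

    def fit(self, X: pd.DataFrame, y) -> "NBCClassifier":
        from .feature_selection import select_top_genes

        if self.n_features is not None:
            fs = select_top_genes(
                X, y, self.n_features, t=self.chi2_bins, candidates=self.candidates
            )
            X = X[list(fs.genes)]
        else:
            fs = None
        self.model_ = fit_nbc(
            X,
            y,
            corr_threshold=self.corr_threshold,
            predictor=self.predictor,
            ridge_lambda=self.ridge_lambda,
            svr_grid=self.svr_grid,
            inner_folds=self.inner_folds,
            seed=self.seed,
            feature_set=fs,
        )
        return self

    def _check_fitted(self) -> NBCModel:
        if self.model_ is None:
            raise NBCError("classifier is not fitted")
        return self.model_

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        model = self._check_fitted()
        mse_s, mse_r = model.mse_matrix(X[list(model.genes)].to_numpy())
        return np.where(mse_s < mse_r, SENSITIVE, RESISTANT).astype(object)

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        model = self._check_fitted()
        mse_s, mse_r = model.mse_matrix(X[list(model.genes)].to_numpy())
        return mse_r - mse_s
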