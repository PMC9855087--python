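"""Multi-output random-forest relevance model.

Fits a forest mapping drug-target (KDT) gene expression to circuit
activities, scores per-circuit predictability with out-of-fold R2, and
derives per-gene relevance as the mean absolute interventional Shapley
contribution across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold

from . import shapley
from .activity import CircuitActivityMatrix, ExpressionMatrix


@dataclass
class RelevanceConfig:
    kdt_genes: list[str]
    n_trees: int = 500
    max_depth: int | None = None
    mtry_fraction: float = 1.0 / 3.0
    cv_folds: int = 5
    seed: int = 0
    shap_mode: str = "interventional"
    background_size: int = 100

    def __post_init__(self) -> None:
        if not self.kdt_genes:
            raise ValueError("kdt_genes must be non-empty")
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if not 0 < self.mtry_fraction <= 1:
            raise ValueError("mtry_fraction must lie in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.shap_mode != "interventional":
            raise ValueError("only interventional SHAP is supported")


@dataclass
class FittedRelevanceModel:
    forest: RandomForestRegressor
    config: RelevanceConfig
    gene_ids: list[str]
    circuit_ids: list[str]
    X_train: np.ndarray
    r2: np.ndarray  # per-circuit out-of-fold R2

    def predict(self, X: np.ndarray) -> np.ndarray:
        pred = self.forest.predict(X)
        return pred.reshape(X.shape[0], len(self.circuit_ids))


@dataclass
class RelevanceResult:
    gene_ids: list[str]
    circuit_ids: list[str]
    relevance: np.ndarray          # genes x circuits, mean |phi|
    r2: np.ndarray                 # per circuit
    global_relevance: np.ndarray   # per gene
    global_rank: np.ndarray        # per gene, 1 = most relevant

    @property
    def n_kdts(self) -> int:
        return len(self.gene_ids)

    def relevance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.relevance, index=self.gene_ids, columns=self.circuit_ids)

    def global_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene": self.gene_ids,
                "global_relevance": self.global_relevance,
                "rank": self.global_rank,
            }
        )
        return df.sort_values("rank").reset_index(drop=True)


def _squeeze_y(Y: np.ndarray) -> np.ndarray:
    # sklearn warns on single-output (n, 1) targets
    return Y[:, 0] if Y.shape[1] == 1 else Y


def _make_forest(config: RelevanceConfig) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features=config.mtry_fraction,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )


def cross_validated_r2(
    X: np.ndarray, Y: np.ndarray, config: RelevanceConfig
) -> np.ndarray:
    """Per-circuit R2 from out-of-fold K-fold predictions.

    A circuit whose observed activity is constant gets R2 = 0 by convention.
    """
    n = X.shape[0]
    if n < config.cv_folds:
        raise ValueError(f"need at least cv_folds={config.cv_folds} samples, got {n}")
    oof = np.empty_like(Y)
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    for train_idx, test_idx in kf.split(X):
        fold_forest = _make_forest(config)
        fold_forest.fit(X[train_idx], _squeeze_y(Y[train_idx]))
        pred = fold_forest.predict(X[test_idx])
        oof[test_idx] = pred.reshape(len(test_idx), Y.shape[1])
    r2 = np.empty(Y.shape[1])
    for c in range(Y.shape[1]):
        if np.ptp(Y[:, c]) == 0:
            r2[c] = 0.0
        else:
            r2[c] = r2_score(Y[:, c], oof[:, c])
    return r2


def fit_relevance_model(
    expr: ExpressionMatrix, activities: CircuitActivityMatrix, config: RelevanceConfig
) -> FittedRelevanceModel:
    """Fit the forest on KDT expression columns and score per-circuit R2."""
    if expr.sample_ids != activities.sample_ids:
        raise ValueError("expression and activity matrices are not row-aligned")
    X = expr.subset_genes(config.kdt_genes).values
    Y = activities.values
    if Y.shape[1] == 0:
        raise ValueError("activity matrix has no circuits")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in model inputs")
    r2 = cross_validated_r2(X, Y, config)
    forest = _make_forest(config)
    forest.fit(X, _squeeze_y(Y))
    return FittedRelevanceModel(
        forest=forest,
        config=config,
        gene_ids=list(config.kdt_genes),
        circuit_ids=list(activities.circuit_ids),
        X_train=X,
        r2=r2,
    )


def draw_background(
    X_train: np.ndarray, background_size: int, seed: int
) -> np.ndarray:
    """Seeded background sample (without replacement) from the training X."""
    n = X_train.shape[0]
    size = min(background_size, n)
    if size < 1:
        raise ValueError("background set would be empty")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=size, replace=False)
    return X_train[np.sort(idx)]


def shap_relevance(
    model: FittedRelevanceModel, X: np.ndarray | None = None
) -> np.ndarray:
    """Genes x circuits matrix of mean |Shapley contribution| across samples."""
    if X is None:
        X = model.X_train
    background = draw_background(
        model.X_train, model.config.background_size, model.config.seed
    )
    phi = shapley.shap_values(model.forest, X, background)
    return np.abs(phi).mean(axis=0)  # (n_genes, n_circuits)


def global_relevance(
    relevance: np.ndarray, gene_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate per-circuit relevance to a per-gene score and rank.

    Score is the mean over circuits; ranks are 1-based by descending score
    with ties broken by gene symbol (ascending).
    """
    relevance = np.asarray(relevance, dtype=float)
    if relevance.ndim != 2 or relevance.shape[1] == 0:
        raise ValueError("relevance matrix must be genes x circuits with >= 1 circuit")
    scores = relevance.mean(axis=1)
    order = sorted(range(len(gene_ids)), key=lambda i: (-scores[i], gene_ids[i]))
    ranks = np.empty(len(gene_ids), dtype=int)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return scores, ranks


def compute_relevance(
    expr: ExpressionMatrix, activities: CircuitActivityMatrix, config: RelevanceConfig
) -> tuple[RelevanceResult, FittedRelevanceModel]:
    """Fit, explain, and aggregate in one call."""
    model = fit_relevance_model(expr, activities, config)
    rel = shap_relevance(model)
    scores, ranks = global_relevance(rel, model.gene_ids)
    result = RelevanceResult(
        gene_ids=model.gene_ids,
        circuit_ids=model.circuit_ids,
        relevance=rel,
        r2=model.r2,
        global_relevance=scores,
        global_rank=ranks,
    )
    return result, model
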