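"""Stability of the feature-selection procedure across data resamples.

Given a binary matrix Z (M resamples x d features) of selected features,
the stability estimate is

    phi_hat = 1 - mean_f s_f^2 / (kbar/d * (1 - kbar/d))

where s_f^2 is the unbiased sample variance of feature f's selection
indicator and kbar the mean number of features selected per resample.
phi_hat = 1 iff every resample selects the same (non-degenerate) set; it is
0 in expectation under uniformly random selection of the same counts.

Confidence intervals come from a percentile bootstrap over resample rows;
the effect size is phi_hat minus the mean estimate under a matched random
null (same per-row selection counts).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .activity import ExpressionMatrix, compute_activities, normalize_expression
from .graphio import PathwayCollection
from .relevance import (
    RelevanceConfig,
    fit_relevance_model,
    shap_relevance,
)
from .selection import select_all


class UndefinedStabilityError(ValueError):
    """Selection matrix is degenerate (nothing or everything selected)."""


@dataclass
class SelectionMatrix:
    Z: np.ndarray  # (M, d) binary
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z)
        if self.Z.ndim != 2 or self.Z.shape[0] < 2:
            raise ValueError("Z must be 2-D with at least 2 resample rows")
        if self.Z.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids length must match Z columns")
        if not np.isin(self.Z, (0, 1)).all():
            raise ValueError("Z entries must be 0/1")
        self.Z = self.Z.astype(np.int8)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.Z, columns=self.feature_ids).to_csv(
            path, sep="\t", index_label="resample"
        )


@dataclass
class StabilityReport:
    phi_hat: float
    ci_low: float
    ci_high: float
    null_phi: float
    effect_size: float
    M: int
    d: int
    mean_k: float
    seed: int | None = None
    parameters: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)
            fh.write("\n")


def _phi(Z: np.ndarray) -> float:
    M, d = Z.shape
    kbar = Z.sum(axis=1).mean()
    if kbar <= 0 or kbar >= d:
        raise UndefinedStabilityError(
            f"mean selection count {kbar} is degenerate for d={d}"
        )
    p = Z.mean(axis=0)
    s2 = M / (M - 1) * p * (1 - p)
    denom = (kbar / d) * (1 - kbar / d)
    return float(1.0 - s2.mean() / denom)


def nogueira_stability(selection: SelectionMatrix | np.ndarray) -> float:
    """Point estimate of selection stability; raises if Z is degenerate."""
    Z = selection.Z if isinstance(selection, SelectionMatrix) else np.asarray(selection)
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 resamples")
    return _phi(Z)


def stability_ci(
    selection: SelectionMatrix | np.ndarray,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """95% percentile-bootstrap CI over resample rows.

    Bootstrap replicates with a degenerate mean selection count are skipped;
    if every replicate is degenerate an error is raised.
    """
    Z = selection.Z if isinstance(selection, SelectionMatrix) else np.asarray(selection)
    M = Z.shape[0]
    rng = np.random.default_rng(seed)
    estimates = []
    n_skipped = 0
    for _ in range(B):
        rows = rng.integers(0, M, size=M)
        try:
            estimates.append(_phi(Z[rows]))
        except UndefinedStabilityError:
            n_skipped += 1
    if not estimates:
        raise UndefinedStabilityError("all bootstrap replicates were degenerate")
    lo, hi = np.quantile(estimates, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def matched_null_phi(
    selection: SelectionMatrix | np.ndarray, draws: int = 500, seed: int = 0
) -> float:
    """Mean stability under random selection with the same per-row counts."""
    Z = selection.Z if isinstance(selection, SelectionMatrix) else np.asarray(selection)
    M, d = Z.shape
    counts = Z.sum(axis=1)
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(draws):
        Znull = np.zeros((M, d), dtype=np.int8)
        for m in range(M):
            k = int(counts[m])
            if k > 0:
                Znull[m, rng.choice(d, size=k, replace=False)] = 1
        try:
            values.append(_phi(Znull))
        except UndefinedStabilityError:
            continue
    if not values:
        raise UndefinedStabilityError("null model degenerate for every draw")
    return float(np.mean(values))


def run_stability_harness(
    collection: PathwayCollection,
    raw_expr: ExpressionMatrix,
    config: RelevanceConfig,
    M: int = 30,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    gamma: float = 1.0,
    upper_quantile: float = 0.99,
    per_circuit: bool = False,
    bootstrap_reps: int = 1000,
    null_draws: int = 500,
) -> tuple[SelectionMatrix, StabilityReport]:
    """Refit relevance + selection on M seeded subsamples and assess stability.

    Each resample draws ``floor(subsample_fraction * n)`` samples without
    replacement, re-normalizes, recomputes activities, refits the forest and
    records the union over circuits of the selected KDTs as one binary row
    (or one row per circuit when ``per_circuit=True``).
    """
    if M < 2:
        raise ValueError("need at least 2 resamples")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    n = raw_expr.n_samples
    size = max(int(np.floor(subsample_fraction * n)), config.cv_folds)
    rng = np.random.default_rng(seed)
    feature_ids = list(config.kdt_genes)
    pos = {g: j for j, g in enumerate(feature_ids)}
    rows = []
    for m in range(M):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        sub = raw_expr.subset_samples(idx)
        norm = normalize_expression(sub, upper_quantile=upper_quantile)
        acts = compute_activities(collection, norm)
        sub_config = dataclasses.replace(config, seed=int(config.seed + 1000 * (m + 1)))
        model = fit_relevance_model(norm, acts, sub_config)
        rel = shap_relevance(model)
        selections = select_all(feature_ids, model.circuit_ids, rel, model.r2, gamma=gamma)
        if per_circuit:
            for sel in selections:
                row = np.zeros(len(feature_ids), dtype=np.int8)
                for g in sel.selected_kdts:
                    row[pos[g]] = 1
                rows.append(row)
        else:
            row = np.zeros(len(feature_ids), dtype=np.int8)
            for sel in selections:
                for g in sel.selected_kdts:
                    row[pos[g]] = 1
            rows.append(row)
    Z = SelectionMatrix(np.vstack(rows), feature_ids)

    try:
        phi = nogueira_stability(Z)
        ci_low, ci_high = stability_ci(Z, B=bootstrap_reps, seed=seed + 1)
        null = matched_null_phi(Z, draws=null_draws, seed=seed + 2)
        effect = phi - null
    except UndefinedStabilityError:
        phi = ci_low = ci_high = null = effect = float("nan")
    report = StabilityReport(
        phi_hat=phi,
        ci_low=ci_low,
        ci_high=ci_high,
        null_phi=null,
        effect_size=effect,
        M=Z.Z.shape[0],
        d=Z.Z.shape[1],
        mean_k=float(Z.Z.sum(axis=1).mean()),
        seed=seed,
        parameters={
            "subsample_fraction": subsample_fraction,
            "gamma": gamma,
            "upper_quantile": upper_quantile,
            "per_circuit": per_circuit,
            "bootstrap_reps": bootstrap_reps,
            "null_draws": null_draws,
        },
    )
    return Z, report
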