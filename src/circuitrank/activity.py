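"""Expression normalization and circuit-activity computation.

Signal propagates through a circuit in topological order. A receptor node
passes its own normalized expression through unchanged; every other node n
with activating parents A and inhibiting parents I takes

    S_n = v_n * (1 - prod_{a in A}(1 - S_a)) * prod_{i in I}(1 - S_i)

with the activation factor defined as 1 when A is empty. The circuit
activity is the signal at the effector node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graphio import ACTIVATION, Circuit, PathwayCollection

logger = logging.getLogger(__name__)

_VALUE_TOL = 1e-12


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values (non-negative)."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no missing values)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes: list[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing}")
        return np.array([pos[g] for g in genes], dtype=int)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(self.sample_ids, list(genes), self.values[:, idx])

    def subset_samples(self, indices: np.ndarray) -> "ExpressionMatrix":
        indices = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            [self.sample_ids[i] for i in indices], self.gene_ids, self.values[indices]
        )

    def to_frame(self) -> pd.DataFrame:
        """Genes x samples frame matching the on-disk orientation."""
        return pd.DataFrame(self.values.T, index=self.gene_ids, columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), list(df.index), df.values.T)


@dataclass
class CircuitActivityMatrix:
    """Samples x circuits activity values, each in [0, 1]."""

    sample_ids: list[str]
    circuit_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.circuit_ids)):
            raise ValueError("values shape does not match sample/circuit ids")
        if np.any(self.values < -_VALUE_TOL) or np.any(self.values > 1 + _VALUE_TOL):
            raise ValueError("circuit activities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.circuit_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "CircuitActivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(s) for s in df.index], list(df.columns), df.values)


def normalize_expression(
    raw: ExpressionMatrix, upper_quantile: float = 0.99
) -> ExpressionMatrix:
    """Quantile-truncate and min-max scale each gene to [0, 1].

    Per gene, values are truncated at the gene's ``upper_quantile`` quantile
    and then scaled so the truncated range maps onto [0, 1]. A gene constant
    across samples maps to all zeros (no signal injected).
    """
    if not 0 < upper_quantile <= 1:
        raise ValueError("upper_quantile must lie in (0, 1]")
    if np.any(raw.values < 0):
        raise ValueError("expression values must be non-negative")
    vals = raw.values
    hi = np.quantile(vals, upper_quantile, axis=0)
    truncated = np.minimum(vals, hi)
    lo = truncated.min(axis=0)
    span = truncated.max(axis=0) - lo
    out = np.zeros_like(truncated)
    ok = span > 0
    out[:, ok] = (truncated[:, ok] - lo[ok]) / span[ok]
    n_const = int((~ok).sum())
    if n_const:
        logger.debug("normalize_expression: %d constant gene(s) mapped to 0", n_const)
    return ExpressionMatrix(raw.sample_ids, raw.gene_ids, out)


def node_values(
    expr: ExpressionMatrix,
    circuit: Circuit,
    aggregator: str = "mean",
    missing: str = "error",
) -> dict[str, np.ndarray]:
    """Per-sample node values: aggregate each node's genes (mean or min).

    ``missing`` controls the policy for genes absent from the matrix:
    ``"error"`` (default) raises, ``"impute"`` substitutes 0.5 with a warning.
    """
    if aggregator not in ("mean", "min"):
        raise ValueError("aggregator must be 'mean' or 'min'")
    if missing not in ("error", "impute"):
        raise ValueError("missing policy must be 'error' or 'impute'")
    pos = {g: i for i, g in enumerate(expr.gene_ids)}
    n = expr.n_samples
    out: dict[str, np.ndarray] = {}
    for node in circuit.nodes:
        cols = []
        for g in node.genes:
            if g in pos:
                cols.append(expr.values[:, pos[g]])
            elif missing == "impute":
                logger.warning(
                    "circuit %s node %s: gene %s absent, imputing 0.5",
                    circuit.id, node.id, g,
                )
                cols.append(np.full(n, 0.5))
            else:
                raise KeyError(
                    f"circuit {circuit.id!r}: gene {g!r} absent from expression matrix"
                )
        stacked = np.vstack(cols)
        out[node.id] = stacked.mean(axis=0) if aggregator == "mean" else stacked.min(axis=0)
    return out


def propagate_circuit(
    circuit: Circuit, node_vals: dict[str, np.ndarray | float]
) -> np.ndarray:
    """Propagate node values through the circuit DAG; return effector signal."""
    vals = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in node_vals.items()}
    for nid, v in vals.items():
        if np.any(v < -_VALUE_TOL) or np.any(v > 1 + _VALUE_TOL):
            raise ValueError(
                f"circuit {circuit.id!r}: node {nid!r} value outside [0, 1] "
                "(normalization contract violated)"
            )
    g = circuit.graph()
    receptors = set(circuit.receptors)
    signal: dict[str, np.ndarray] = {}
    for nid in nx.topological_sort(g):
        v = np.clip(vals[nid], 0.0, 1.0)
        if nid in receptors:
            signal[nid] = v
            continue
        act = [signal[p] for p in g.predecessors(nid) if g.edges[p, nid]["sign"] == ACTIVATION]
        inh = [signal[p] for p in g.predecessors(nid) if g.edges[p, nid]["sign"] != ACTIVATION]
        s = v
        if len(act) == 1:
            # single activating parent: multiply directly (1-(1-x) loses a ulp)
            s = s * act[0]
        elif act:
            one_minus = np.ones_like(s)
            for a in act:
                one_minus = one_minus * (1.0 - a)
            s = s * (1.0 - one_minus)
        for i in inh:
            s = s * (1.0 - i)
        signal[nid] = s
    return signal[circuit.effector]


def compute_activities(
    collection: PathwayCollection,
    expr: ExpressionMatrix,
    aggregator: str = "mean",
    missing: str = "error",
) -> CircuitActivityMatrix:
    """One activity column per circuit, rows aligned to the expression samples.

    ``expr`` must already be normalized to [0, 1].
    """
    columns = []
    for circuit in collection.circuits:
        nv = node_values(expr, circuit, aggregator=aggregator, missing=missing)
        columns.append(propagate_circuit(circuit, nv))
    values = np.column_stack(columns) if columns else np.zeros((expr.n_samples, 0))
    return CircuitActivityMatrix(expr.sample_ids, collection.circuit_ids, values)
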