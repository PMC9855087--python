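"""R2-gated selection of top-ranked drug-target genes per circuit.

The fraction of genes selected for a circuit interpolates convexly with the
circuit's predictability: at R2 = 1 the top 5% of the ranking is kept
(effective quantile 0.95); as R2 falls toward 0 the selected fraction
shrinks linearly to nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

TOP_FRACTION = 0.05
_EPS = 1e-9


@dataclass
class CircuitSelection:
    circuit_id: str
    r2: float
    selected_fraction: float
    selected_kdts: list[str]


def select_kdts(
    circuit_id: str,
    genes: list[str],
    scores: np.ndarray,
    r2: float,
    gamma: float = 1.0,
) -> CircuitSelection:
    """Select the top-ranked genes for one circuit, gated by its R2.

    The effective quantile is q = 1 - 0.05 * clip(r2, 0, 1)**gamma, i.e. the
    convex combination of 0.95 and 1.0 weighted by predictability (gamma=1).
    The number of genes kept is floor((1 - q) * n); ties in score are broken
    by gene symbol ascending.
    """
    n = len(genes)
    if n == 0:
        raise ValueError("empty gene ranking")
    if len(scores) != n:
        raise ValueError("scores and genes must have equal length")
    if not math.isfinite(r2):
        raise ValueError(f"circuit {circuit_id!r}: non-finite r2")
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < 0):
        raise ValueError("relevance scores must be non-negative")
    clipped = min(max(r2, 0.0), 1.0)
    fraction = TOP_FRACTION * clipped**gamma
    count = int(math.floor(fraction * n + _EPS))
    order = sorted(range(n), key=lambda i: (-scores[i], genes[i]))
    selected = [genes[i] for i in order[:count]]
    return CircuitSelection(
        circuit_id=circuit_id, r2=float(r2), selected_fraction=fraction,
        selected_kdts=selected,
    )


def select_all(
    gene_ids: list[str],
    circuit_ids: list[str],
    relevance: np.ndarray,
    r2: np.ndarray,
    gamma: float = 1.0,
) -> list[CircuitSelection]:
    """Per-circuit selection from a genes x circuits relevance matrix."""
    relevance = np.asarray(relevance, dtype=float)
    return [
        select_kdts(cid, gene_ids, relevance[:, c], float(r2[c]), gamma=gamma)
        for c, cid in enumerate(circuit_ids)
    ]


@dataclass
class TargetSummary:
    circuits_by_target: dict[str, list[str]]
    pathway_counts: dict[str, int]
    shared_circuits: dict[tuple[str, str], list[str]]

    def circuit_count(self, gene: str) -> int:
        return len(self.circuits_by_target.get(gene, []))


def circuits_per_target(
    selections: list[CircuitSelection],
    kdt_genes: list[str],
    circuit_pathway_map: dict[str, str] | None = None,
) -> TargetSummary:
    """Summarize, per target gene, which circuits selected it.

    Also reports pathway counts (when a circuit-to-pathway map is given) and
    the circuits shared by every pair of targets that co-occur anywhere.
    """
    circuits_by_target: dict[str, list[str]] = {g: [] for g in kdt_genes}
    for sel in selections:
        for g in sel.selected_kdts:
            circuits_by_target.setdefault(g, []).append(sel.circuit_id)
    pathway_counts = {}
    for g, cids in circuits_by_target.items():
        if circuit_pathway_map is None:
            pathway_counts[g] = 0
        else:
            pathway_counts[g] = len({circuit_pathway_map[c] for c in cids})
    shared: dict[tuple[str, str], list[str]] = {}
    for g1, g2 in combinations(sorted(circuits_by_target), 2):
        common = sorted(set(circuits_by_target[g1]) & set(circuits_by_target[g2]))
        if common:
            shared[(g1, g2)] = common
    return TargetSummary(circuits_by_target, pathway_counts, shared)


def selections_to_frame(selections: list[CircuitSelection]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "circuit_id": [s.circuit_id for s in selections],
            "r2": [s.r2 for s in selections],
            "fraction": [s.selected_fraction for s in selections],
            "selected_kdts": [";".join(s.selected_kdts) for s in selections],
        }
    )


def summary_to_frame(summary: TargetSummary) -> pd.DataFrame:
    genes = sorted(summary.circuits_by_target)
    return pd.DataFrame(
        {
            "gene": genes,
            "n_circuits": [summary.circuit_count(g) for g in genes],
            "n_pathways": [summary.pathway_counts[g] for g in genes],
            "circuits": [";".join(sorted(summary.circuits_by_target[g])) for g in genes],
        }
    )
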