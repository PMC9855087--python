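"""Synthetic pathway collections and expression matrices with planted drivers.

Circuits are chain or lightly branched DAGs whose nodes carry driver genes
drawn from the KDT (known-drug-target) list. Decoy KDTs and background genes
sit outside every circuit, so they can influence the response only by
chance: driver recovery through the model is then a genuine test. Driver
genes vary across samples with a variance scaled by the chosen effect size;
all other variation enters through the additive noise term.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .activity import ExpressionMatrix
from .graphio import (
    ACTIVATION,
    INHIBITION,
    Circuit,
    Node,
    Pathway,
    PathwayCollection,
)

EFFECT_MULTIPLIERS = {"strong": 3.0, "moderate": 1.5, "weak": 0.5}

_BASE_SD = 0.4  # cross-sample s.d. of a unit-effect driver gene


@dataclass
class SimulationConfig:
    n_pathways: int = 2
    circuits_per_pathway: int = 3
    chain_length_range: tuple[int, int] = (3, 4)
    n_samples: int = 300
    n_kdts: int = 20
    n_drivers: int = 4
    n_background_genes: int = 10
    driver_effect: str | float = "strong"
    noise_sd: float = 0.05
    branch_prob: float = 0.3
    multi_gene_prob: float = 0.2
    inhibition_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pathways", "circuits_per_pathway", "n_samples", "n_kdts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_drivers < 0 or self.n_background_genes < 0:
            raise ValueError("counts must be non-negative")
        if self.n_drivers > self.n_kdts:
            raise ValueError("n_drivers cannot exceed n_kdts")
        lo, hi = self.chain_length_range
        if lo < 2 or hi < lo:
            raise ValueError("chain_length_range must be (lo >= 2, hi >= lo)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if isinstance(self.driver_effect, str) and self.driver_effect not in EFFECT_MULTIPLIERS:
            raise ValueError(
                f"driver_effect must be one of {sorted(EFFECT_MULTIPLIERS)} or a number"
            )

    @property
    def effect_multiplier(self) -> float:
        if isinstance(self.driver_effect, str):
            return EFFECT_MULTIPLIERS[self.driver_effect]
        return float(self.driver_effect)

    @property
    def kdt_genes(self) -> list[str]:
        return [f"KDT{i + 1:03d}" for i in range(self.n_kdts)]

    @property
    def background_genes(self) -> list[str]:
        return [f"BG{i + 1:03d}" for i in range(self.n_background_genes)]


@dataclass
class SyntheticTruth:
    driver_genes: list[str]
    decoy_genes: list[str]
    driver_circuit_map: dict[str, list[str]]
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _build_circuit(cid: str, length: int, gene_pool: list[str], config: SimulationConfig, rng) -> Circuit:
    """A chain R -> m1 -> ... -> E, optionally with a second receptor branch."""

    def pick_genes() -> list[str]:
        k = 2 if (len(gene_pool) > 1 and rng.random() < config.multi_gene_prob) else 1
        return list(rng.choice(gene_pool, size=k, replace=False))

    node_ids = [f"{cid}.n{i + 1}" for i in range(length)]
    nodes = [Node(nid, pick_genes()) for nid in node_ids]
    edges = []
    for i in range(length - 1):
        sign = ACTIVATION
        # keep the receptor->first and last->effector links activating so a
        # planted signal always has an excitatory route to the effector
        if 0 < i < length - 2 and rng.random() < config.inhibition_prob:
            sign = INHIBITION
        edges.append((node_ids[i], node_ids[i + 1], sign))
    receptors = [node_ids[0]]
    if length >= 4 and rng.random() < config.branch_prob:
        extra = f"{cid}.n{length + 1}"
        nodes.append(Node(extra, pick_genes()))
        edges.append((extra, node_ids[1], ACTIVATION))
        receptors.append(extra)
    return Circuit(
        id=cid, nodes=nodes, edges=edges, receptors=receptors, effector=node_ids[-1]
    )


def generate_pathways(config: SimulationConfig) -> tuple[PathwayCollection, SyntheticTruth]:
    """Deterministically generate a pathway collection with planted drivers."""
    rng = np.random.default_rng([config.seed, 0])
    kdts = config.kdt_genes
    driver_idx = rng.choice(config.n_kdts, size=config.n_drivers, replace=False)
    drivers = [kdts[i] for i in sorted(driver_idx)]
    decoys = [g for g in kdts if g not in drivers]

    gene_pool = drivers if drivers else config.background_genes
    if not gene_pool:
        raise ValueError("no genes available to place in circuit nodes")

    pathways = []
    n_slots = 0
    for p in range(config.n_pathways):
        pid = f"P{p + 1:02d}"
        circuits = []
        for c in range(config.circuits_per_pathway):
            length = int(rng.integers(config.chain_length_range[0], config.chain_length_range[1] + 1))
            circuit = _build_circuit(f"{pid}.C{c + 1:02d}", length, gene_pool, config, rng)
            n_slots += len(circuit.nodes)
            circuits.append(circuit)
        pathways.append(Pathway(id=pid, name=f"synthetic pathway {pid}", circuits=circuits))

    if config.n_drivers > n_slots:
        raise ValueError(
            f"infeasible config: {config.n_drivers} drivers but only {n_slots} node slots"
        )

    collection = PathwayCollection(pathways)
    # guarantee every driver occupies at least one node (append, never evict)
    placed = {g for c in collection.circuits for g in c.genes}
    unplaced = [g for g in drivers if g not in placed]
    if unplaced:
        all_nodes = [n for c in collection.circuits for n in c.nodes]
        slots = rng.choice(len(all_nodes), size=len(unplaced), replace=False)
        for g, s in zip(unplaced, slots):
            all_nodes[int(s)].genes.append(g)
    collection.validate()

    driver_circuit_map = {
        g: sorted(c.id for c in collection.circuits if g in c.genes) for g in drivers
    }
    echoed = dataclasses.asdict(config)
    echoed["chain_length_range"] = list(echoed["chain_length_range"])  # JSON-stable
    truth = SyntheticTruth(
        driver_genes=drivers,
        decoy_genes=decoys,
        driver_circuit_map=driver_circuit_map,
        config=echoed,
    )
    return collection, truth


def generate_expression(
    collection: PathwayCollection, truth: SyntheticTruth, config: SimulationConfig
) -> ExpressionMatrix:
    """Raw (pre-normalization) expression with planted driver variance.

    Driver genes: per-gene mean in [2, 8], s.d. = 0.4 * effect multiplier.
    Decoy KDTs and background genes: same means, fixed baseline values whose
    only cross-sample variation is the additive noise term. Values are
    truncated at zero.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = config.kdt_genes + config.background_genes
    drivers = set(truth.driver_genes)
    n = config.n_samples
    mult = config.effect_multiplier

    cols = []
    for g in genes:
        mu = rng.uniform(2.0, 8.0)
        if g in drivers:
            col = mu + rng.normal(0.0, _BASE_SD * mult, size=n)
        else:
            col = np.full(n, mu)
        cols.append(col)
    values = np.column_stack(cols)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    return ExpressionMatrix(sample_ids, genes, values)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[PathwayCollection, SyntheticTruth, ExpressionMatrix]:
    """Convenience wrapper: pathways + truth + raw expression from one config."""
    collection, truth = generate_pathways(config)
    expr = generate_expression(collection, truth, config)
    return collection, truth, expr
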