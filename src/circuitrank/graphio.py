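"""Data model and I/O for pathway collections of receptor→effector circuits.

A :class:`Circuit` is a directed acyclic signed graph with one or more
receptor nodes (in-degree 0) and a single effector node (out-degree 0).
Each node carries one or more gene symbols. Collections are serialized to a
small JSON schema; single circuits can also be imported from SIF files with
a sidecar table declaring receptor/effector roles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

ACTIVATION = "activation"
INHIBITION = "inhibition"
EDGE_SIGNS = (ACTIVATION, INHIBITION)


class PathwayParseError(ValueError):
    """Raised when an input file does not conform to the expected schema."""


class GraphValidationError(ValueError):
    """Raised when a circuit or collection violates a structural invariant."""


@dataclass
class Node:
    id: str
    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = list(self.genes)


@dataclass
class Circuit:
    id: str
    nodes: list[Node]
    edges: list[tuple[str, str, str]]
    receptors: list[str]
    effector: str

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        self.edges = [tuple(e) for e in self.edges]
        self.receptors = list(self.receptors)

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    @property
    def genes(self) -> list[str]:
        """All gene symbols in the circuit, deduplicated, insertion order."""
        seen: dict[str, None] = {}
        for node in self.nodes:
            for g in node.genes:
                seen.setdefault(g)
        return list(seen)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        for src, dst, sign in self.edges:
            g.add_edge(src, dst, sign=sign)
        return g

    def validate(self) -> None:
        ids = self.node_ids
        if len(set(ids)) != len(ids):
            raise GraphValidationError(f"circuit {self.id!r}: duplicate node ids")
        for node in self.nodes:
            if not node.genes:
                raise GraphValidationError(
                    f"circuit {self.id!r}: node {node.id!r} has an empty gene list"
                )
        known = set(ids)
        for src, dst, sign in self.edges:
            if src not in known or dst not in known:
                raise GraphValidationError(
                    f"circuit {self.id!r}: edge ({src!r}, {dst!r}) references unknown node"
                )
            if sign not in EDGE_SIGNS:
                raise GraphValidationError(
                    f"circuit {self.id!r}: invalid edge sign {sign!r}"
                )
        if not self.receptors:
            raise GraphValidationError(f"circuit {self.id!r}: no receptor nodes")
        for r in self.receptors:
            if r not in known:
                raise GraphValidationError(
                    f"circuit {self.id!r}: receptor {r!r} is not a node"
                )
        if self.effector not in known:
            raise GraphValidationError(
                f"circuit {self.id!r}: effector {self.effector!r} is not a node"
            )

        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise GraphValidationError(f"circuit {self.id!r}: graph contains a cycle")
        for r in self.receptors:
            if g.in_degree(r) != 0:
                raise GraphValidationError(
                    f"circuit {self.id!r}: receptor {r!r} has incoming edges"
                )
        if g.out_degree(self.effector) != 0:
            raise GraphValidationError(
                f"circuit {self.id!r}: effector {self.effector!r} has outgoing edges"
            )
        reachable: set[str] = set()
        for r in self.receptors:
            descendants = nx.descendants(g, r) | {r}
            reachable |= descendants
            if self.effector not in descendants:
                raise GraphValidationError(
                    f"circuit {self.id!r}: effector not reachable from receptor {r!r}"
                )
        missing = known - reachable
        if missing:
            raise GraphValidationError(
                f"circuit {self.id!r}: nodes unreachable from any receptor: "
                f"{sorted(missing)}"
            )


@dataclass
class Pathway:
    id: str
    name: str
    circuits: list[Circuit] = field(default_factory=list)


@dataclass
class PathwayCollection:
    pathways: list[Pathway] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def circuits(self) -> list[Circuit]:
        return [c for p in self.pathways for c in p.circuits]

    @property
    def circuit_ids(self) -> list[str]:
        return [c.id for c in self.circuits]

    def circuit_pathway_map(self) -> dict[str, str]:
        return {c.id: p.id for p in self.pathways for c in p.circuits}

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.circuits:
            for g in c.genes:
                seen.setdefault(g)
        return list(seen)

    def validate(self) -> None:
        pids = [p.id for p in self.pathways]
        if len(set(pids)) != len(pids):
            raise GraphValidationError("duplicate pathway ids in collection")
        cids = self.circuit_ids
        if len(set(cids)) != len(cids):
            raise GraphValidationError("duplicate circuit ids in collection")
        for c in self.circuits:
            c.validate()


# ---------------------------------------------------------------------------
# JSON serialization


def _circuit_to_dict(c: Circuit) -> dict:
    return {
        "id": c.id,
        "nodes": [{"id": n.id, "genes": list(n.genes)} for n in c.nodes],
        "edges": [list(e) for e in c.edges],
        "receptors": list(c.receptors),
        "effector": c.effector,
    }


def _circuit_from_dict(d: dict) -> Circuit:
    try:
        return Circuit(
            id=d["id"],
            nodes=[Node(n["id"], n["genes"]) for n in d["nodes"]],
            edges=[(e[0], e[1], e[2]) for e in d["edges"]],
            receptors=d["receptors"],
            effector=d["effector"],
        )
    except (KeyError, IndexError, TypeError) as exc:
        raise PathwayParseError(f"malformed circuit record {d.get('id', d)!r}: {exc}")


def write_pathways(collection: PathwayCollection, path: str | Path) -> None:
    """Serialize a collection to JSON; ``read_pathways`` inverts this."""
    payload = {
        "pathways": [
            {
                "id": p.id,
                "name": p.name,
                "circuits": [_circuit_to_dict(c) for c in p.circuits],
            }
            for p in collection.pathways
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_pathways(path: str | Path, format: str = "json", sidecar: str | Path | None = None) -> PathwayCollection:
    """Read and validate a pathway collection.

    Parameters
    ----------
    path:
        JSON collection file, or a SIF edge list when ``format="sif"``.
    format:
        ``"json"`` (default) or ``"sif"``.
    sidecar:
        For SIF input, a mandatory TSV declaring receptor/effector node roles
        (lines ``receptor<TAB>node`` / ``effector<TAB>node``, optionally
        ``circuit<TAB>id`` and ``pathway<TAB>id``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "json":
        return _read_json(path)
    if format == "sif":
        if sidecar is None:
            raise PathwayParseError("SIF import requires a sidecar role table")
        return _read_sif(path, Path(sidecar))
    raise ValueError(f"unknown format {format!r}")


def _read_json(path: Path) -> PathwayCollection:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise PathwayParseError(f"{path}: invalid JSON: {exc}")
    if not isinstance(payload, dict) or "pathways" not in payload:
        raise PathwayParseError(f"{path}: top-level object must contain 'pathways'")
    pathways = []
    for p in payload["pathways"]:
        try:
            pathways.append(
                Pathway(
                    id=p["id"],
                    name=p.get("name", p["id"]),
                    circuits=[_circuit_from_dict(c) for c in p.get("circuits", [])],
                )
            )
        except (KeyError, TypeError) as exc:
            raise PathwayParseError(f"{path}: malformed pathway record: {exc}")
    return PathwayCollection(pathways)


def _read_sif(path: Path, sidecar: Path) -> PathwayCollection:
    edges: list[tuple[str, str, str]] = []
    node_ids: dict[str, None] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise PathwayParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
        src, relation, dst = parts
        if relation not in EDGE_SIGNS:
            raise PathwayParseError(
                f"{path}:{lineno}: relation must be one of {EDGE_SIGNS}, got {relation!r}"
            )
        edges.append((src, dst, relation))
        node_ids.setdefault(src)
        node_ids.setdefault(dst)

    receptors: list[str] = []
    effectors: list[str] = []
    circuit_id = path.stem
    pathway_id = path.stem
    for lineno, line in enumerate(sidecar.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise PathwayParseError(f"{sidecar}:{lineno}: expected 2 tab-separated fields")
        kind, value = parts
        if kind == "receptor":
            receptors.append(value)
        elif kind == "effector":
            effectors.append(value)
        elif kind == "circuit":
            circuit_id = value
        elif kind == "pathway":
            pathway_id = value
        else:
            raise PathwayParseError(f"{sidecar}:{lineno}: unknown role {kind!r}")
    if len(effectors) != 1:
        raise PathwayParseError(f"{sidecar}: exactly one effector required")

    # SIF carries no gene bundling: node id doubles as the gene symbol.
    circuit = Circuit(
        id=circuit_id,
        nodes=[Node(i, [i]) for i in node_ids],
        edges=edges,
        receptors=receptors,
        effector=effectors[0],
    )
    return PathwayCollection([Pathway(id=pathway_id, name=pathway_id, circuits=[circuit])])


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one symbol per line, '#' comments allowed."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    if len(set(genes)) != len(genes):
        raise PathwayParseError(f"{path}: duplicate gene symbols")
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
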