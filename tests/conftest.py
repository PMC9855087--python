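import numpy as np
import pytest

from circuitrank.graphio import (
    ACTIVATION,
    INHIBITION,
    Circuit,
    Node,
    Pathway,
    PathwayCollection,
)


def make_chain(cid="c1", genes=("g1", "g2", "g3"), signs=None):
    """A simple receptor -> ... -> effector chain, one gene per node."""
    n = len(genes)
    nodes = [Node(f"{cid}.n{i}", [g]) for i, g in enumerate(genes, start=1)]
    if signs is None:
        signs = [ACTIVATION] * (n - 1)
    edges = [
        (nodes[i].id, nodes[i + 1].id, signs[i]) for i in range(n - 1)
    ]
    return Circuit(
        id=cid, nodes=nodes, edges=edges,
        receptors=[nodes[0].id], effector=nodes[-1].id,
    )


def random_activation_circuit(rng, n_nodes=None, cid="rc"):
    """Random all-activation DAG circuit: a chain plus random forward edges."""
    if n_nodes is None:
        n_nodes = int(rng.integers(3, 8))
    nodes = [Node(f"{cid}.n{i}", [f"{cid}.g{i}"]) for i in range(n_nodes)]
    edges = [(nodes[i].id, nodes[i + 1].id, ACTIVATION) for i in range(n_nodes - 1)]
    for i in range(n_nodes - 2):
        for j in range(i + 2, n_nodes):
            if rng.random() < 0.25:
                edges.append((nodes[i].id, nodes[j].id, ACTIVATION))
    return Circuit(
        id=cid, nodes=nodes, edges=edges,
        receptors=[nodes[0].id], effector=nodes[-1].id,
    )


def add_inhibitor(circuit, target_node_id, cid_suffix="inh"):
    """Attach an extra receptor node with a single inhibition edge."""
    inh = Node(f"{circuit.id}.{cid_suffix}", [f"{circuit.id}.g_{cid_suffix}"])
    return Circuit(
        id=circuit.id,
        nodes=circuit.nodes + [inh],
        edges=circuit.edges + [(inh.id, target_node_id, INHIBITION)],
        receptors=circuit.receptors + [inh.id],
        effector=circuit.effector,
    ), inh.id


@pytest.fixture
def chain_collection():
    c1 = make_chain("c1", ("g1", "g2", "g3"))
    c2 = make_chain("c2", ("g4", "g5"))
    return PathwayCollection([Pathway("p1", "pathway one", [c1, c2])])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
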