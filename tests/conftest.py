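import networkx as nx
import numpy as np
import pandas as pd
import pytest

from methanonet.network import CooccurrenceNetwork, OtuTable


def make_table(counts: np.ndarray, lineages=None, methanogens=()):
    """OtuTable from a raw samples x OTUs array with default labels."""
    n, p = counts.shape
    otus = [f"OTU{j}" for j in range(p)]
    frame = pd.DataFrame(np.asarray(counts, dtype=np.int64),
                         index=[f"S{i}" for i in range(n)], columns=otus)
    lineages = lineages or {o: "L0" for o in otus}
    return OtuTable(counts=frame, lineage_map=lineages,
                    methanogen_lineages=frozenset(methanogens))


def make_network(node_lineages: dict, edges) -> CooccurrenceNetwork:
    """Hand-built network: {node: lineage} plus an edge list."""
    g = nx.Graph()
    for node, lin in node_lineages.items():
        g.add_node(node, lineage=lin)
    for u, v in edges:
        g.add_edge(u, v, rho=0.9, p=1e-6, q=1e-4)
    return CooccurrenceNetwork(graph=g)


@pytest.fixture
def cross_block_network():
    """4 methanogen + 4 partner nodes, edges = all 16 cross pairs:
    the worked O/R example (expected 64/7, ratio 1.75)."""
    lineages = {f"M{i}": "meth" for i in range(4)}
    lineages.update({f"X{i}": "lineage_x" for i in range(4)})
    edges = [(f"M{i}", f"X{j}") for i in range(4) for j in range(4)]
    return make_network(lineages, edges)
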