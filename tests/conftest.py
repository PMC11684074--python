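"""Shared fixtures and independent oracles for the test suite."""

import itertools
import math

import networkx as nx
import pytest


@pytest.fixture
def path4():
    return nx.path_graph(["A", "B", "C", "D"])


@pytest.fixture
def triangle():
    return nx.complete_graph(["A", "B", "C"])


@pytest.fixture
def rab_effector_graph():
    """Two Rab GTPases sharing two effectors: the worked CPL example.

    RAB19 and RAB6A do not interact directly but both bind the golgins
    GOLGA1 and GCC1, so their shortest path crosses exactly one
    intermediate node.
    """
    g = nx.Graph()
    g.add_edges_from(
        [
            ("RAB19", "GOLGA1"),
            ("RAB19", "GCC1"),
            ("RAB6A", "GOLGA1"),
            ("RAB6A", "GCC1"),
            ("GOLGA1", "GCC1"),
        ]
    )
    return g


def exhaustive_mean_entropy(net: nx.Graph, f: float) -> float:
    """Oracle: exact expected entropy over all C(N, k) removal sets.

    Entirely independent of the package: components via networkx on the
    node-removed subgraph, entropy from the definition with removed nodes
    as singletons and a base-N logarithm.
    """
    nodes = list(net.nodes)
    n = len(nodes)
    k = int(math.floor(f * n + 0.5))
    if k == 0:
        sizes = [len(c) for c in nx.connected_components(net)]
        return _entropy(sizes, n)
    if k >= n:
        return 1.0
    total = 0.0
    count = 0
    for removed in itertools.combinations(nodes, k):
        sub = net.copy()
        sub.remove_nodes_from(removed)
        sizes = [len(c) for c in nx.connected_components(sub)] + [1] * k
        total += _entropy(sizes, n)
        count += 1
    return total / count


def _entropy(sizes, n):
    h = 0.0
    for c in sizes:
        p = c / n
        h -= p * math.log(p, n)
    return h
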