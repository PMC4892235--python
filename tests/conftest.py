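"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: patristic
distances come from Dijkstra on an explicit edge graph (networkx), and
null-distribution moments come from exhaustive enumeration of every
possible tip draw.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from morphaudit import read_newick
from morphaudit.tree_io import DistanceMatrix

T4_NEWICK = "((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);"


@pytest.fixture
def t4():
    """Minimal balanced 4-tip tree with two cherries (A,B) and (C,D)."""
    return read_newick(T4_NEWICK)


def brute_force_patristic(tree) -> DistanceMatrix:
    """All-pairs path-length oracle: Dijkstra over the explicit edge graph."""
    g = nx.Graph()
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        g.add_edge(id(edge.tail_node), id(edge.head_node), weight=edge.length or 0.0)
    leaves = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
    labels = tuple(sorted(leaves))
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = nx.dijkstra_path_length(g, leaves[labels[i]], leaves[labels[j]])
    return DistanceMatrix(labels, d)


def metric_brute(dm: DistanceMatrix, focal, metric: str) -> float:
    """MPD/MNTD by direct pair enumeration, independent of the numpy path."""
    focal = sorted(focal)
    if metric == "MPD":
        pairs = list(itertools.combinations(focal, 2))
        return sum(dm.distance(a, b) for a, b in pairs) / len(pairs)
    return float(np.mean([min(dm.distance(a, b) for b in focal if b != a) for a in focal]))


def exhaustive_null(dm: DistanceMatrix, n: int, metric: str) -> np.ndarray:
    """Metric values over every possible draw of n tips (the exact null)."""
    return np.array([metric_brute(dm, subset, metric)
                     for subset in itertools.combinations(dm.labels, n)])
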