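"""Independent brute-force d-separation oracle for small DAGs.

Enumerates every simple path between the two node sets in the skeleton and
applies the blocking rules directly: a chain or fork node blocks when
conditioned on; a collider blocks unless it or one of its descendants is
conditioned on.  Exponential in graph size — test-only, for graphs of at most
~8 nodes — and deliberately independent of the reachability-based production
implementation.
"""

from itertools import product

import networkx as nx


def _descendants(g: nx.DiGraph, node) -> set:
    return nx.descendants(g, node) | {node}


def _path_blocked(g: nx.DiGraph, path: list, z: set) -> bool:
    """Is this skeleton path blocked given conditioning set z?"""
    for i in range(1, len(path) - 1):
        prev_node, node, next_node = path[i - 1], path[i], path[i + 1]
        into_left = g.has_edge(prev_node, node)
        into_right = g.has_edge(next_node, node)
        is_collider = into_left and into_right
        if is_collider:
            if not (_descendants(g, node) & z):
                return True
        else:
            if node in z:
                return True
    return False


def brute_force_d_separated(g: nx.DiGraph, x, y, z) -> bool:
    """True iff every simple path between x and y is blocked given z."""
    x, y, z = set(x), set(y), set(z)
    skeleton = g.to_undirected()
    for source, sink in product(x, y):
        if source == sink:
            return False
        if source not in skeleton or sink not in skeleton:
            continue
        for path in nx.all_simple_paths(skeleton, source, sink):
            if any(p in z for p in (path[0], path[-1])):
                continue
            if not _path_blocked(g, path, z):
                return False
    return True


def random_dag(rng, n_nodes: int, p_edge: float = 0.4) -> nx.DiGraph:
    """Random DAG over labeled nodes, edges oriented along a random order."""
    labels = [f"V{i}" for i in range(n_nodes)]
    order = list(rng.permutation(labels))
    g = nx.DiGraph()
    g.add_nodes_from(labels)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(order[i], order[j])
    return g
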