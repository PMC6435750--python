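"""Graph-based oracles for tree tests, independent of the package's tree code.

Monophyly is re-derived by deleting each edge of the tree graph and checking
connected components (networkx); additive distances come from weighted
shortest paths on randomly grown unrooted binary trees.
"""

import networkx as nx
import numpy as np
import pandas as pd


def random_topology_newick(rng: np.random.Generator, n_leaves: int, with_supports=False):
    """A random rooted-binary newick over leaves L1..Ln, optional int supports."""
    names = [f"L{i}" for i in range(1, n_leaves + 1)]
    order = list(names)
    rng.shuffle(order)

    def build(leaves):
        if len(leaves) == 1:
            return leaves[0]
        k = int(rng.integers(1, len(leaves)))
        label = str(int(rng.integers(0, 101))) if with_supports else ""
        return f"({build(leaves[:k])},{build(leaves[k:])}){label}"

    return f"{build(order)};", names


def tree_graph(stree):
    """networkx view of a SupportedTree: (graph, node-id -> leaf-name map)."""
    g = nx.Graph()
    leaf_of = {}
    for node in stree.tree.preorder_node_iter():
        if node.is_leaf():
            leaf_of[id(node)] = node.taxon.label
        if node.parent_node is not None:
            length = node.edge.length if node.edge.length is not None else 1.0
            g.add_edge(id(node.parent_node), id(node), length=length)
    return g, leaf_of


def monophyly_bruteforce(stree, members) -> bool:
    """Members form a clade iff deleting some edge isolates exactly them."""
    members = frozenset(members)
    g, leaf_of = tree_graph(stree)
    for u, v in list(g.edges):
        g.remove_edge(u, v)
        for comp in nx.connected_components(g):
            leaves = frozenset(leaf_of[n] for n in comp if n in leaf_of)
            if leaves == members:
                g.add_edge(u, v)
                return True
        g.add_edge(u, v)
    return False


def random_tree_graph(rng: np.random.Generator, n_leaves: int):
    """Grow a random unrooted binary tree with branch lengths in [0.5, 2].

    Returns (graph, leaf names). Internal nodes are negative ints.
    """
    g = nx.Graph()
    leaves = [f"T{i}" for i in range(1, n_leaves + 1)]
    g.add_edge(-1, leaves[0])
    g.add_edge(-1, leaves[1])
    g.add_edge(-1, leaves[2])
    next_internal = -2
    for leaf in leaves[3:]:
        edges = list(g.edges)
        u, v = edges[int(rng.integers(len(edges)))]
        g.remove_edge(u, v)
        w = next_internal
        next_internal -= 1
        g.add_edge(u, w)
        g.add_edge(w, v)
        g.add_edge(w, leaf)
    for u, v in g.edges:
        g.edges[u, v]["length"] = float(rng.uniform(0.5, 2.0))
    return g, leaves


def graph_distance_matrix(g, leaves) -> pd.DataFrame:
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    data = [[0.0 if a == b else dist[a][b] for b in leaves] for a in leaves]
    return pd.DataFrame(data, index=leaves, columns=leaves)


def _canonical(split, all_leaves):
    other = frozenset(all_leaves) - split
    return min(tuple(sorted(split)), tuple(sorted(other)))


def graph_splits(g, leaves):
    """Non-trivial bipartitions of an unrooted tree graph."""
    all_leaves = frozenset(leaves)
    splits = set()
    for u, v in list(g.edges):
        g.remove_edge(u, v)
        comp = next(c for c in nx.connected_components(g) if u in c)
        g.add_edge(u, v)
        side = frozenset(n for n in comp if n in all_leaves)
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(_canonical(side, all_leaves))
    return splits


def supported_tree_splits(stree):
    all_leaves = frozenset(stree.leaf_names)
    splits = set()
    for _node, below in stree._edge_bipartitions():
        if 1 < len(below) < len(all_leaves) - 1:
            splits.add(_canonical(below, all_leaves))
    return splits
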