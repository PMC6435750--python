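"""Dual-tree clade criteria and a minimal neighbor-joining builder.

A clade, under the criteria applied here, must (i) be monophyletic in the
ML tree, (ii) be monophyletic in the Bayesian tree, and (iii) have ML
bootstrap support strictly greater than a floor (default 70%) on its
defining edge. Monophyly is defined on unrooted trees via bipartitions:
a leaf set is monophyletic iff some edge separates exactly that set from
all remaining leaves.

The NJ builder exists so the criteria are testable end-to-end without
external ML/Bayesian software; it is a standard saitou-nei implementation
with deterministic tie-breaking, not a phylogenetic inference tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

SUPPORT_SCALES = ("percent", "probability")


@dataclass
class SupportedTree:
    """An (effectively unrooted) phylogeny with optional edge supports.

    ``scale`` declares the interpretation of support numbers: ``"percent"``
    for ML bootstrap (0-100) or ``"probability"`` for Bayesian posteriors
    (0-1). Supports live on internal nodes of the underlying dendropy tree,
    i.e. on the edge above each node.
    """

    tree: dendropy.Tree
    scale: str = "percent"

    def __post_init__(self) -> None:
        if self.scale not in SUPPORT_SCALES:
            raise ValueError(f"scale must be one of {SUPPORT_SCALES}, got {self.scale!r}")
        names = self.leaf_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names in tree")

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, scale: str = "percent") -> "SupportedTree":
        # internal-node newick labels become numeric supports where they parse
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            support = None
            if node.label is not None:
                try:
                    support = float(node.label)
                except ValueError:
                    support = None
            node.support = support
        return cls(tree, scale)

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    # -- bipartitions ------------------------------------------------------

    def _edge_bipartitions(self):
        """Yield (node, frozenset of leaf names below the node's edge).

        Every edge of the unrooted tree appears (the root edge set yields
        complementary duplicates, which is harmless for membership tests).
        """
        for node in self.tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            yield node, leaves


def is_monophyletic(tree: SupportedTree, members: Iterable[str]):
    """Test whether ``members`` form a clade on the unrooted tree.

    Returns ``(flag, node)`` where ``node`` heads the defining edge (its
    subtree side equals ``members`` or their complement), or ``None``.
    """
    members = frozenset(members)
    all_leaves = frozenset(tree.leaf_names)
    unknown = members - all_leaves
    if unknown:
        raise KeyError(f"leaves not in tree: {sorted(unknown)}")
    if not members:
        raise ValueError("empty member set")
    if members == all_leaves:
        raise ValueError("monophyly of the full leaf set is undefined on an unrooted tree")
    complement = all_leaves - members
    for node, below in tree._edge_bipartitions():
        if below == members or below == complement:
            return True, node
    return False, None


def clade_support(tree: SupportedTree, members: Iterable[str]):
    """Support value stored on the defining edge of a monophyletic group.

    Returns ``None`` when the tree stores no support there (e.g. a leaf
    edge, or an unannotated internal edge). Raises if the members are not
    monophyletic.
    """
    mono, _ = is_monophyletic(tree, members)
    if not mono:
        raise ValueError("members are not monophyletic; support undefined")
    members = frozenset(members)
    complement = frozenset(tree.leaf_names) - members
    # a rooted-binary representation can expose the same bipartition on two
    # root edges; prefer the node subtending the members themselves, then
    # fall back to an annotated complement-side node
    direct, mirror = [], []
    for node, below in tree._edge_bipartitions():
        if below == members:
            direct.append(getattr(node, "support", None))
        elif below == complement:
            mirror.append(getattr(node, "support", None))
    for s in direct + mirror:
        if s is not None:
            return s
    return None


@dataclass(frozen=True)
class CladeVerdict:
    """Evaluation of one candidate clade against the dual-tree criteria."""

    clade: str
    monophyletic_ml: bool
    monophyletic_bayes: bool
    support_ml: float | None
    support_bayes: float | None
    passes: bool


def evaluate_clade(
    tree_ml: SupportedTree,
    tree_bayes: SupportedTree,
    members: Iterable[str],
    clade_name: str = "clade",
    min_bootstrap: float = 70.0,
    min_posterior: float | None = None,
) -> CladeVerdict:
    """Apply the clade criteria: dual monophyly + ML bootstrap > ``min_bootstrap``.

    The bootstrap floor is strict (a support of exactly 70 fails at the
    default) and applies to the ML tree only; the Bayesian tree contributes
    the monophyly requirement, plus an optional posterior floor
    (``min_posterior``, off by default).
    """
    members = frozenset(members)
    for name, tree in (("ml", tree_ml), ("bayes", tree_bayes)):
        missing = members - frozenset(tree.leaf_names)
        if missing:
            raise KeyError(f"members missing from {name} tree: {sorted(missing)}")
    mono_ml, _ = is_monophyletic(tree_ml, members)
    mono_bayes, _ = is_monophyletic(tree_bayes, members)
    support_ml = clade_support(tree_ml, members) if mono_ml else None
    support_bayes = clade_support(tree_bayes, members) if mono_bayes else None
    passes = (
        mono_ml
        and mono_bayes
        and support_ml is not None
        and support_ml > min_bootstrap
    )
    if passes and min_posterior is not None:
        passes = support_bayes is not None and support_bayes >= min_posterior
    return CladeVerdict(clade_name, mono_ml, mono_bayes, support_ml, support_bayes, passes)


def verdicts_to_frame(verdicts: Sequence[CladeVerdict]) -> pd.DataFrame:
    return pd.DataFrame([v.__dict__ for v in verdicts]).set_index("clade")


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(distances: pd.DataFrame) -> SupportedTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    On additive distances the reconstructed tree's path lengths reproduce
    the input exactly. Q-matrix ties are broken by the lexicographically
    smallest pair of cluster representative labels (the smallest leaf label
    within each cluster), so the result is deterministic. The returned tree
    is unrooted (trifurcating seed node) with branch lengths and no supports.
    """
    labels = list(distances.index)
    if list(distances.columns) != labels:
        raise ValueError("distance matrix rows and columns must match")
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = distances.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix diagonal must be zero")

    taxon_namespace = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    nodes: list[dendropy.Node] = []
    reps: list[str] = []  # representative (smallest) leaf label per cluster
    for lab in labels:
        node = dendropy.Node(taxon=taxon_namespace.get_taxon(lab))
        nodes.append(node)
        reps.append(lab)
    d = d.copy()
    active = list(range(len(labels)))

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (n - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic tie-break on representative labels
        candidates = [
            (tuple(sorted((reps[active[i]], reps[active[j]]))), i, j)
            for i, j in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12)))
            if i < j
        ]
        _, ii, jj = min(candidates)
        a, b = active[ii], active[jj]
        dist_ab = d[a, b]
        la = 0.5 * dist_ab + (totals[ii] - totals[jj]) / (2 * (n - 2))
        lb = dist_ab - la
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = la
        parent.add_child(nodes[b])
        nodes[b].edge.length = lb
        # distances from the new node to the remaining clusters
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (a, b):
                continue
            new_row[k] = 0.5 * (d[a, k] + d[b, k] - dist_ab)
        nodes[a] = parent  # reuse slot a for the merged cluster
        reps[a] = min(reps[a], reps[b])
        d[a, :] = new_row
        d[:, a] = new_row
        active.remove(b)

    # terminal trifurcation
    a, b, c = active
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = tree.seed_node
    for idx, length in ((a, va), (b, vb), (c, vc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = length
    tree.is_rooted = False
    out = SupportedTree(tree, scale="percent")
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.support = None
    return out


def path_length_matrix(tree: SupportedTree) -> pd.DataFrame:
    """Leaf-to-leaf path lengths of a tree with branch lengths."""
    pdm = tree.tree.phylogenetic_distance_matrix()
    names = sorted(tree.leaf_names)
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    data = [
        [0.0 if i == j else pdm.patristic_distance(taxa[i], taxa[j]) for j in names]
        for i in names
    ]
    return pd.DataFrame(data, index=names, columns=names)
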