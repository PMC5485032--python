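"""Small shared helpers for working with dendropy trees.

Edges are identified by their child node: a leaf edge by the leaf's taxon
label, an internal edge by the internal node's label (assigned in preorder
by :func:`label_internal_nodes`). The edge above the root is the "root edge".
"""

from __future__ import annotations

from typing import Iterable

import dendropy
import numpy as np


def leaf_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label  # pragma: no cover - leaves normally carry taxa


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "n") -> None:
    """Assign deterministic preorder labels to unlabeled internal nodes."""
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.label is None:
            node.label = f"{prefix}{counter}"
        counter += 1


def edge_id(node: dendropy.Node) -> str:
    """Name of the edge subtending ``node`` (= the child node's name)."""
    if node.is_leaf():
        return leaf_label(node)
    if node.label is None:
        raise ValueError("internal node has no label; call label_internal_nodes first")
    return node.label


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [leaf_label(lf) for lf in tree.leaf_node_iter()]


def leafsets_below(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    """Postorder map node → frozenset of leaf names in its subtree."""
    below: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([leaf_label(node)])
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= below[child]
            below[node] = frozenset(acc)
    return below


def mrca(tree: dendropy.Tree, leaves: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of the named leaves (the leaf itself for
    a single name)."""
    wanted = frozenset(leaves)
    if not wanted:
        raise ValueError("empty leaf set has no MRCA")
    below = leafsets_below(tree)
    missing = wanted - below[tree.seed_node]
    if missing:
        raise ValueError(f"leaf name(s) not in tree: {sorted(missing)}")
    node = tree.seed_node
    while True:
        nxt = None
        for child in node.child_nodes():
            if wanted <= below[child]:
                nxt = child
                break
        if nxt is None:
            return node
        node = nxt


def require_rooted(tree: dendropy.Tree) -> None:
    """Reject trees whose root is an unresolved (>2-child) basal polytomy.

    A basal trifurcation is the standard serialization of an unrooted tree;
    gain placement depends on the root, so such inputs are refused rather
    than auto-rooted.
    """
    if len(tree.seed_node.child_nodes()) != 2:
        raise ValueError(
            "tree root is not bifurcating; supply an explicitly rooted tree"
        )


def random_binary_tree(
    names: list[str],
    rng: np.random.Generator,
    mean_branch_length: float = 0.1,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Random rooted binary tree over ``names`` built by sequential joining.

    Branch lengths are exponential with the given mean; deterministic for a
    fixed generator state.
    """
    if len(names) < 2:
        raise ValueError("need at least two leaves")
    tns = taxon_namespace or dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    for name in names:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=name)
        node.edge.length = float(rng.exponential(mean_branch_length))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(mean_branch_length))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.support = None
    return tree


def subtree_leaves(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf_label(lf) for lf in node.leaf_iter())
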