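"""Dollo-parsimony reconstruction of gene-family gains and losses.

Under Dollo parsimony a family arises exactly once and may only be lost
thereafter. For a binary presence row the minimal-event history places the
gain on the edge subtending the most recent common ancestor of the present
leaves, with one loss on each maximal subtree of that clade containing no
present leaf. Placing the gain any higher adds at least one loss while
removing none, so the MRCA placement is the unique event-count minimizer;
the loss set is unique because maximal absent subtrees are.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .trees import edge_id, label_internal_nodes, leaf_label, mrca, require_rooted


@dataclass(frozen=True)
class DolloReconstruction:
    family_id: str
    gain_edge: str
    loss_edges: frozenset[str]
    presence: frozenset[str]

    @property
    def n_events(self) -> int:
        return 1 + len(self.loss_edges)


def dollo_reconstruct(
    tree: dendropy.Tree,
    presence: Iterable[str],
    family_id: str = "",
) -> DolloReconstruction:
    """Minimal single-gain history explaining one presence row.

    The tree must be explicitly rooted (basal bifurcation); leaf names must
    match the tree; an all-absent row is rejected. Edges are named by their
    child node (internal nodes are labeled in preorder if unlabeled).
    """
    require_rooted(tree)
    label_internal_nodes(tree)
    present = frozenset(presence)
    if not present:
        raise ValueError("all-absent row: a family must be present somewhere")
    leaves = {leaf_label(lf) for lf in tree.leaf_node_iter()}
    unknown = present - leaves
    if unknown:
        raise ValueError(f"unknown leaf name(s): {sorted(unknown)}")

    gain_node = mrca(tree, present)
    losses: set[str] = set()

    def has_present(node: dendropy.Node) -> bool:
        if node.is_leaf():
            return leaf_label(node) in present
        return any(has_present(c) for c in node.child_nodes())

    def walk(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            if has_present(child):
                walk(child)
            else:
                losses.add(edge_id(child))

    walk(gain_node)
    return DolloReconstruction(
        family_id=family_id,
        gain_edge=edge_id(gain_node),
        loss_edges=frozenset(losses),
        presence=present,
    )


def implied_leaf_states(
    tree: dendropy.Tree, reconstruction: DolloReconstruction
) -> frozenset[str]:
    """Leaf presence implied by a reconstruction (for consistency checks)."""
    label_internal_nodes(tree)
    target = reconstruction.gain_edge
    gain_node = None
    for node in tree.preorder_node_iter():
        if edge_id(node) == target:
            gain_node = node
            break
    if gain_node is None:
        raise ValueError(f"gain edge {target!r} not found on tree")
    present: set[str] = set()

    def walk(node: dendropy.Node) -> None:
        if edge_id(node) in reconstruction.loss_edges and node is not gain_node:
            return
        if node.is_leaf():
            present.add(leaf_label(node))
            return
        for child in node.child_nodes():
            walk(child)

    walk(gain_node)
    return frozenset(present)


def reconstruct_matrix(
    tree: dendropy.Tree, matrix: pd.DataFrame
) -> list[DolloReconstruction]:
    """Reconstruct every row of a presence/absence matrix on one tree."""
    leaves = sorted(leaf_label(lf) for lf in tree.leaf_node_iter())
    if sorted(matrix.columns) != leaves:
        raise ValueError("matrix columns do not match the tree's leaf set")
    recons = []
    for family_id, row in matrix.iterrows():
        present = [sp for sp in matrix.columns if row[sp] == 1]
        recons.append(dollo_reconstruct(tree, present, family_id=str(family_id)))
    return recons


@dataclass
class EventTable:
    """Per-edge gain/loss totals plus per-species orphan-family counts."""

    per_edge: pd.DataFrame  # index: edge (child-node name); columns: gains, losses
    orphans: pd.Series  # index: species; families present in that species only


def aggregate_events(
    reconstructions: Sequence[DolloReconstruction], tree: dendropy.Tree
) -> EventTable:
    label_internal_nodes(tree)
    edges = [edge_id(n) for n in tree.preorder_node_iter()]
    leaves = sorted(leaf_label(lf) for lf in tree.leaf_node_iter())
    per_edge = pd.DataFrame(0, index=edges, columns=["gains", "losses"])
    orphans = pd.Series(0, index=leaves)
    for rec in reconstructions:
        per_edge.loc[rec.gain_edge, "gains"] += 1
        for loss in rec.loss_edges:
            per_edge.loc[loss, "losses"] += 1
        if len(rec.presence) == 1:
            orphans[next(iter(rec.presence))] += 1
    return EventTable(per_edge=per_edge, orphans=orphans)


def stramenopile_filter(
    clusters: Sequence[frozenset[str]],
    species_of: Mapping[str, str],
    scope_species: Iterable[str],
    family_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Presence/absence matrix restricted to a species scope.

    Clusters with at least one member from the scope are retained; the
    matrix columns are exactly the scope species, values are presence
    indicators.
    """
    scope = sorted(set(scope_species))
    known = set(species_of.values())
    missing = set(scope) - known
    if missing:
        raise ValueError(f"scope species not in the species map: {sorted(missing)}")
    ids = list(family_ids) if family_ids is not None else [f"fam{i}" for i in range(len(clusters))]
    rows = {}
    for fid, cluster in zip(ids, clusters):
        species = {species_of[p] for p in cluster}
        if species & set(scope):
            rows[fid] = [1 if s in species else 0 for s in scope]
    return pd.DataFrame.from_dict(rows, orient="index", columns=scope).astype(int)
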