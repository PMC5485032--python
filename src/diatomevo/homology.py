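"""Protein homology graph, Markov clustering, orphan calling, gene-family
count matrices and expansion Z-scores, reciprocal-best-hit orthology,
divergence profiles and Fisher enrichment.

The clustering follows the classic Markov Cluster (MCL) scheme: a
column-stochastic flow matrix is alternately expanded (squared) and
inflated (entry-wise powered and renormalized) until the flow stabilizes;
connected components of the limiting flow are the families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import fisher_exact

from .io import SimilarityEdge


def build_graph(
    edges: Iterable[SimilarityEdge],
    max_evalue: float = 1e-5,
    min_coverage: float = 0.0,
) -> nx.Graph:
    """Symmetrize directed similarity hits into an undirected weighted graph.

    A directed hit qualifies when its e-value and query coverage both pass
    the thresholds; an undirected edge is kept when at least one direction
    qualifies, weighted by the best bitscore over qualifying directions.
    Self hits are dropped.
    """
    if max_evalue < 0 or min_coverage < 0:
        raise ValueError("thresholds must be non-negative")
    graph = nx.Graph()
    any_edge = False
    for e in edges:
        any_edge = True
        graph.add_node(e.query)
        graph.add_node(e.subject)
        if e.query == e.subject:
            continue
        if e.evalue > max_evalue or e.query_coverage < min_coverage:
            continue
        prev = graph.edges.get((e.query, e.subject), {}).get("weight", 0.0)
        graph.add_edge(e.query, e.subject, weight=max(prev, e.bitscore))
    if not any_edge:
        import warnings

        warnings.warn("empty similarity table: returning an empty graph", stacklevel=2)
    return graph


@dataclass
class MclResult:
    clusters: list[frozenset[str]]
    converged: bool
    iterations: int
    #: max deviation of any column sum from 1 after each inflation (debug only)
    column_sum_error: list[float] = field(default_factory=list)


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    pruning_threshold: float = 1e-5,
    tolerance: float = 1e-6,
    max_iterations: int = 100,
    debug: bool = False,
) -> MclResult:
    """Markov clustering of a weighted undirected graph.

    Self loops with weight equal to each node's maximum incident weight are
    added before normalization (the usual regularization, so isolated and
    weakly attached nodes behave sensibly). Iteration alternates expansion
    (matrix squaring) and inflation (entry-wise power ``inflation`` followed
    by column renormalization, with entries below ``pruning_threshold``
    dropped) until the largest entry change falls below ``tolerance``.
    Clusters are the connected components of the limiting flow matrix and
    always refine the graph's connected components. Results are invariant
    to node input order (nodes are sorted internally).
    """
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    if not nodes:
        return MclResult(clusters=[], converged=True, iterations=0)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = sparse.lil_matrix((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if u == v:
            continue
        m[index[u], index[v]] = w
        m[index[v], index[u]] = w
    m = m.tocsr()
    loop = np.asarray(m.max(axis=0).todense()).ravel()
    loop[loop == 0.0] = 1.0
    m = m + sparse.diags(loop)

    def normalize(mat: sparse.csr_matrix) -> sparse.csr_matrix:
        sums = np.asarray(mat.sum(axis=0)).ravel()
        sums[sums == 0.0] = 1.0
        return (mat @ sparse.diags(1.0 / sums)).tocsr()

    m = normalize(m)
    errors: list[float] = []
    converged = False
    iteration = 0
    for iteration in range(1, max_iterations + 1):
        expanded = (m @ m).tocsr()
        inflated = expanded.power(inflation)
        inflated.data[inflated.data < pruning_threshold] = 0.0
        inflated.eliminate_zeros()
        inflated = normalize(inflated)
        if debug:
            sums = np.asarray(inflated.sum(axis=0)).ravel()
            errors.append(float(np.abs(sums - 1.0).max()))
        change = abs(inflated - m).max()
        m = inflated
        if change < tolerance:
            converged = True
            break

    flow = nx.Graph()
    flow.add_nodes_from(range(n))
    coo = m.tocoo()
    flow.add_edges_from(zip(coo.row, coo.col))
    clusters = [
        frozenset(nodes[i] for i in comp) for comp in nx.connected_components(flow)
    ]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return MclResult(
        clusters=clusters,
        converged=converged,
        iterations=iteration,
        column_sum_error=errors,
    )


# ---------------------------------------------------------------------------
# Orphans, single-copy clusters, count matrices, Z-scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrphanReport:
    """Focal-species orphans, split into singletons (unclustered proteins
    and size-1 clusters) and members of clusters containing only the focal
    species."""

    singletons: frozenset[str]
    single_species_cluster_members: frozenset[str]
    n_clusters_single_species: int

    @property
    def orphans(self) -> frozenset[str]:
        return self.singletons | self.single_species_cluster_members

    @property
    def n_orphans(self) -> int:
        return len(self.orphans)


def call_orphans(
    clusters: Sequence[frozenset[str]],
    species_of: Mapping[str, str],
    focal_species: str,
    focal_proteome: Iterable[str],
) -> OrphanReport:
    """Orphans = focal proteins with no homolog outside the focal species.

    Unclustered focal proteins count as singletons, as do focal proteins in
    size-1 clusters; focal members of multi-protein clusters whose species
    set is exactly the focal species form the second orphan class.
    """
    proteome = set(focal_proteome)
    singles: set[str] = set()
    private_members: set[str] = set()
    clustered: set[str] = set()
    n_private = 0
    for cluster in clusters:
        focal_members = {p for p in cluster if species_of[p] == focal_species}
        clustered |= focal_members
        if not focal_members:
            continue
        species = {species_of[p] for p in cluster}
        if len(cluster) == 1:
            singles |= focal_members
        elif species == {focal_species}:
            private_members |= focal_members
            n_private += 1
    singles |= proteome - clustered
    return OrphanReport(
        singletons=frozenset(singles),
        single_species_cluster_members=frozenset(private_members),
        n_clusters_single_species=n_private,
    )


def select_single_copy_clusters(
    clusters: Sequence[frozenset[str]],
    species_of: Mapping[str, str],
    required_species: Iterable[str],
) -> list[frozenset[str]]:
    """Clusters containing exactly one member of every required species and
    no other proteins (one-to-one orthologue sets)."""
    required = set(required_species)
    if not required:
        raise ValueError("required species set is empty")
    selected = []
    for cluster in clusters:
        counts: dict[str, int] = {}
        for p in cluster:
            counts[species_of[p]] = counts.get(species_of[p], 0) + 1
        if set(counts) == required and all(v == 1 for v in counts.values()):
            selected.append(cluster)
    return selected


def family_count_matrix(
    clusters: Sequence[frozenset[str]],
    species_of: Mapping[str, str],
    family_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Family × species matrix of member counts."""
    species = sorted(set(species_of.values()))
    ids = list(family_ids) if family_ids is not None else [f"fam{i}" for i in range(len(clusters))]
    data = np.zeros((len(clusters), len(species)), dtype=int)
    col = {s: j for j, s in enumerate(species)}
    for i, cluster in enumerate(clusters):
        for p in cluster:
            data[i, col[species_of[p]]] += 1
    return pd.DataFrame(data, index=ids, columns=species)


def expansion_zscore(counts: pd.DataFrame, focal_species: str) -> pd.DataFrame:
    """Per-family expansion Z-score of the focal species.

    Z = (focal count − mean count over all species) / SD over all species,
    with the population (divide-by-N) standard deviation taken over every
    species column including the focal one. Families with zero SD get
    ``defined = False`` and a missing Z, never a division error.
    """
    if focal_species not in counts.columns:
        raise ValueError(f"focal species {focal_species!r} not in count matrix")
    if counts.shape[1] < 2:
        raise ValueError("need at least two species columns")
    values = counts.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    focal = counts[focal_species].to_numpy(dtype=float)
    defined = sd > 0.0
    z = np.full(len(counts), np.nan)
    z[defined] = (focal[defined] - mean[defined]) / sd[defined]
    return pd.DataFrame(
        {
            "focal_count": focal,
            "mean": mean,
            "sd": sd,
            "z": z,
            "defined": defined,
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# Reciprocal best hits and divergence profiles
# ---------------------------------------------------------------------------

def _unique_best_hit(
    hits: Mapping[str, list[tuple[str, float]]]
) -> dict[str, str]:
    """Per query, the unique top-scoring subject; ties disqualify the query."""
    best: dict[str, str] = {}
    for query, subject_scores in hits.items():
        top = max(s for _, s in subject_scores)
        winners = {subj for subj, s in subject_scores if s == top}
        if len(winners) == 1:
            best[query] = next(iter(winners))
    return best


def rbh_orthologs(
    edges: Iterable[SimilarityEdge],
    species_of: Mapping[str, str],
    species_a: str,
    species_b: str,
    min_coverage: float = 0.30,
) -> list[tuple[str, str]]:
    """Reciprocal best hits between two species.

    Hits whose query coverage falls below ``min_coverage`` are discarded
    first (the 30% rule applied to the query sequence of each direction).
    A pair (a, b) is returned iff b is a's unique best remaining hit and a
    is b's; ties for best score disqualify conservatively. The result is a
    partial matching sorted by the species-A protein id.
    """
    forward: dict[str, list[tuple[str, float]]] = {}
    backward: dict[str, list[tuple[str, float]]] = {}
    for e in edges:
        sq, ss = species_of.get(e.query), species_of.get(e.subject)
        if e.query_coverage < min_coverage:
            continue
        if sq == species_a and ss == species_b:
            forward.setdefault(e.query, []).append((e.subject, e.bitscore))
        elif sq == species_b and ss == species_a:
            backward.setdefault(e.query, []).append((e.subject, e.bitscore))
    best_ab = _unique_best_hit(forward)
    best_ba = _unique_best_hit(backward)
    pairs = [
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    ]
    pairs.sort()
    return pairs


def divergence_profile(edges: Iterable[SimilarityEdge]) -> pd.DataFrame:
    """Cumulative distribution of best-hit percent identity per query.

    For each query, take the percent identity of its maximum-score hit
    (ties resolved to the highest identity); return the empirical
    cumulative proportion of queries at or below each identity value. The
    curve is monotone non-decreasing and ends at 1.
    """
    best: dict[str, tuple[float, float]] = {}
    for e in edges:
        key = (e.bitscore, e.percent_identity)
        if e.query not in best or key > best[e.query]:
            best[e.query] = key
    if not best:
        return pd.DataFrame(columns=["identity", "cumulative_fraction"])
    identities = np.sort(np.array([pid for _, pid in best.values()]))
    unique, counts = np.unique(identities, return_counts=True)
    cumulative = np.cumsum(counts) / len(identities)
    return pd.DataFrame({"identity": unique, "cumulative_fraction": cumulative})


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def set_enrichment_fisher(
    gene_set: Iterable[str],
    background: Iterable[str],
    labelled: Iterable[str],
) -> tuple[float, float]:
    """Two-sided Fisher exact test of label enrichment within a gene set.

    The 2×2 table crosses set membership against label status over the
    background universe. Returns (odds ratio, two-sided p-value).
    """
    gene_set = set(gene_set)
    background = set(background)
    labelled = set(labelled) & background
    if not gene_set:
        raise ValueError("gene set is empty")
    if not gene_set <= background:
        raise ValueError("gene set is not a subset of the background")
    a = len(gene_set & labelled)
    b = len(gene_set - labelled)
    c = len(labelled - gene_set)
    d = len(background) - a - b - c
    odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)
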