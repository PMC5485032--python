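"""Synthetic-data generators with planted ground truth.

Every pipeline input can be generated here: species trees with taxon maps,
gene families evolving under a single-gain (Dollo) process, gene trees with
planted bacteria→diatom transfer clades, alignment blocks with planted
conserved intergenic elements, codon pairs evolved at a controlled dN/dS,
LTR pairs diverged under a transition/transversion model, and two-species
similarity tables with known mutual-best structure. All generators are
deterministic for a fixed seed and return a truth object alongside the data.

The generators deliberately omit features of real data that the analyses do
not depend on: there is no indel model (alignment blocks are generated
aligned), codon evolution is a per-site accept/reject scheme rather than a
continuous-time codon model, and similarity scores are drawn from disjoint
score bands rather than from an alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import Gene, GenomicInterval, MafRow, AlignmentBlock, SimilarityEdge, TaxonMap
from .trees import (
    edge_id,
    label_internal_nodes,
    leaf_label,
    random_binary_tree,
    subtree_leaves,
)

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"),
    "C": ("A", "G"), "T": ("A", "G"),
}


# ---------------------------------------------------------------------------
# Species trees and taxon maps
# ---------------------------------------------------------------------------

def simulate_species_tree(
    n_species: int,
    group_proportions: Mapping[str, float],
    seed: int,
    focal_group: str = "diatom",
) -> tuple[dendropy.Tree, TaxonMap]:
    """Random rooted binary species tree with taxon-group assignments.

    Species counts per group follow ``group_proportions`` (largest-remainder
    apportionment); the focal species is the first species of
    ``focal_group``. Proportions must sum to 1.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    total = sum(group_proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"group proportions sum to {total}, not 1")
    if focal_group not in group_proportions or group_proportions[focal_group] <= 0:
        raise ValueError(f"focal group {focal_group!r} has zero proportion")
    rng = np.random.default_rng(seed)

    groups = sorted(group_proportions)
    raw = {g: group_proportions[g] * n_species for g in groups}
    counts = {g: int(np.floor(raw[g])) for g in groups}
    remainder = n_species - sum(counts.values())
    for g in sorted(groups, key=lambda g: raw[g] - counts[g], reverse=True)[:remainder]:
        counts[g] += 1
    if counts[focal_group] == 0:
        counts[focal_group] += 1
        donor = max(counts, key=counts.get)
        counts[donor] -= 1

    entries: dict[str, str] = {}
    for g in groups:
        for i in range(counts[g]):
            entries[f"{g}_{i}"] = g
    names = sorted(entries)
    rng.shuffle(names)
    tree = random_binary_tree(names, rng)
    label_internal_nodes(tree)
    taxon_map = TaxonMap(entries=entries, focal_species=f"{focal_group}_0")
    return tree, taxon_map


# ---------------------------------------------------------------------------
# Dollo gene families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DolloSimTruth:
    """Planted history of one gene family: a single gain edge and the loss
    edges below it; leaves below a loss are absent."""

    family_id: str
    gain_edge: str
    loss_edges: frozenset[str]
    presence: frozenset[str]


def simulate_dollo_families(
    tree: dendropy.Tree,
    n_families: int,
    seed: int,
    loss_prob: float = 0.1,
    gain_weights: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, list[DolloSimTruth]]:
    """Evolve ``n_families`` binary characters under a single-gain process.

    Each family gains exactly once on an edge drawn uniformly (or by
    ``gain_weights``, keyed by edge name) and is then lost independently
    with probability ``loss_prob`` on every edge strictly below the gain;
    a loss prunes the whole subtree. Families whose leaf presence would be
    empty are resampled.
    """
    if not 0.0 <= loss_prob < 1.0:
        raise ValueError("loss probability must be in [0, 1)")
    rng = np.random.default_rng(seed)
    label_internal_nodes(tree)
    nodes = list(tree.preorder_node_iter())
    edge_names = [edge_id(n) for n in nodes]
    if gain_weights is None:
        probs = np.full(len(nodes), 1.0 / len(nodes))
    else:
        w = np.array([gain_weights.get(name, 0.0) for name in edge_names], dtype=float)
        if w.sum() <= 0:
            raise ValueError("gain weights sum to zero on this tree")
        probs = w / w.sum()

    leaves = sorted(leaf_label(lf) for lf in tree.leaf_node_iter())
    truths: list[DolloSimTruth] = []
    rows = np.zeros((n_families, len(leaves)), dtype=int)
    col = {name: i for i, name in enumerate(leaves)}

    fam = 0
    while fam < n_families:
        gain_node = nodes[rng.choice(len(nodes), p=probs)]
        losses: set[str] = set()
        present: set[str] = set()

        def descend(node: dendropy.Node) -> None:
            if node is not gain_node and rng.random() < loss_prob:
                losses.add(edge_id(node))
                return
            if node.is_leaf():
                present.add(leaf_label(node))
                return
            for child in node.child_nodes():
                descend(child)

        descend(gain_node)
        if not present:
            continue
        fid = f"fam{fam}"
        truths.append(
            DolloSimTruth(
                family_id=fid,
                gain_edge=edge_id(gain_node),
                loss_edges=frozenset(losses),
                presence=frozenset(present),
            )
        )
        for sp in present:
            rows[fam, col[sp]] = 1
        fam += 1

    matrix = pd.DataFrame(rows, index=[t.family_id for t in truths], columns=leaves)
    return matrix, truths


# ---------------------------------------------------------------------------
# Gene trees with planted transfer clades
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HgtSimTruth:
    planted: bool
    clade_leaves: frozenset[str]
    clade_support: float | None
    donor_group: str
    recipients: tuple[str, ...]


_DEFAULT_BACKGROUND = {
    "metazoa": 6,
    "fungi": 4,
    "plantae": 4,
    "other-eukaryote": 4,
    "other-stramenopile": 2,
    "diatom": 2,
    "bacteria": 6,
}


def simulate_gene_tree_with_hgt(
    seed: int,
    planted: bool = True,
    n_bacteria_in_clade: int = 10,
    recipients: Sequence[str] = ("Pmultistriata",),
    focal_species: str = "Pmultistriata",
    background: Mapping[str, int] | None = None,
    clade_support: tuple[float, float] = (0.7, 1.0),
    other_support: tuple[float, float] = (0.3, 1.0),
) -> tuple[dendropy.Tree, TaxonMap, HgtSimTruth]:
    """Gene tree with (optionally) a planted bacteria→diatom transfer clade.

    When ``planted``, the focal diatom gene (plus any further recipient
    diatoms) sits inside a clade of ``n_bacteria_in_clade`` bacterial leaves
    whose subtending-edge support is drawn from ``clade_support``. When not
    planted, the focal gene nests among the eukaryote background leaves and
    the background bacteria are scattered at random.
    """
    if planted and not recipients:
        raise ValueError("planted transfer requires a non-empty recipient set")
    if planted and n_bacteria_in_clade < 1:
        raise ValueError("need at least one bacterial leaf in the planted clade")
    rng = np.random.default_rng(seed)
    background = dict(_DEFAULT_BACKGROUND if background is None else background)

    entries: dict[str, str] = {focal_species: "diatom"}
    for sp in recipients:
        entries[sp] = "diatom"
    bg_names: list[str] = []
    for group, count in sorted(background.items()):
        for i in range(count):
            name = f"{group}_{i}"
            entries[name] = group
            bg_names.append(name)
    clade_bacteria = [f"bacteria_c{i}" for i in range(n_bacteria_in_clade if planted else 0)]
    for name in clade_bacteria:
        entries[name] = "bacteria"

    tns = dendropy.TaxonNamespace()
    if planted:
        clade_names = list(clade_bacteria) + list(dict.fromkeys([focal_species, *recipients]))
        clade_tree = random_binary_tree(clade_names, rng, taxon_namespace=tns)
        bg_tree = random_binary_tree(bg_names, rng, taxon_namespace=tns)
        root = dendropy.Node()
        root.add_child(clade_tree.seed_node)
        root.add_child(bg_tree.seed_node)
        clade_tree.seed_node.edge.length = float(rng.exponential(0.1))
        bg_tree.seed_node.edge.length = float(rng.exponential(0.1))
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node = root
        tree.is_rooted = True
        clade_root = clade_tree.seed_node
    else:
        names = bg_names + [focal_species] + [s for s in recipients if s != focal_species]
        tree = random_binary_tree(names, rng, taxon_namespace=tns)
        clade_root = None

    support = None
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node is clade_root:
            node.support = float(rng.uniform(*clade_support))
            support = node.support
        else:
            node.support = float(rng.uniform(*other_support))
    tree.seed_node.support = None  # the root edge has no bipartition support

    truth = HgtSimTruth(
        planted=planted,
        clade_leaves=subtree_leaves(clade_root) if planted else frozenset(),
        clade_support=support,
        donor_group="bacteria",
        recipients=tuple(recipients) if planted else (),
    )
    return tree, TaxonMap(entries=entries, focal_species=focal_species), truth


# ---------------------------------------------------------------------------
# Alignment blocks with planted conserved intergenic elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CneSpec:
    """A planted conserved element: block-relative interval, per-base
    identity level, and the non-reference species in which it is conserved
    (``None`` = all)."""

    start: int
    end: int
    identity: float = 1.0
    species: frozenset[str] | None = None


@dataclass(frozen=True)
class PlantedCne:
    block_id: int
    interval: GenomicInterval
    identity: float
    conserved: frozenset[str]


@dataclass
class CneSimTruth:
    planted: list[PlantedCne] = field(default_factory=list)
    genes: dict[str, list[Gene]] = field(default_factory=dict)


def _evenly_spaced_mismatches(length: int, identity: float) -> set[int]:
    """Positions to mutate so every window of the element keeps close to the
    stated identity (mismatches spread evenly, never bunched)."""
    n_mis = int(np.floor((1.0 - identity) * length))
    if n_mis == 0:
        return set()
    stride = length / n_mis
    return {int(stride / 2 + i * stride) for i in range(n_mis)}


def simulate_alignment_with_cnes(
    seed: int,
    species: Sequence[str] = ("Pmultiseries", "Fcylindrus"),
    reference: str = "Pmultistriata",
    n_blocks: int = 1,
    block_length: int = 800,
    cne_specs: Sequence[Sequence[CneSpec]] | None = None,
    gene_specs: Sequence[Sequence[tuple[int, int]]] | None = None,
    background_identity: float = 0.25,
    window: int = 20,
) -> tuple[list[AlignmentBlock], dict[str, list[Gene]], CneSimTruth]:
    """Gap-free alignment blocks with planted conserved intergenic elements.

    ``cne_specs``/``gene_specs`` give, per block, the planted elements and
    genic intervals in block-relative coordinates (genes are annotated at
    the same offsets in every species). When omitted, two genes and two
    fully conserved elements are placed per block with clearance of at
    least two window lengths between features. Planted elements must be
    at least one window long and may not overlap any gene.
    """
    rng = np.random.default_rng(seed)
    all_species = [reference, *species]
    if cne_specs is None or gene_specs is None:
        cne_specs, gene_specs = [], []
        for _ in range(n_blocks):
            c, g = _random_block_layout(rng, block_length, window)
            cne_specs.append(c)
            gene_specs.append(g)
    if len(cne_specs) != n_blocks or len(gene_specs) != n_blocks:
        raise ValueError("need one CNE spec list and one gene spec list per block")

    src_size = n_blocks * block_length * 4 + 1000
    blocks: list[AlignmentBlock] = []
    truth = CneSimTruth(genes={sp: [] for sp in all_species})

    for b in range(n_blocks):
        genes_b = sorted(gene_specs[b])
        for spec in cne_specs[b]:
            if spec.end - spec.start < window:
                raise ValueError("planted element shorter than the scan window")
            if not 0.0 <= spec.identity <= 1.0:
                raise ValueError("identity level outside [0, 1]")
            for gs, ge in genes_b:
                if spec.start < ge and gs < spec.end:
                    raise ValueError(
                        f"block {b}: planted element {spec.start}-{spec.end} "
                        f"overlaps gene {gs}-{ge}"
                    )
        offset = b * block_length * 4
        ref_seq = rng.choice(_BASES, size=block_length)
        rows = [
            MafRow(
                species=reference,
                seq_id=f"{reference}_chr",
                start=offset,
                end=offset + block_length,
                strand="+",
                text="".join(ref_seq),
                src_size=src_size,
            )
        ]
        for sp in species:
            seq = ref_seq.copy()
            # background divergence everywhere, then overwrite planted elements
            bg_mismatch = rng.random(block_length) >= background_identity
            conserved_mask = np.zeros(block_length, dtype=bool)
            forced_mismatch = np.zeros(block_length, dtype=bool)
            for spec in cne_specs[b]:
                if spec.species is not None and sp not in spec.species:
                    continue
                conserved_mask[spec.start : spec.end] = True
                for p in _evenly_spaced_mismatches(spec.end - spec.start, spec.identity):
                    forced_mismatch[spec.start + p] = True
            mutate = (bg_mismatch & ~conserved_mask) | forced_mismatch
            for pos in np.flatnonzero(mutate):
                choices = [x for x in "ACGT" if x != seq[pos]]
                seq[pos] = choices[rng.integers(3)]
            rows.append(
                MafRow(
                    species=sp,
                    seq_id=f"{sp}_chr",
                    start=offset,
                    end=offset + block_length,
                    strand="+",
                    text="".join(seq),
                    src_size=src_size,
                )
            )
        blocks.append(AlignmentBlock(rows=rows, block_id=b))

        for spec in cne_specs[b]:
            conserved = frozenset(species) if spec.species is None else spec.species
            truth.planted.append(
                PlantedCne(
                    block_id=b,
                    interval=GenomicInterval(
                        seq_id=f"{reference}_chr",
                        start=offset + spec.start,
                        end=offset + spec.end,
                    ),
                    identity=spec.identity,
                    conserved=conserved,
                )
            )
        for gi, (gs, ge) in enumerate(genes_b):
            for sp in all_species:
                truth.genes[sp].append(
                    Gene(
                        gene_id=f"{sp}_b{b}g{gi}",
                        interval=GenomicInterval(
                            seq_id=f"{sp}_chr", start=offset + gs, end=offset + ge, strand="+"
                        ),
                    )
                )
    return blocks, truth.genes, truth


def _random_block_layout(
    rng: np.random.Generator, block_length: int, window: int
) -> tuple[list[CneSpec], list[tuple[int, int]]]:
    """Two genes and two conserved elements with ≥ 2·window clearance."""
    margin = 2 * window
    placed: list[tuple[int, int]] = []

    def place(length: int, tries: int = 200) -> tuple[int, int]:
        for _ in range(tries):
            start = int(rng.integers(margin, block_length - length - margin))
            iv = (start, start + length)
            if all(iv[0] >= e + margin or iv[1] + margin <= s for s, e in placed):
                placed.append(iv)
                return iv
        raise RuntimeError("could not place feature; block too crowded")

    genes = [place(int(rng.integers(40, 80))) for _ in range(2)]
    cnes = []
    for _ in range(2):
        s, e = place(int(rng.integers(2 * window, 4 * window)))
        cnes.append(CneSpec(start=s, end=e, identity=1.0))
    return cnes, genes


# ---------------------------------------------------------------------------
# TSS proximity datasets
# ---------------------------------------------------------------------------

def simulate_tss_dataset(
    seed: int,
    genome_length: int = 100_000,
    n_genes: int = 50,
    gene_length: int = 600,
    n_cnes: int = 30,
    cne_length: int = 50,
    max_tss_distance: int | None = None,
    seq_id: str = "chr1",
) -> tuple[list[Gene], list[GenomicInterval]]:
    """Stranded gene annotation plus candidate elements on one sequence.

    With ``max_tss_distance=None`` the elements are drawn uniformly from
    intergenic space (a null dataset); otherwise each element midpoint is
    placed within that distance of a random transcription start site.
    """
    rng = np.random.default_rng(seed)
    spacing = genome_length // n_genes
    if spacing <= gene_length + 2 * cne_length:
        raise ValueError("genome too small for the requested gene density")
    genes: list[Gene] = []
    for i in range(n_genes):
        lo = i * spacing + cne_length
        start = int(rng.integers(lo, lo + spacing - gene_length - 2 * cne_length))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            Gene(
                gene_id=f"g{i}",
                interval=GenomicInterval(seq_id, start, start + gene_length, strand),
            )
        )
    spans = sorted((g.interval.start, g.interval.end) for g in genes)

    def intergenic(pos: int, length: int) -> bool:
        if pos < 0 or pos + length > genome_length:
            return False
        return all(pos >= e or pos + length <= s for s, e in spans)

    cnes: list[GenomicInterval] = []
    while len(cnes) < n_cnes:
        if max_tss_distance is None:
            pos = int(rng.integers(0, genome_length - cne_length))
        else:
            g = genes[rng.integers(n_genes)]
            tss = g.interval.start if g.interval.strand == "+" else g.interval.end
            mid = tss + int(rng.integers(-max_tss_distance, max_tss_distance + 1))
            pos = mid - cne_length // 2
        if intergenic(pos, cne_length):
            cnes.append(GenomicInterval(seq_id, pos, pos + cne_length))
    return genes, cnes


# ---------------------------------------------------------------------------
# Codon pairs at controlled dN/dS
# ---------------------------------------------------------------------------

def simulate_codon_pair(
    n_codons: int, target_ks: float, omega: float, seed: int
) -> tuple[str, str, dict[str, float]]:
    """Evolve a CDS pair to a target synonymous divergence at a given dN/dS.

    Substitutions are proposed uniformly over sites and bases; proposals
    creating stop codons are rejected, synonymous changes are accepted with
    probability 1/max(1, ω) and nonsynonymous changes with probability
    ω/max(1, ω), so the realized nonsynonymous:synonymous rate ratio is ω.
    Evolution stops once the number of synonymous events reaches
    ``target_ks`` × (synonymous sites of the ancestor). The truth dict
    records the realized event counts and per-site rates.
    """
    from .molevo import count_sites  # local import: molevo does not import simulate

    if n_codons < 30:
        raise ValueError("need at least 30 codons")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if target_ks < 0:
        raise ValueError("target Ks must be non-negative")
    rng = np.random.default_rng(seed)

    from .molevo import CODON_TABLE, STOP_CODONS

    sense = sorted(set(CODON_TABLE) - STOP_CODONS)
    codons = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]
    seq1 = "".join(codons)
    s_sites, n_sites = count_sites(seq1)
    n_syn_target = int(round(target_ks * s_sites))

    p_syn = 1.0 / max(1.0, omega)
    p_non = omega / max(1.0, omega)
    seq = list(seq1)
    n_syn = n_non = 0
    while n_syn < n_syn_target:
        pos = int(rng.integers(0, 3 * n_codons))
        ci = pos // 3
        codon = "".join(seq[3 * ci : 3 * ci + 3])
        old = seq[pos]
        new = "ACGT"[rng.integers(4)]
        if new == old:
            continue
        mutated = codon[: pos % 3] + new + codon[pos % 3 + 1 :]
        if mutated in STOP_CODONS:
            continue
        synonymous = CODON_TABLE[mutated] == CODON_TABLE[codon]
        if synonymous:
            if rng.random() < p_syn:
                seq[pos] = new
                n_syn += 1
        else:
            if rng.random() < p_non:
                seq[pos] = new
                n_non += 1
    seq2 = "".join(seq)
    truth = {
        "true_ks": n_syn / s_sites,
        "true_ka": n_non / n_sites if n_sites > 0 else 0.0,
        "n_syn_events": float(n_syn),
        "n_nonsyn_events": float(n_non),
        "syn_sites": s_sites,
        "nonsyn_sites": n_sites,
    }
    return seq1, seq2, truth


# ---------------------------------------------------------------------------
# LTR pairs under a two-parameter substitution model
# ---------------------------------------------------------------------------

def simulate_ltr_pair(
    length: int,
    age: float,
    rate: float,
    ts_tv_ratio: float = 2.0,
    seed: int = 0,
) -> tuple[str, str, dict[str, float]]:
    """Diverge two initially identical LTR copies for ``age`` years.

    Each copy accumulates substitutions at ``rate`` per site per year, so
    the expected pairwise distance is K = 2·rate·age. Per site the event
    count is Poisson(K); each event is a transition with probability
    κ/(κ+2) and otherwise one of the two transversions. Distances at or
    beyond 0.75 expected substitutions per site are refused as saturated.
    """
    expected_k = 2.0 * rate * age
    if expected_k >= 0.75:
        raise ValueError(f"expected distance {expected_k:.3f} >= 0.75 (saturated)")
    rng = np.random.default_rng(seed)
    seq1 = rng.choice(_BASES, size=length)
    seq2 = seq1.copy()
    kappa = ts_tv_ratio
    p_transition = kappa / (kappa + 2.0)
    n_events = rng.poisson(expected_k, size=length)
    for pos in np.flatnonzero(n_events):
        base = seq2[pos]
        for _ in range(n_events[pos]):
            if rng.random() < p_transition:
                base = _TRANSITION[base]
            else:
                base = _TRANSVERSIONS[base][rng.integers(2)]
        seq2[pos] = base
    truth = {"expected_k": expected_k, "n_events": float(n_events.sum()), "age": age}
    return "".join(seq1), "".join(seq2), truth


# ---------------------------------------------------------------------------
# Two-species similarity tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedOrtholog:
    protein_a: str
    protein_b: str
    coverage_a: float


def simulate_similarity_table(
    seed: int,
    n_a: int = 1000,
    n_b: int = 1000,
    n_pairs: int = 300,
    decoy_rate: float = 5.0,
    low_coverage_fraction: float = 0.0,
    species_a: str = "Pmu",
    species_b: str = "Pms",
) -> tuple[list[SimilarityEdge], list[PlantedOrtholog]]:
    """Two-species similarity table with planted reciprocal-best structure.

    The first ``n_pairs`` proteins of each species form planted ortholog
    pairs whose mutual hits score in a band strictly above every decoy hit,
    so each planted pair is the mutual best. Decoys are one-directional
    (A→B) so they can never create a reciprocal pair of their own. A
    ``low_coverage_fraction`` of planted pairs gets focal-side coverage
    below 0.3 — traps that a 30% coverage filter must remove.
    """
    if n_pairs > min(n_a, n_b):
        raise ValueError("more planted pairs than proteins")
    rng = np.random.default_rng(seed)
    edges: list[SimilarityEdge] = []
    truth: list[PlantedOrtholog] = []
    n_low = int(round(low_coverage_fraction * n_pairs))
    low_idx = set(rng.choice(n_pairs, size=n_low, replace=False)) if n_low else set()

    for i in range(n_pairs):
        a, b = f"{species_a}_p{i}", f"{species_b}_p{i}"
        score = float(rng.uniform(200.0, 400.0))
        cov_a = float(rng.uniform(0.10, 0.25)) if i in low_idx else float(rng.uniform(0.40, 1.0))
        cov_b = float(rng.uniform(0.40, 1.0))
        pid = float(rng.uniform(60.0, 95.0))
        ev = float(10.0 ** rng.uniform(-50.0, -20.0))
        edges.append(SimilarityEdge(a, b, score, ev, cov_a, pid))
        edges.append(
            SimilarityEdge(b, a, score * float(rng.uniform(0.95, 1.0)), ev, cov_b, pid)
        )
        truth.append(PlantedOrtholog(a, b, cov_a))

    n_decoys = rng.poisson(decoy_rate, size=n_a)
    for i in range(n_a):
        a = f"{species_a}_p{i}"
        for _ in range(n_decoys[i]):
            j = int(rng.integers(0, n_b))
            if j == i and i < n_pairs:
                continue  # never duplicate a planted pairing
            edges.append(
                SimilarityEdge(
                    a,
                    f"{species_b}_p{j}",
                    float(rng.uniform(50.0, 150.0)),
                    float(10.0 ** rng.uniform(-8.0, -2.0)),
                    float(rng.uniform(0.30, 1.0)),
                    float(rng.uniform(20.0, 35.0)),
                )
            )
    return edges, truth
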