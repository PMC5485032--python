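"""Conserved noncoding element (CNE) discovery from alignment blocks.

A sliding window (20 bp, step 10 bp by default) moves along the reference
row of every alignment block; a window passes for a non-reference species
when its column identity against the reference reaches the threshold and
its projection overlaps no genic interval in either genome. Overlapping
and adjacent passing windows merge into CNEs; the conserved-species set of
a merged element is the intersection over its constituent windows, and its
identity is recomputed over the merged columns.

Identity is computed on aligned columns with gap columns counted in the
denominator — a conservative, deterministic choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .homology import set_enrichment_fisher
from .io import AlignmentBlock, Gene, GenomicInterval, MafRow

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 20
DEFAULT_STEP = 10
DEFAULT_MIN_IDENTITY = 0.70


@dataclass(frozen=True)
class WindowHit:
    block_id: int
    ref_offset: int  # reference-base offset within the block
    ref_interval: GenomicInterval
    species_identity: Mapping[str, float]  # passing species only

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.species_identity)


@dataclass(frozen=True)
class CneRecord:
    interval: GenomicInterval  # on the reference genome
    conserved_species: frozenset[str]
    mean_identity: float  # percent, over conserved species
    block_id: int
    tss_distance: float | None = None

    @property
    def length(self) -> int:
        return self.interval.length


def _genic_trees(genes: Mapping[str, Sequence[Gene]]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for species, gene_list in genes.items():
        for g in gene_list:
            key = (species, g.interval.seq_id)
            trees.setdefault(key, IntervalTree()).addi(g.interval.start, g.interval.end)
    return trees


def _row_projection(row: MafRow, col_start: int, col_end: int) -> tuple[int, int]:
    """Forward-strand source interval covered by columns [col_start, col_end)."""
    text = row.text
    before = col_start - text.count("-", 0, col_start)
    within = (col_end - col_start) - text.count("-", col_start, col_end)
    if row.strand == "+":
        start = row.start + before
        return start, start + within
    end = row.end - before
    return end - within, end


def _ref_columns(ref: MafRow) -> np.ndarray:
    """Alignment-column index of each ungapped reference base."""
    return np.flatnonzero(np.frombuffer(ref.text.encode(), dtype=np.uint8) != ord("-"))


def window_identity(block: AlignmentBlock, species: str, col_start: int, col_end: int) -> float:
    """Column identity of one species against the reference over a column
    span; gap columns count in the denominator."""
    ref_text = block.reference.text[col_start:col_end]
    row = next(r for r in block.rows if r.species == species)
    text = row.text[col_start:col_end]
    matches = sum(
        1 for a, b in zip(ref_text, text) if a == b and a != "-"
    )
    return matches / (col_end - col_start)


def scan_windows(
    blocks: Iterable[AlignmentBlock],
    genes: Mapping[str, Sequence[Gene]],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[WindowHit]:
    """Windowed scan for conserved intergenic segments.

    ``genes`` maps species → genic intervals (full gene spans). A window is
    emitted when at least one non-reference species passes both the
    identity threshold and the intergenic requirement on both genomes.
    Blocks shorter than one window are skipped with a log entry.
    """
    trees = _genic_trees(genes)
    hits: list[WindowHit] = []
    for block in blocks:
        ref = block.reference
        if ref.strand != "+":
            raise ValueError(
                f"block {block.block_id}: reference row must be on the forward strand"
            )
        ref_cols = _ref_columns(ref)
        n_ref = len(ref_cols)
        if n_ref < window:
            logger.info("block %d shorter than one window; skipped", block.block_id)
            continue
        for offset in range(0, n_ref - window + 1, step):
            col_start = int(ref_cols[offset])
            col_end = int(ref_cols[offset + window - 1]) + 1
            ref_start = ref.start + offset
            ref_iv = GenomicInterval(ref.seq_id, ref_start, ref_start + window)
            ref_tree = trees.get((ref.species, ref.seq_id))
            if ref_tree is not None and ref_tree.overlap(ref_iv.start, ref_iv.end):
                continue
            passing: dict[str, float] = {}
            for row in block.rows[1:]:
                identity = window_identity(block, row.species, col_start, col_end)
                if identity < min_identity:
                    continue
                ps, pe = _row_projection(row, col_start, col_end)
                sp_tree = trees.get((row.species, row.seq_id))
                if ps < pe and sp_tree is not None and sp_tree.overlap(ps, pe):
                    continue
                passing[row.species] = identity
            if passing:
                hits.append(
                    WindowHit(
                        block_id=block.block_id,
                        ref_offset=offset,
                        ref_interval=ref_iv,
                        species_identity=passing,
                    )
                )
    return hits


def merge_windows(
    hits: Sequence[WindowHit],
    blocks: Sequence[AlignmentBlock],
) -> list[CneRecord]:
    """Merge overlapping/adjacent window hits into CNE records.

    Hits chain together while their reference intervals overlap or touch
    and the running intersection of passing-species sets stays non-empty;
    the merged element's conserved set is that intersection and its mean
    identity is recomputed over the merged interval. The operation is
    idempotent and independent of input order.
    """
    by_block: dict[int, AlignmentBlock] = {b.block_id: b for b in blocks}
    groups: dict[tuple[int, str], list[WindowHit]] = {}
    for h in hits:
        groups.setdefault((h.block_id, h.ref_interval.seq_id), []).append(h)

    records: list[CneRecord] = []
    for (block_id, _seq), group in sorted(groups.items()):
        block = by_block[block_id]
        ref_cols = _ref_columns(block.reference)
        group.sort(key=lambda h: h.ref_interval.start)
        chain: list[WindowHit] = []
        chain_species: frozenset[str] = frozenset()

        def flush() -> None:
            if not chain:
                return
            start = chain[0].ref_interval.start
            end = chain[-1].ref_interval.end
            off0 = start - block.reference.start
            off1 = end - block.reference.start
            col_start = int(ref_cols[off0])
            col_end = int(ref_cols[off1 - 1]) + 1
            identities = [
                window_identity(block, sp, col_start, col_end) for sp in chain_species
            ]
            records.append(
                CneRecord(
                    interval=GenomicInterval(chain[0].ref_interval.seq_id, start, end),
                    conserved_species=chain_species,
                    mean_identity=100.0 * float(np.mean(identities)),
                    block_id=block_id,
                )
            )

        for hit in group:
            if not chain:
                chain = [hit]
                chain_species = hit.species
                continue
            touching = hit.ref_interval.start <= chain[-1].ref_interval.end
            shared = chain_species & hit.species
            if touching and shared:
                chain.append(hit)
                chain_species = shared
            else:
                flush()
                chain = [hit]
                chain_species = hit.species
        flush()
    records.sort(key=lambda r: (r.interval.seq_id, r.interval.start))
    return records


def classify_by_species(
    cnes: Sequence[CneRecord],
    combinations: Mapping[str, frozenset[str] | set[str]],
) -> dict[str, list[CneRecord]]:
    """Partition CNEs by exact match of their conserved-species set to
    named combinations; unmatched elements land under ``"other"``."""
    lookup = {frozenset(v): k for k, v in combinations.items()}
    out: dict[str, list[CneRecord]] = {k: [] for k in combinations}
    out["other"] = []
    for cne in cnes:
        out[lookup.get(cne.conserved_species, "other")].append(cne)
    return out


# ---------------------------------------------------------------------------
# TSS proximity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TssTestResult:
    statistic: float
    p_value: float
    direction: str  # "closer" | "farther" | "none"
    mean_cne_distance: float
    mean_control_distance: float


def _tss_positions(genes: Sequence[Gene]) -> np.ndarray:
    """Strand-aware transcription start sites (gene start on its strand)."""
    tss = []
    for g in genes:
        iv = g.interval
        tss.append(iv.start if iv.strand != "-" else iv.end)
    return np.asarray(tss, dtype=float)


def nearest_tss_distance(
    intervals: Sequence[GenomicInterval], genes: Sequence[Gene]
) -> np.ndarray:
    """Minimum absolute distance from each interval midpoint to any TSS."""
    tss = _tss_positions(genes)
    mids = np.asarray([(iv.start + iv.end) / 2.0 for iv in intervals])
    return np.abs(mids[:, None] - tss[None, :]).min(axis=1)


def _intergenic_spans(genes: Sequence[Gene], seq_length: int) -> list[tuple[int, int]]:
    spans = sorted((g.interval.start, g.interval.end) for g in genes)
    gaps = []
    cursor = 0
    for s, e in spans:
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < seq_length:
        gaps.append((cursor, seq_length))
    return gaps


def sample_intergenic_controls(
    lengths: Sequence[int],
    genes: Sequence[Gene],
    seq_length: int,
    n_controls: int,
    rng: np.random.Generator,
    seq_id: str = "chr",
) -> list[GenomicInterval]:
    """Length-matched intervals drawn uniformly from intergenic space."""
    gaps = _intergenic_spans(genes, seq_length)
    controls: list[GenomicInterval] = []
    lengths = list(lengths)
    max_tries = 50 * n_controls + 100
    tries = 0
    while len(controls) < n_controls:
        tries += 1
        if tries > max_tries:
            raise ValueError("no intergenic space large enough for the controls")
        length = int(lengths[rng.integers(len(lengths))])
        fitting = [(s, e) for s, e in gaps if e - s >= length]
        if not fitting:
            raise ValueError("no intergenic space large enough for the controls")
        weights = np.array([e - s - length + 1 for s, e in fitting], dtype=float)
        s, e = fitting[rng.choice(len(fitting), p=weights / weights.sum())]
        start = int(rng.integers(s, e - length + 1))
        controls.append(GenomicInterval(seq_id, start, start + length))
    return controls


def tss_proximity_test(
    cnes: Sequence[GenomicInterval | CneRecord],
    genes: Sequence[Gene],
    seq_length: int,
    n_controls: int = 1000,
    seed: int = 0,
) -> TssTestResult:
    """Are CNEs closer to transcription start sites than random intergenic
    intervals of the same lengths?

    Controls are sampled uniformly from intergenic space; the CNE and
    control nearest-TSS distance samples are compared with Welch's t-test.
    """
    intervals = [c.interval if isinstance(c, CneRecord) else c for c in cnes]
    if not intervals:
        raise ValueError("no CNEs to test")
    rng = np.random.default_rng(seed)
    controls = sample_intergenic_controls(
        [iv.length for iv in intervals], genes, seq_length, n_controls, rng
    )
    d_cne = nearest_tss_distance(intervals, genes)
    d_ctrl = nearest_tss_distance(controls, genes)
    stat, p = stats.ttest_ind(d_cne, d_ctrl, equal_var=False)
    delta = float(d_cne.mean() - d_ctrl.mean())
    direction = "none" if delta == 0 else ("closer" if delta < 0 else "farther")
    return TssTestResult(
        statistic=float(stat),
        p_value=float(p),
        direction=direction,
        mean_cne_distance=float(d_cne.mean()),
        mean_control_distance=float(d_ctrl.mean()),
    )


# ---------------------------------------------------------------------------
# Gene-association enrichment
# ---------------------------------------------------------------------------

def nearest_gene(cne: GenomicInterval | CneRecord, genes: Sequence[Gene]) -> Gene:
    iv = cne.interval if isinstance(cne, CneRecord) else cne
    mid = (iv.start + iv.end) / 2.0
    candidates = [g for g in genes if g.interval.seq_id == iv.seq_id] or list(genes)

    def distance(g: Gene) -> float:
        if g.interval.start <= mid < g.interval.end:
            return 0.0
        return min(abs(mid - g.interval.start), abs(mid - g.interval.end))

    return min(candidates, key=lambda g: (distance(g), g.gene_id))


def cne_gene_enrichment(
    cnes: Sequence[GenomicInterval | CneRecord],
    genes: Sequence[Gene],
    gene_terms: Mapping[str, Iterable[str]],
) -> dict[str, tuple[float, float]]:
    """Per-term Fisher enrichment of CNE-adjacent genes.

    Each CNE is assigned to its nearest gene; per term, a 2×2 table crosses
    CNE adjacency against term membership over all annotated genes.
    """
    if not gene_terms:
        raise ValueError("empty gene→term table")
    adjacent = {nearest_gene(c, genes).gene_id for c in cnes}
    background = {g.gene_id for g in genes}
    terms: dict[str, set[str]] = {}
    for gene, term_list in gene_terms.items():
        for t in term_list:
            terms.setdefault(t, set()).add(gene)
    return {
        term: set_enrichment_fisher(adjacent, background, members)
        for term, members in sorted(terms.items())
    }
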