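"""Readers and writers for the external formats the pipeline touches.

All coordinates inside the package are 0-based half-open on the forward
strand; GFF3 (1-based inclusive) and MAF (strand-relative) coordinates are
converted at the I/O boundary, never downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Closed vocabulary of taxonomic groups used throughout the package.
TAXON_GROUPS = frozenset(
    {
        "bacteria",
        "archaea",
        "diatom",
        "other-stramenopile",
        "red-alga",
        "plantae",
        "fungi",
        "metazoa",
        "other-eukaryote",
    }
)


@dataclass(frozen=True)
class TaxonMap:
    """Species → taxonomic-group assignment plus the focal species.

    The group labels are restricted to :data:`TAXON_GROUPS`; the focal
    species (the genome under study) must itself be mapped.
    """

    entries: Mapping[str, str]
    focal_species: str

    def __post_init__(self) -> None:
        bad = {g for g in self.entries.values() if g not in TAXON_GROUPS}
        if bad:
            raise ValueError(f"unknown taxon group label(s): {sorted(bad)}")
        if self.focal_species not in self.entries:
            raise ValueError(f"focal species {self.focal_species!r} not in taxon map")

    def group(self, species: str) -> str:
        try:
            return self.entries[species]
        except KeyError:
            raise KeyError(f"species {species!r} has no taxon-group assignment") from None


@dataclass(frozen=True)
class SimilarityEdge:
    """One directed similarity hit (query → subject).

    ``query_coverage`` is the fraction of the query sequence covered by the
    alignment, in [0, 1]; ``percent_identity`` is on the 0–100 scale.
    """

    query: str
    subject: str
    bitscore: float
    evalue: float
    query_coverage: float = 1.0
    percent_identity: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError(f"coverage {self.query_coverage} outside [0, 1]")
        if self.bitscore < 0 or self.evalue < 0:
            raise ValueError("bitscore and evalue must be non-negative")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.seq_id}:{self.start}-{self.end}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class MafRow:
    """One species row of an alignment block.

    ``start``/``end`` are forward-strand 0-based half-open coordinates on the
    source sequence regardless of the aligned strand; ``text`` is the aligned
    sequence (with gaps) as it appears on ``strand``.
    """

    species: str
    seq_id: str
    start: int
    end: int
    strand: str
    text: str
    src_size: int

    @property
    def ungapped_length(self) -> int:
        return len(self.text) - self.text.count("-")


@dataclass
class AlignmentBlock:
    """One MAF block; the first row is the reference."""

    rows: list[MafRow]
    block_id: int = 0

    def __post_init__(self) -> None:
        lengths = {len(r.text) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"block {self.block_id}: aligned rows have unequal lengths")
        for r in self.rows:
            if r.ungapped_length != r.end - r.start:
                raise ValueError(
                    f"block {self.block_id}, row {r.species}.{r.seq_id}: "
                    f"ungapped length {r.ungapped_length} != span {r.end - r.start}"
                )

    @property
    def reference(self) -> MafRow:
        return self.rows[0]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].text)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(id, sequence)``.

    Residues are upper-cased; gap characters, if present, are preserved.
    Duplicate record ids raise ``ValueError``; an empty file returns an
    empty list with a warning.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record id: {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        warnings.warn(f"FASTA file {path} contains no records", stacklevel=2)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def _attach_supports(tree: dendropy.Tree) -> None:
    """Interpret numeric internal-node labels as support values.

    Values in (1, 100] are taken to be bootstrap percentages and divided by
    100; unlabeled internal nodes get ``support = None`` (missing, not zero).
    """
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        support = None
        if node.label is not None:
            try:
                value = float(node.label)
            except ValueError:
                value = None
            if value is not None:
                if 1.0 < value <= 100.0:
                    value /= 100.0
                if 0.0 <= value <= 1.0:
                    support = value
                    node.label = None
        node.support = support


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a newick tree; numeric internal labels become edge supports.

    The support of an internal node is attached as ``node.support`` and
    refers to the edge above that node (the convention of FastTree/RAxML
    output). Missing labels are recorded as ``None``.
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    _attach_supports(tree)
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    _attach_supports(tree)
    return tree


def tree_to_string(tree: dendropy.Tree) -> str:
    """Serialize a tree, writing supports (or labels) on internal nodes."""
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        support = getattr(node, "support", None)
        if node.label is None and support is not None:
            node.label = format(support, "g")
    out = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    # undo the temporary label injection so the in-memory tree is unchanged
    _attach_supports(tree)
    return out


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_string(tree) + "\n")


# ---------------------------------------------------------------------------
# MAF alignment blocks
# ---------------------------------------------------------------------------

def _split_src(src: str) -> tuple[str, str]:
    """Split a MAF ``src`` field of the form ``species.sequence``."""
    if "." in src:
        species, seq_id = src.split(".", 1)
    else:
        species = seq_id = src
    return species, seq_id


def read_maf(path: str | Path) -> list[AlignmentBlock]:
    """Read MAF alignment blocks; the first ``s`` row of each block is the
    reference. Negative-strand coordinates are converted to forward-strand
    0-based half-open; non-``s`` lines (``e``/``i``/``q``) are ignored by the
    underlying parser.
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for block_idx, aln in enumerate(AlignIO.parse(fh, "maf")):
            rows = []
            for rec in aln:
                species, seq_id = _split_src(rec.id)
                start = rec.annotations["start"]
                size = rec.annotations["size"]
                strand = "+" if rec.annotations["strand"] in (1, "+") else "-"
                src_size = rec.annotations["srcSize"]
                if strand == "-":
                    fwd_start = src_size - start - size
                else:
                    fwd_start = start
                rows.append(
                    MafRow(
                        species=species,
                        seq_id=seq_id,
                        start=fwd_start,
                        end=fwd_start + size,
                        strand=strand,
                        text=str(rec.seq).upper(),
                        src_size=src_size,
                    )
                )
            try:
                blocks.append(AlignmentBlock(rows=rows, block_id=block_idx))
            except ValueError as exc:
                raise ValueError(f"malformed MAF block {block_idx}: {exc}") from exc
    return blocks


def write_maf(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for block in blocks:
            fh.write("a\n")
            for row in block.rows:
                size = row.end - row.start
                start = row.start if row.strand == "+" else row.src_size - row.end
                fh.write(
                    f"s {row.species}.{row.seq_id} {start} {size} "
                    f"{row.strand} {row.src_size} {row.text}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# GFF3 gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    gene_id: str
    interval: GenomicInterval


def read_gff_genes(
    path: str | Path, feature_types: Sequence[str] = ("gene",)
) -> list[Gene]:
    """Extract genic features from a GFF3 file as 0-based half-open intervals."""
    genes: list[Gene] = []
    wanted = set(feature_types)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns, got {len(fields)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in wanted:
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ValueError(f"{path}:{lineno}: start {start_i} > end {end_i}")
            gene_id = f"{seqid}:{start_i}-{end_i}"
            for part in attrs.split(";"):
                if part.startswith("ID="):
                    gene_id = part[3:]
                    break
            genes.append(
                Gene(
                    gene_id=gene_id,
                    interval=GenomicInterval(
                        seq_id=seqid,
                        start=start_i - 1,  # 1-based inclusive -> 0-based half-open
                        end=end_i,
                        strand=strand if strand in "+-" else ".",
                    ),
                )
            )
    return genes


def write_gff_genes(genes: Iterable[Gene], path: str | Path, source: str = "diatomevo") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            strand = iv.strand if iv.strand in "+-" else "."
            fh.write(
                f"{iv.seq_id}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------

_BLAST_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_similarity_tsv(
    path: str | Path, query_lengths: Mapping[str, int] | None = None
) -> list[SimilarityEdge]:
    """Read a 12-column tabular BLAST file, with an optional 13th
    query-coverage column. When the column is absent, coverage is computed
    as alignment length / query length if ``query_lengths`` is given,
    otherwise it defaults to 1.0.
    """
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    if df.shape[1] not in (12, 13):
        raise ValueError(f"expected 12 or 13 columns, got {df.shape[1]}")
    df.columns = _BLAST_COLUMNS + (["qcov"] if df.shape[1] == 13 else [])
    edges = []
    for row in df.itertuples(index=False):
        if df.shape[1] == 13:
            cov = float(row.qcov)
        elif query_lengths is not None:
            cov = min(1.0, float(row.length) / query_lengths[str(row.query)])
        else:
            cov = 1.0
        edges.append(
            SimilarityEdge(
                query=str(row.query),
                subject=str(row.subject),
                bitscore=float(row.bitscore),
                evalue=float(row.evalue),
                query_coverage=cov,
                percent_identity=float(row.pident),
            )
        )
    return edges


def write_similarity_tsv(edges: Iterable[SimilarityEdge], path: str | Path) -> None:
    """Write edges as 13-column tabular BLAST (coverage in the last column)."""
    with open(path, "w") as fh:
        for e in edges:
            aln_len = 100  # placeholder alignment geometry for round-tripping
            fh.write(
                f"{e.query}\t{e.subject}\t{e.percent_identity:.2f}\t{aln_len}\t0\t0\t"
                f"1\t{aln_len}\t1\t{aln_len}\t{e.evalue:.3g}\t{e.bitscore:.1f}\t"
                f"{e.query_coverage:.4f}\n"
            )


def read_presence_absence(path: str | Path) -> pd.DataFrame:
    """Read a family × species 0/1 matrix from TSV (first column = family id)."""
    df = pd.read_csv(str(path), sep="\t", index_col=0)
    if not df.isin([0, 1]).all().all():
        raise ValueError("presence/absence matrix contains values outside {0, 1}")
    return df.astype(int)


def write_presence_absence(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(str(path), sep="\t")


def read_taxon_map(path: str | Path) -> TaxonMap:
    """Read a 2/3-column TSV ``species<TAB>group[<TAB>focal]``; exactly one
    species must be flagged focal (third column ``focal`` or ``1``)."""
    entries: dict[str, str] = {}
    focal = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            species, group = fields[0], fields[1]
            if species in entries:
                raise ValueError(f"species {species!r} listed twice in taxon map")
            entries[species] = group
            if len(fields) > 2 and fields[2].lower() in {"focal", "1", "true"}:
                if focal is not None:
                    raise ValueError("more than one focal species flagged")
                focal = species
    if focal is None:
        raise ValueError("no focal species flagged in taxon map")
    return TaxonMap(entries=entries, focal_species=focal)


def write_taxon_map(taxon_map: TaxonMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for species, group in taxon_map.entries.items():
            flag = "\tfocal" if species == taxon_map.focal_species else ""
            fh.write(f"{species}\t{group}{flag}\n")
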