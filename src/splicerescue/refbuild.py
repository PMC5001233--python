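"""Splice-junction flank reference construction.

Builds, from a UCSC ``knownGene``-style gene table and a genome FASTA, a
collection of exon–exon junction flank sequences and merges them with the
genome into the *expanded genome* used for the first alignment pass.  Each
flank covers the terminal bases of the upstream exon and the initial bases of
the downstream exon, with each side four bases shorter than the read length
(truncated to the exon when the exon is shorter).  Reads that span an
annotated canonical junction therefore align contiguously to a flank record
instead of being reported as unmapped, so only genuinely unannotated splicing
survives to the split stage.

All coordinates are 0-based half-open throughout (the knownGene dump is
already in this convention, and BED output stays in it).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

from pyfaidx import Fasta

#: Reserved prefix that makes junction-record names impossible to confuse with
#: chromosome names ('|' is illegal in FASTA chromosome names in practice and
#: never produced by the synthetic generator).
FLANK_PREFIX = "|jct|"


class KnownGeneParseError(ValueError):
    """A malformed row in a knownGene table, annotated with its line number."""


@dataclass(frozen=True)
class GeneModel:
    """One transcript model from a knownGene table.

    ``exon_starts``/``exon_ends`` are equal-length ascending tuples of 0-based
    half-open exon coordinates.
    """

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_count: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.exon_count != len(self.exon_starts) or self.exon_count != len(self.exon_ends):
            raise ValueError(
                f"gene {self.name}: exonCount {self.exon_count} disagrees with "
                f"exon list lengths {len(self.exon_starts)}/{len(self.exon_ends)}"
            )
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not s < e:
                raise ValueError(f"gene {self.name}: exon [{s}, {e}) is empty or inverted")
        for prev_end, next_start in zip(self.exon_ends, self.exon_starts[1:]):
            if prev_end > next_start:
                raise ValueError(f"gene {self.name}: exons overlap or are unsorted")

    @property
    def introns(self) -> list[tuple[int, int]]:
        """(start, end) of each intron, 0-based half-open."""
        return list(zip(self.exon_ends[:-1], self.exon_starts[1:]))


@dataclass(frozen=True)
class JunctionFlankRecord:
    """Concatenated flank sequence for one annotated exon–exon junction."""

    gene: str
    chrom: str
    left_end: int  # genomic end of the upstream exon (junction donor side)
    right_start: int  # genomic start of the downstream exon (acceptor side)
    left_flank_len: int
    right_flank_len: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.left_flank_len + self.right_flank_len:
            raise ValueError("flank sequence length inconsistent with flank lengths")

    @property
    def id(self) -> str:
        return f"{FLANK_PREFIX}{self.gene}|{self.chrom}|{self.left_end}|{self.right_start}"


def parse_flank_id(record_id: str) -> tuple[str, str, int, int]:
    """Recover (gene, chrom, leftEnd, rightStart) from a flank record id."""
    if not record_id.startswith(FLANK_PREFIX):
        raise ValueError(f"not a junction flank id: {record_id!r}")
    fields = record_id[len(FLANK_PREFIX):].split("|")
    if len(fields) != 4:
        raise ValueError(f"malformed junction flank id: {record_id!r}")
    gene, chrom, left_end, right_start = fields
    try:
        return gene, chrom, int(left_end), int(right_start)
    except ValueError as exc:
        raise ValueError(f"malformed junction flank id: {record_id!r}") from exc


def _parse_exon_list(field: str, line_no: int, what: str) -> tuple[int, ...]:
    try:
        return tuple(int(x) for x in field.rstrip(",").split(",") if x != "")
    except ValueError as exc:
        raise KnownGeneParseError(f"line {line_no}: unparseable {what} list {field!r}") from exc


def parse_known_genes(path: str | Path) -> list[GeneModel]:
    """Parse a UCSC knownGene-format tab-separated table.

    Uses the first ten knownGene columns (name, chrom, strand, txStart, txEnd,
    cdsStart, cdsEnd, exonCount, exonStarts, exonEnds); any trailing columns
    (proteinID, alignID) are ignored.  Exon lists are comma-terminated as in
    UCSC dumps.  Malformed rows raise :class:`KnownGeneParseError` naming the
    offending line.
    """
    genes: list[GeneModel] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise KnownGeneParseError(
                    f"line {line_no}: expected >= 10 tab-separated columns, got {len(fields)}"
                )
            name, chrom, strand = fields[0], fields[1], fields[2]
            try:
                tx_start, tx_end = int(fields[3]), int(fields[4])
                exon_count = int(fields[7])
            except ValueError as exc:
                raise KnownGeneParseError(f"line {line_no}: non-integer coordinate field") from exc
            starts = _parse_exon_list(fields[8], line_no, "exonStarts")
            ends = _parse_exon_list(fields[9], line_no, "exonEnds")
            try:
                genes.append(
                    GeneModel(name, chrom, strand, tx_start, tx_end, exon_count, starts, ends)
                )
            except ValueError as exc:
                raise KnownGeneParseError(f"line {line_no}: {exc}") from exc
    return genes


def build_junction_flanks(
    genes: Iterable[GeneModel],
    genome: Mapping[str, str],
    read_length: int,
) -> list[JunctionFlankRecord]:
    """Build one flank record per adjacent exon pair per gene.

    Each side of the junction contributes ``min(read_length - 4, exon length)``
    bases; junctions shared by overlapping isoforms (same chrom and boundary
    pair) are emitted once, keeping the first gene name encountered.
    """
    if read_length < 6:
        raise ValueError(f"read_length must be >= 6, got {read_length}")
    flank = read_length - 4
    records: dict[tuple[str, int, int], JunctionFlankRecord] = {}
    for gene in genes:
        if gene.chrom not in genome:
            raise KeyError(f"gene {gene.name}: chromosome {gene.chrom!r} absent from genome")
        chrom_seq = genome[gene.chrom]
        for i in range(gene.exon_count - 1):
            left_start, left_end = gene.exon_starts[i], gene.exon_ends[i]
            right_start, right_end = gene.exon_starts[i + 1], gene.exon_ends[i + 1]
            key = (gene.chrom, left_end, right_start)
            if key in records:
                continue
            lf = min(flank, left_end - left_start)
            rf = min(flank, right_end - right_start)
            seq = chrom_seq[left_end - lf:left_end] + chrom_seq[right_start:right_start + rf]
            records[key] = JunctionFlankRecord(
                gene=gene.name,
                chrom=gene.chrom,
                left_end=left_end,
                right_start=right_start,
                left_flank_len=lf,
                right_flank_len=rf,
                sequence=seq,
            )
    return [records[k] for k in sorted(records)]


def build_expanded_genome(
    genome: Mapping[str, str],
    flanks: Iterable[JunctionFlankRecord],
) -> dict[str, str]:
    """Merge genome chromosomes and junction flank records into one collection.

    Genome sequences pass through byte-identical; flank ids must be unique.
    """
    expanded: dict[str, str] = dict(genome)
    for rec in flanks:
        if rec.id in expanded:
            raise ValueError(f"duplicate junction flank id: {rec.id}")
        expanded[rec.id] = rec.sequence
    return expanded


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a (multi-record, wrapped or unwrapped) FASTA into name -> sequence."""
    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


def write_flank_fasta(flanks: Iterable[JunctionFlankRecord], path: str | Path) -> None:
    write_fasta({rec.id: rec.sequence for rec in flanks}, path)
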