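"""Core split-read junction discovery.

An unmapped read that straddles a splice (or endonucleolytic excision) point
cannot align contiguously, but its two sides can.  This module implements the
four stages that turn unmapped reads into junction calls:

1. **split** every unmapped read into all (left, right) decompositions with
   both parts at least the minimum split size MS;
2. **match** the second-pass alignments of those halves into *matched pairs* —
   two halves of the same split of the same read, colinear on one chromosome
   and strand, with a gap (the putative excised region) between the minimum
   candidate distance and the maximum candidate distance MD;
3. **cluster** matched pairs of identical gap length whose positions agree
   within the boundary buffer BB into junctions (single linkage), counting
   support as *distinct origin reads*;
4. **filter/annotate/rank** — drop junctions below the minimum supporting-read
   count, label each as known (an annotated junction of the same length within
   BB) or novel, and rank by support.

Matching is grouped by origin read, so its cost is quadratic only in the
number of half placements of one read, never in the whole half pool.

Junction coordinates are the 0-based half-open (leftEnd, rightStart) of the
excised region; spliced length = rightStart − leftEnd.  On the reverse strand
the read-order upstream half is the one with the larger genomic coordinate,
and coordinates are reported in genomic orientation.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, replace
from pathlib import Path

from .align import Alignment, Read
from .refbuild import JunctionFlankRecord, parse_flank_id


@dataclass(frozen=True)
class Params:
    """Tunable parameters of the junction-discovery pipeline.

    min_split_size (MS): smallest admissible half, bp.  Typically 8 up to a
    third of the read length; smaller values admit more splits (and more
    spurious half placements).
    max_distance (MD): largest admissible gap between the two halves, bp;
    chosen near the gene length scale of the organism (default 40,000).
    min_distance: smallest admissible gap, bp (inclusive; 2 by default, so a
    2 bp excision is the shortest reportable region).
    boundary_buffer (BB): positional tolerance, bp, when one matched pair
    supports another and when junctions are compared across samples.
    min_support: minimum distinct supporting reads per reported junction.
    max_good_alignments: placements above which a query is suppressed.
    """

    min_split_size: int = 8
    max_distance: int = 40_000
    min_distance: int = 2
    boundary_buffer: int = 5
    min_support: int = 2
    max_good_alignments: int = 8

    def __post_init__(self) -> None:
        if self.min_split_size < 1:
            raise ValueError("min_split_size must be >= 1")
        if not 0 < self.min_distance <= self.max_distance:
            raise ValueError("need 0 < min_distance <= max_distance")
        if self.boundary_buffer < 0:
            raise ValueError("boundary_buffer must be >= 0")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.max_good_alignments < 1:
            raise ValueError("max_good_alignments must be >= 1")


@dataclass(frozen=True)
class SplitPair:
    """One decomposition of a read at a candidate splice point."""

    read_id: str
    split_offset: int  # bases in the left part
    left_seq: str
    right_seq: str

    @property
    def left_id(self) -> str:
        return f"{self.read_id}/{self.split_offset}/L"

    @property
    def right_id(self) -> str:
        return f"{self.read_id}/{self.split_offset}/R"


@dataclass(frozen=True, order=True)
class MatchedPair:
    """Two colinear half placements of one split — evidence for one junction."""

    chrom: str
    left_end: int
    right_start: int
    strand: str
    read_id: str
    split_offset: int

    @property
    def gap(self) -> int:
        return self.right_start - self.left_end


@dataclass(frozen=True)
class Junction:
    """A clustered spliced region."""

    chrom: str
    left_end: int
    right_start: int
    strand: str
    support_count: int
    supporting_read_ids: tuple[str, ...]
    status: str = "novel"  # {"novel", "known"}

    @property
    def length(self) -> int:
        return self.right_start - self.left_end

    def __post_init__(self) -> None:
        if self.support_count != len(set(self.supporting_read_ids)):
            raise ValueError("support_count must equal the number of distinct read ids")


def split_read(read: Read, min_split_size: int) -> list[SplitPair]:
    """All decompositions with both parts >= ``min_split_size``.

    A read of length L yields max(0, L − 2·MS + 1) pairs, at split offsets
    MS .. L − MS inclusive.
    """
    L = len(read.seq)
    ms = min_split_size
    return [
        SplitPair(read.id, off, read.seq[:off], read.seq[off:])
        for off in range(ms, L - ms + 1)
    ]


def half_queries(pairs: Iterable[SplitPair]) -> list[tuple[str, str]]:
    """Flatten split pairs into (query_id, sequence) records for pass 2."""
    out = []
    for p in pairs:
        out.append((p.left_id, p.left_seq))
        out.append((p.right_id, p.right_seq))
    return out


def parse_half_id(query_id: str) -> tuple[str, int, str]:
    """Recover (readId, splitOffset, side) from a half query id."""
    head, sep, side = query_id.rpartition("/")
    read_id, sep2, offset = head.rpartition("/")
    if not sep or not sep2 or side not in ("L", "R"):
        raise ValueError(f"unparseable half query id: {query_id!r}")
    try:
        return read_id, int(offset), side
    except ValueError as exc:
        raise ValueError(f"unparseable half query id: {query_id!r}") from exc


def find_matched_pairs(
    half_alignments: Iterable[Alignment],
    params: Params,
) -> list[MatchedPair]:
    """Pair up half alignments into matched pairs.

    For every read and split offset, each (left-half, right-half) placement
    combination is tested: same chromosome, same strand, colinear in read
    orientation, gap within [min_distance, max_distance].  On the '+' strand
    the left (read-order upstream) half must precede the right half
    genomically; on '-' the placements are mirrored.  Output is sorted, hence
    independent of input order.
    """
    by_split: dict[tuple[str, int], dict[str, list[Alignment]]] = defaultdict(
        lambda: {"L": [], "R": []}
    )
    for aln in half_alignments:
        read_id, offset, side = parse_half_id(aln.query_id)
        by_split[(read_id, offset)][side].append(aln)

    pairs: set[MatchedPair] = set()
    for (read_id, offset), sides in by_split.items():
        for left in sides["L"]:
            for right in sides["R"]:
                if left.ref_name != right.ref_name or left.strand != right.strand:
                    continue
                if left.strand == "+":
                    left_end, right_start = left.end, right.start
                else:
                    left_end, right_start = right.end, left.start
                gap = right_start - left_end
                if params.min_distance <= gap <= params.max_distance:
                    pairs.add(
                        MatchedPair(
                            left.ref_name, left_end, right_start,
                            left.strand, read_id, offset,
                        )
                    )
    return sorted(pairs)


def cluster_junctions(matched_pairs: Iterable[MatchedPair], boundary_buffer: int) -> list[Junction]:
    """Single-linkage clustering of matched pairs into junctions.

    Pairs cluster within (chrom, strand, gap length); two pairs link iff their
    leftEnd coordinates differ by at most the boundary buffer (with equal gap
    lengths this also bounds the rightStart difference).  The cluster's
    reported coordinates are the modal (leftEnd, rightStart) of its members,
    ties broken toward the smallest leftEnd; support counts distinct origin
    reads.  Output is sorted by (chrom, leftEnd).
    """
    groups: dict[tuple[str, str, int], list[MatchedPair]] = defaultdict(list)
    for mp in matched_pairs:
        groups[(mp.chrom, mp.strand, mp.gap)].append(mp)

    junctions: list[Junction] = []
    for (chrom, strand, _gap), members in groups.items():
        members.sort(key=lambda mp: (mp.left_end, mp.read_id, mp.split_offset))
        cluster: list[MatchedPair] = []
        for mp in members:
            if cluster and mp.left_end - cluster[-1].left_end > boundary_buffer:
                junctions.append(_make_junction(chrom, strand, cluster))
                cluster = []
            cluster.append(mp)
        if cluster:
            junctions.append(_make_junction(chrom, strand, cluster))
    junctions.sort(key=lambda j: (j.chrom, j.left_end, j.right_start, j.strand))
    return junctions


def _make_junction(chrom: str, strand: str, cluster: Sequence[MatchedPair]) -> Junction:
    coord_votes = Counter((mp.left_end, mp.right_start) for mp in cluster)
    best = max(coord_votes.items(), key=lambda kv: (kv[1], -kv[0][0]))
    (left_end, right_start), _ = best
    read_ids = tuple(sorted({mp.read_id for mp in cluster}))
    return Junction(chrom, left_end, right_start, strand, len(read_ids), read_ids)


def filter_junctions(junctions: Iterable[Junction], min_support: int) -> list[Junction]:
    """Keep junctions with support >= ``min_support``; order preserved."""
    return [j for j in junctions if j.support_count >= min_support]


def annotate_known(
    junctions: Iterable[Junction],
    flanks: Iterable[JunctionFlankRecord | str],
    boundary_buffer: int,
) -> list[Junction]:
    """Label each junction known or novel against the annotated junction set.

    A junction is *known* iff an annotated exon–exon junction exists on the
    same chromosome with the same spliced length and a leftEnd within the
    boundary buffer.  ``flanks`` may be flank records or their ids.
    """
    annotated: dict[tuple[str, int], list[int]] = defaultdict(list)
    for rec in flanks:
        if isinstance(rec, JunctionFlankRecord):
            chrom, left_end, right_start = rec.chrom, rec.left_end, rec.right_start
        else:
            _, chrom, left_end, right_start = parse_flank_id(rec)
        annotated[(chrom, right_start - left_end)].append(left_end)

    out = []
    for j in junctions:
        hits = annotated.get((j.chrom, j.length), [])
        known = any(abs(j.left_end - le) <= boundary_buffer for le in hits)
        out.append(replace(j, status="known" if known else "novel"))
    return out


def rank_junctions(junctions: Iterable[Junction]) -> list[Junction]:
    """Descending support, ties by (chrom, leftEnd)."""
    return sorted(junctions, key=lambda j: (-j.support_count, j.chrom, j.left_end))


# ---------------------------------------------------------------------------
# Output writers


def write_junction_bed(junctions: Sequence[Junction], path: str | Path) -> None:
    """BED6: chrom, leftEnd, rightStart, J<n>|<status>, support, strand."""
    with open(path, "w") as out:
        for n, j in enumerate(junctions, start=1):
            out.write(
                f"{j.chrom}\t{j.left_end}\t{j.right_start}\t"
                f"J{n}|{j.status}\t{j.support_count}\t{j.strand}\n"
            )


def write_junction_detail(junctions: Sequence[Junction], path: str | Path) -> None:
    """Tab-separated: one row per junction with its supporting read ids."""
    with open(path, "w") as out:
        out.write("chrom\tleftEnd\trightStart\tlength\tstrand\tstatus\tsupport\treadIds\n")
        for j in junctions:
            out.write(
                f"{j.chrom}\t{j.left_end}\t{j.right_start}\t{j.length}\t{j.strand}\t"
                f"{j.status}\t{j.support_count}\t{','.join(j.supporting_read_ids)}\n"
            )
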