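"""Case–control junction comparison.

The negative-control subtraction at the heart of the comparative mode: a
junction found in sample A (e.g. a splicing-competent heterozygote) is kept
only if no junction of the same spliced length sits within the boundary
buffer on the same chromosome in sample B (e.g. the knockout control).  Strand
is ignored — junction coordinates are reported in genomic orientation, so the
comparison is strand-agnostic.  The same tolerance BB used for intra-sample
clustering serves as the inter-sample matching tolerance.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .splitcore import Junction, rank_junctions


@dataclass(frozen=True)
class ComparisonRow:
    junction: Junction  # from sample A
    matched_in_b: Optional[Junction]

    @property
    def verdict(self) -> str:
        return "shared" if self.matched_in_b is not None else "unique-to-A"


def _index_by_length(junctions: Iterable[Junction]) -> dict[tuple[str, int], list[Junction]]:
    idx: dict[tuple[str, int], list[Junction]] = defaultdict(list)
    for j in junctions:
        idx[(j.chrom, j.length)].append(j)
    return idx


def best_match(a: Junction, b_index: dict[tuple[str, int], list[Junction]],
               boundary_buffer: int) -> Optional[Junction]:
    """Closest admissible B junction (same chrom and length, leftEnd within BB).

    Ties on |leftEnd difference| go to the smaller leftEnd.
    """
    candidates = [
        b for b in b_index.get((a.chrom, a.length), [])
        if abs(a.left_end - b.left_end) <= boundary_buffer
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda b: (abs(a.left_end - b.left_end), b.left_end))


def subtract_junctions(
    a: Iterable[Junction],
    b: Iterable[Junction],
    boundary_buffer: int,
) -> list[Junction]:
    """Junctions of A with no admissible match in B, ranked by support."""
    b_index = _index_by_length(b)
    unique = [j for j in a if best_match(j, b_index, boundary_buffer) is None]
    return rank_junctions(unique)


def side_by_side_report(
    a: Iterable[Junction],
    b: Iterable[Junction],
    boundary_buffer: int,
) -> list[ComparisonRow]:
    """One row per A junction with its best B match (or none).

    The symmetric report is obtained by swapping the arguments.
    """
    b_index = _index_by_length(b)
    return [
        ComparisonRow(j, best_match(j, b_index, boundary_buffer))
        for j in rank_junctions(a)
    ]


def write_side_by_side(rows: Sequence[ComparisonRow], path: str | Path) -> None:
    """Tab-separated side-by-side file: A columns, B columns, verdict."""
    cols = ["chrom", "leftEnd", "rightStart", "length", "support", "status"]
    header = [f"A_{c}" for c in cols] + [f"B_{c}" for c in cols] + ["verdict"]
    with open(path, "w") as out:
        out.write("\t".join(header) + "\n")
        for row in rows:
            a = row.junction
            a_cells = [a.chrom, a.left_end, a.right_start, a.length, a.support_count, a.status]
            if row.matched_in_b is not None:
                b = row.matched_in_b
                b_cells = [b.chrom, b.left_end, b.right_start, b.length, b.support_count, b.status]
            else:
                b_cells = [""] * len(cols)
            out.write("\t".join(str(c) for c in (*a_cells, *b_cells, row.verdict)) + "\n")
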