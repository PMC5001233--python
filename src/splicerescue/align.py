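"""Two-pass short-read alignment behind a single contract.

The pipeline aligns whole reads against the expanded genome (pass 1) and the
halves of every admissible split of each unmapped read against the plain
genome (pass 2).  Both passes run either through an external bowtie-1
compatible aligner or through the built-in exact-match aligner, which doubles
as the testing oracle: every exact, end-to-end occurrence of the query on the
forward strand and of its reverse complement on the reverse strand, with
reads placed at more than ``max_good_alignments`` equally good loci suppressed
outright (mirroring bowtie's ``-m`` semantics — such reads are mapped, just
ambiguously, so they are discarded rather than treated as splicing
candidates).

Parsers for bowtie's default tabular output and for SAM normalise both
encodings of a placement to the same ``Alignment`` record (0-based, half-open,
reverse-strand SAM positions already being genomic).
"""

from __future__ import annotations

import shutil
import subprocess
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Optional

import pysam

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AlignerConfigurationError(RuntimeError):
    """External aligner missing or misconfigured."""


class AlignmentParseError(ValueError):
    """Truncated or malformed alignment record, annotated with line number."""


@dataclass(frozen=True)
class Read:
    """One input short-read record."""

    id: str
    seq: str
    qual: str = ""


@dataclass(frozen=True, order=True)
class Alignment:
    """One ungapped end-to-end placement of a read (or split half).

    ``start``/``end`` are 0-based half-open genomic coordinates regardless of
    strand; ``alt_count`` is the number of other equally good placements the
    aligner reported for the same query.
    """

    query_id: str
    ref_name: str
    strand: str
    start: int
    end: int
    mismatches: int = 0
    alt_count: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"alignment {self.query_id}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"alignment {self.query_id}: bad strand {self.strand!r}")


@dataclass
class AlignerConfig:
    mode: str = "builtin"  # {"builtin", "external"}
    executable_path: Optional[str] = None
    max_good_alignments: int = 8
    report_unmapped: bool = True
    extra_args: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.max_good_alignments < 1:
            raise ValueError("max_good_alignments must be >= 1")
        if self.mode not in ("builtin", "external"):
            raise ValueError(f"unknown aligner mode {self.mode!r}")


def builtin_align(
    query: str,
    ref: Mapping[str, str],
    max_hits: int,
    query_id: str = "",
) -> list[Alignment]:
    """All exact occurrences of ``query`` (both strands), or [] if suppressed.

    Returns every placement when their number is <= ``max_hits`` and an empty
    list marked as *suppressed* (distinguished from no-occurrence by the
    second element of :func:`builtin_align_status`) otherwise.
    """
    hits, suppressed = builtin_align_status(query, ref, max_hits, query_id)
    return [] if suppressed else hits


def builtin_align_status(
    query: str,
    ref: Mapping[str, str],
    max_hits: int,
    query_id: str = "",
) -> tuple[list[Alignment], bool]:
    """Exact search on both strands; (hits, was_suppressed)."""
    if not query:
        raise ValueError("empty query")
    query = query.upper()
    rc = reverse_complement(query)
    raw: list[tuple[str, str, int]] = []
    for name, seq in ref.items():
        for strand, q in (("+", query), ("-", rc)):
            if strand == "-" and rc == query:
                continue  # palindromic query: forward scan already found it
            pos = seq.find(q)
            while pos != -1:
                raw.append((name, strand, pos))
                if len(raw) > max_hits:
                    return [], True
                pos = seq.find(q, pos + 1)
    n = len(raw)
    hits = [
        Alignment(query_id, name, strand, pos, pos + len(query), 0, n - 1)
        for name, strand, pos in raw
    ]
    return hits, False


def first_pass(
    reads: Iterable[Read],
    ref: Mapping[str, str],
    cfg: AlignerConfig,
) -> tuple[list[Alignment], list[Read]]:
    """Align whole reads against the expanded genome.

    Every input read lands in exactly one of {aligned, unmapped, suppressed};
    suppressed reads (more equally good placements than allowed) appear in
    neither returned collection.
    """
    if cfg.mode == "external":
        return _external_pass(list(reads), ref, cfg)
    alignments: list[Alignment] = []
    unmapped: list[Read] = []
    for read in reads:
        hits, suppressed = builtin_align_status(read.seq, ref, cfg.max_good_alignments, read.id)
        if suppressed:
            continue
        if hits:
            alignments.extend(hits)
        else:
            unmapped.append(read)
    return alignments, unmapped


def second_pass(
    halves: Iterable[tuple[str, str]],
    ref: Mapping[str, str],
    cfg: AlignerConfig,
) -> list[Alignment]:
    """Align split halves (query_id, sequence) against the plain genome.

    Query ids follow the ``<readId>/<splitOffset>/<L|R>`` convention, so the
    origin read and split offset stay recoverable downstream.
    """
    if cfg.mode == "external":
        aligned, _ = _external_pass(
            [Read(qid, seq) for qid, seq in halves], ref, cfg
        )
        return aligned
    alignments: list[Alignment] = []
    for qid, seq in halves:
        hits, suppressed = builtin_align_status(seq, ref, cfg.max_good_alignments, qid)
        if not suppressed:
            alignments.extend(hits)
    return alignments


# ---------------------------------------------------------------------------
# Alignment-format parsers


def parse_bowtie_default(stream: IO[str] | Iterable[str]) -> list[Alignment]:
    """Parse bowtie-1 default tabular output.

    Columns: read name, strand, reference, 0-based offset, sequence,
    qualities, number of other equally good alignments, mismatch descriptors
    (optional, comma-separated).
    """
    alignments = []
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 7:
            raise AlignmentParseError(
                f"line {line_no}: truncated bowtie record ({len(fields)} columns)"
            )
        name, strand, ref_name, offset, seq = fields[0], fields[1], fields[2], fields[3], fields[4]
        try:
            start = int(offset)
            alt = int(fields[6])
        except ValueError as exc:
            raise AlignmentParseError(f"line {line_no}: non-integer field") from exc
        mm = 0
        if len(fields) > 7 and fields[7]:
            mm = fields[7].count(":")
        alignments.append(Alignment(name, ref_name, strand, start, start + len(seq), mm, alt))
    return alignments


def parse_sam(
    source: str | Path | IO,
    unmapped: Optional[list[str]] = None,
) -> list[Alignment]:
    """Parse SAM into the same Alignment convention as the bowtie parser.

    Reverse-strand records (FLAG 0x10) keep their genomic coordinates and are
    tagged strand '-'.  Unmapped records (FLAG 0x4) yield no Alignment; their
    query names are appended to ``unmapped`` when a list is supplied.
    """
    alignments = []
    if isinstance(source, Path):
        source = str(source)
    with pysam.AlignmentFile(source, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                if unmapped is not None:
                    unmapped.append(rec.query_name)
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            alignments.append(
                Alignment(
                    rec.query_name,
                    rec.reference_name,
                    "-" if rec.is_reverse else "+",
                    rec.reference_start,
                    rec.reference_end,
                    int(nm),
                    int(rec.get_tag("X1")) if rec.has_tag("X1") else 0,
                )
            )
    return alignments


# ---------------------------------------------------------------------------
# External bowtie-1 compatible driver


def _external_pass(
    reads: list[Read],
    ref: Mapping[str, str],
    cfg: AlignerConfig,
) -> tuple[list[Alignment], list[Read]]:
    """Run a bowtie-1 compatible aligner: index, align, parse, split unmapped."""
    import tempfile

    from . import refbuild

    exe = cfg.executable_path or "bowtie"
    if shutil.which(exe) is None:
        raise AlignerConfigurationError(f"external aligner executable not found: {exe!r}")
    build = shutil.which(exe + "-build") or (exe + "-build")
    with tempfile.TemporaryDirectory(prefix="splicerescue-aln-") as tmp:
        tmpdir = Path(tmp)
        ref_fa = tmpdir / "ref.fa"
        refbuild.write_fasta(ref, ref_fa)
        idx = tmpdir / "index"
        try:
            subprocess.run(
                [build, "-q", str(ref_fa), str(idx)],
                check=True, capture_output=True, text=True,
            )
        except (OSError, subprocess.CalledProcessError) as exc:
            raise AlignerConfigurationError(f"reference index build failed: {exc}") from exc
        reads_path = tmpdir / "reads.fa"
        with open(reads_path, "w") as out:
            for r in reads:
                out.write(f">{r.id}\n{r.seq}\n")
        out_path = tmpdir / "hits.bowtie"
        un_path = tmpdir / "unmapped.fa"
        cmd = [
            exe, "-f", "-a", "-m", str(cfg.max_good_alignments),
            "--un", str(un_path), *cfg.extra_args,
            str(idx), str(reads_path), str(out_path),
        ]
        try:
            subprocess.run(cmd, check=True, capture_output=True, text=True)
        except subprocess.CalledProcessError as exc:
            raise AlignerConfigurationError(f"external aligner failed: {exc.stderr}") from exc
        with open(out_path) as handle:
            alignments = parse_bowtie_default(handle)
        unmapped: list[Read] = []
        if un_path.exists():
            by_id = {r.id: r for r in reads}
            for name, seq in _iter_fasta(un_path):
                unmapped.append(by_id.get(name, Read(name, seq)))
    return alignments, unmapped


def _iter_fasta(path: Path):
    name, chunks = None, []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)
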