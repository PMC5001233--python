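"""Self-contained synthetic fixtures with machine-readable ground truth.

Emulates the biological setting the pipeline targets: a stress-responsive
transcription factor whose mRNA loses a short segment (26 nt by default,
mirroring the cytosolic endonucleolytic excision from Xbp1 during the
unfolded protein response) in splicing-competent heterozygote (Het) cells but
never in knockout (KO) control cells.  The generator produces

* a small multi-chromosome genome with no repeated k-mer at read length (so
  exact alignment is unique), rejection-sampled;
* a knownGene-format table with one canonical multi-exon gene and one
  single-exon target gene;
* Het and KO FASTQ read sets drawn uniformly from the mature transcripts,
  error-free, constant quality Phred 40 (Phred+33);
* a truth record naming the engineered junction.

The Het spliced-transcript pool always contains a few *anchor* reads spanning
the excision point at evenly spaced offsets, so the promised minimum support
holds by construction for every seed; the remaining coverage is uniform.

Default geometry mirrors the thapsigargin-treatment experiment the method was
demonstrated on: 33 bp reads with pipeline parameters MS 8, MD 40,000, BB 5,
minimum gap 2, minimum support 2.
"""

from __future__ import annotations

import random
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

from .align import Read
from .refbuild import GeneModel

DEFAULT_SEED = 1234
DEFAULT_READ_LENGTH = 33
DEFAULT_EXCISION_LENGTH = 26
DEFAULT_COVERAGE = 20.0

CANONICAL_GENE = "housekeep1"
TARGET_GENE = "stressTF1"

_QUAL_CHAR = "I"  # Phred 40, Phred+33


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one engineered non-canonical excision."""

    chrom: str
    left_end: int
    right_start: int
    min_het_support: int  # spanning reads guaranteed in Het, >= 2 distinct offsets
    seed: int
    coverage: float
    read_length: int

    @property
    def length(self) -> int:
        return self.right_start - self.left_end


class FixtureError(ValueError):
    """Requested fixture parameters cannot satisfy the generator's promises."""


def _random_sequence(rng: random.Random, length: int, gc_content: float) -> str:
    weights = [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    return "".join(rng.choices("ACGT", weights=weights, k=length))


def _kmers_unique(chroms: Sequence[str], k: int) -> bool:
    from .align import reverse_complement

    seen: set[str] = set()
    for seq in chroms:
        for s in (seq, reverse_complement(seq)):
            for i in range(len(s) - k + 1):
                kmer = s[i:i + k]
                if kmer in seen:
                    return False
                seen.add(kmer)
    return True


def make_genome(
    seed: int = DEFAULT_SEED,
    n_chrom: int = 2,
    chrom_length: int = 10_000,
    gc_content: float = 0.5,
    read_length: int = DEFAULT_READ_LENGTH,
    max_attempts: int = 50,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome plus gene models, deterministic for a fixed seed.

    chr1 carries a three-exon gene with canonical introns; the last chromosome
    carries the single-exon target gene that hosts the engineered excision.
    The genome is rejection-sampled until no ``read_length``-mer repeats
    anywhere (either strand), which makes exact alignment of every genomic
    read unique.
    """
    if n_chrom < 1:
        raise FixtureError("n_chrom must be >= 1")
    if chrom_length < 10 * read_length:
        raise FixtureError(f"chrom_length must be >= 10 * read_length = {10 * read_length}")
    rng = random.Random(seed)
    for _ in range(max_attempts):
        chroms = [_random_sequence(rng, chrom_length, gc_content) for _ in range(n_chrom)]
        if _kmers_unique(chroms, read_length):
            break
    else:
        raise FixtureError(
            f"could not generate a genome with unique {read_length}-mers "
            f"in {max_attempts} attempts; increase chrom_length or read_length"
        )
    genome = {f"chr{i + 1}": seq for i, seq in enumerate(chroms)}

    exon_len = max(read_length, (3 * chrom_length) // 100)
    intron_len = max(2 * read_length, (5 * chrom_length) // 100)
    canon_start = chrom_length // 10
    starts, ends = [], []
    pos = canon_start
    for _ in range(3):
        starts.append(pos)
        ends.append(pos + exon_len)
        pos += exon_len + intron_len
    if pos - intron_len > chrom_length:
        raise FixtureError("chrom_length too small for the canonical gene layout")
    canonical = GeneModel(
        CANONICAL_GENE, "chr1", "+", starts[0], ends[-1], 3, tuple(starts), tuple(ends)
    )

    target_chrom = f"chr{n_chrom}"
    t_start = chrom_length // 5
    t_len = max(6 * read_length, (12 * chrom_length) // 100)
    if t_start + t_len > chrom_length:
        raise FixtureError("chrom_length too small for the target gene layout")
    target = GeneModel(
        TARGET_GENE, target_chrom, "+", t_start, t_start + t_len, 1,
        (t_start,), (t_start + t_len,),
    )
    return genome, [canonical, target]


def _spliced_transcript(seq: str, gene: GeneModel) -> str:
    return "".join(seq[s:e] for s, e in zip(gene.exon_starts, gene.exon_ends))


def _sample_reads(
    rng: random.Random,
    transcript: str,
    n_reads: int,
    read_length: int,
    prefix: str,
    forced_starts: Sequence[int] = (),
) -> list[Read]:
    n_pos = len(transcript) - read_length + 1
    if n_pos < 1:
        raise FixtureError("transcript shorter than read length")
    reads = []
    starts = list(forced_starts)
    starts += [rng.randrange(n_pos) for _ in range(max(0, n_reads - len(starts)))]
    for i, s in enumerate(starts):
        reads.append(Read(f"{prefix}:{i}", transcript[s:s + read_length], _QUAL_CHAR * read_length))
    return reads


def _anchor_excision(chrom_seq: str, preferred: int, excision_length: int,
                     max_shift: int = 30) -> int:
    """Pick an excision start near ``preferred`` with no boundary micro-homology.

    If the bases just inside either boundary match the bases just outside the
    opposite one, a junction-spanning read can be split one base earlier or
    later and still align, so the reported coordinates become ambiguous (a
    real phenomenon at splice sites with terminal repeats).  Requiring
    inequality at both innermost boundary bases blocks every such shift and
    makes coordinate recovery exact.
    """
    for delta in sorted(range(-max_shift, max_shift + 1), key=abs):
        left_end = preferred + delta
        right_start = left_end + excision_length
        if (chrom_seq[left_end - 1] != chrom_seq[right_start - 1]
                and chrom_seq[left_end] != chrom_seq[right_start]):
            return left_end
    raise FixtureError("no homology-free excision boundary near the target midpoint")


def make_case_control_reads(
    genome: dict[str, str],
    genes: Sequence[GeneModel],
    coverage: float = DEFAULT_COVERAGE,
    read_length: int = DEFAULT_READ_LENGTH,
    seed: int = DEFAULT_SEED,
    excision_length: int = DEFAULT_EXCISION_LENGTH,
    min_split_size: int = 8,
    min_support: int = 2,
    error_rate: float = 0.0,
) -> tuple[list[Read], list[Read], SyntheticTruth]:
    """Draw Het and KO read pools; return them with the engineered truth.

    Both samples receive uniform coverage of the canonical gene's mRNA and of
    the unspliced target transcript; the Het sample additionally receives the
    excised (spliced) target transcript, seeded with ``min_support + 2``
    anchor reads spanning the excision point at distinct offsets with at
    least ``min_split_size`` bases on each side.  KO reads never cross the
    excision boundary in spliced form.

    ``error_rate`` applies uniform substitution errors per base; the spanning
    promise is only guaranteed at the error-free default of 0.
    """
    if read_length < 2 * min_split_size:
        raise FixtureError("read_length must be >= 2 * min_split_size")
    genes_by_name = {g.name: g for g in genes}
    canonical = genes_by_name[CANONICAL_GENE]
    target = genes_by_name[TARGET_GENE]

    t_start, t_end = target.tx_start, target.tx_end
    chrom_seq = genome[target.chrom]
    mid = (t_start + t_end) // 2
    left_end = _anchor_excision(chrom_seq, mid, excision_length)
    right_start = left_end + excision_length
    if left_end - t_start < read_length or t_end - right_start < read_length:
        raise FixtureError("target gene too short to host the excision with read-length flanks")
    unspliced = chrom_seq[t_start:t_end]
    spliced = chrom_seq[t_start:left_end] + chrom_seq[right_start:t_end]
    canonical_mrna = _spliced_transcript(genome[canonical.chrom], canonical)

    def n_reads(transcript: str) -> int:
        return max(1, round(coverage * len(transcript) / read_length))

    # anchor reads: evenly spaced split offsets across the admissible window
    p = left_end - t_start  # excision point in spliced-transcript coordinates
    lo, hi = p - (read_length - min_split_size), p - min_split_size
    n_anchor = min_support + 2
    if hi < lo:
        raise FixtureError("no admissible spanning offset; decrease min_split_size")
    anchor_starts = sorted({lo + round(i * (hi - lo) / max(1, n_anchor - 1))
                            for i in range(n_anchor)})
    n_spliced = n_reads(spliced)
    if n_spliced < len(anchor_starts):
        min_cov = len(anchor_starts) * read_length / len(spliced)
        raise FixtureError(
            f"coverage {coverage} too low to guarantee {len(anchor_starts)} spanning "
            f"reads; use coverage >= {min_cov:.2f}"
        )

    rng = random.Random(seed + 1)
    het: list[Read] = []
    het += _sample_reads(rng, canonical_mrna, n_reads(canonical_mrna), read_length, "het:canon")
    het += _sample_reads(rng, unspliced, n_reads(unspliced), read_length, "het:target_u")
    het += _sample_reads(rng, spliced, n_spliced, read_length, "het:target_s", anchor_starts)

    rng_ko = random.Random(seed + 2)
    ko: list[Read] = []
    ko += _sample_reads(rng_ko, canonical_mrna, n_reads(canonical_mrna), read_length, "ko:canon")
    ko += _sample_reads(rng_ko, unspliced, n_reads(unspliced), read_length, "ko:target_u")

    if error_rate > 0:
        het = _apply_substitution_errors(rng, het, error_rate)
        ko = _apply_substitution_errors(rng_ko, ko, error_rate)

    truth = SyntheticTruth(
        chrom=target.chrom,
        left_end=left_end,
        right_start=right_start,
        min_het_support=len(anchor_starts),
        seed=seed,
        coverage=coverage,
        read_length=read_length,
    )
    return het, ko, truth


def _apply_substitution_errors(
    rng: random.Random, reads: list[Read], rate: float
) -> list[Read]:
    out = []
    for r in reads:
        seq = list(r.seq)
        for i, base in enumerate(seq):
            if rng.random() < rate:
                seq[i] = rng.choice([b for b in "ACGT" if b != base])
        out.append(Read(r.id, "".join(seq), r.qual))
    return out


# ---------------------------------------------------------------------------
# File output


def write_fastq(reads: Sequence[Read], path: str | Path) -> None:
    with open(path, "w") as out:
        for r in reads:
            out.write(f"@{r.id}\n{r.seq}\n+\n{r.qual or _QUAL_CHAR * len(r.seq)}\n")


def write_known_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    """UCSC knownGene-format dump (12 columns, comma-terminated exon lists)."""
    with open(path, "w") as out:
        for g in genes:
            starts = ",".join(str(s) for s in g.exon_starts) + ","
            ends = ",".join(str(e) for e in g.exon_ends) + ","
            out.write(
                f"{g.name}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t"
                f"{g.tx_start}\t{g.tx_end}\t{g.exon_count}\t{starts}\t{ends}\t\t\n"
            )


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("chrom\tleftEnd\trightStart\tlength\tminHetSupport\tseed\tcoverage\treadLength\n")
        out.write(
            f"{truth.chrom}\t{truth.left_end}\t{truth.right_start}\t{truth.length}\t"
            f"{truth.min_het_support}\t{truth.seed}\t{truth.coverage}\t{truth.read_length}\n"
        )


def read_truth(path: str | Path) -> SyntheticTruth:
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        row = handle.readline().rstrip("\n").split("\t")
    rec = dict(zip(header, row))
    return SyntheticTruth(
        chrom=rec["chrom"],
        left_end=int(rec["leftEnd"]),
        right_start=int(rec["rightStart"]),
        min_het_support=int(rec["minHetSupport"]),
        seed=int(rec["seed"]),
        coverage=float(rec["coverage"]),
        read_length=int(rec["readLength"]),
    )


def generate_fixture(
    out_dir: str | Path,
    seed: int = DEFAULT_SEED,
    n_chrom: int = 2,
    chrom_length: int = 10_000,
    gc_content: float = 0.5,
    coverage: float = DEFAULT_COVERAGE,
    read_length: int = DEFAULT_READ_LENGTH,
    excision_length: int = DEFAULT_EXCISION_LENGTH,
    min_split_size: int = 8,
    min_support: int = 2,
) -> dict[str, Path | SyntheticTruth]:
    """Write genome.fa, genes.txt, het.fastq, ko.fastq and truth.tsv."""
    from .refbuild import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, genes = make_genome(seed, n_chrom, chrom_length, gc_content, read_length)
    het, ko, truth = make_case_control_reads(
        genome, genes, coverage, read_length, seed, excision_length,
        min_split_size, min_support,
    )
    paths: dict[str, Path | SyntheticTruth] = {
        "genome": out / "genome.fa",
        "known_genes": out / "genes.txt",
        "het_fastq": out / "het.fastq",
        "ko_fastq": out / "ko.fastq",
        "truth_file": out / "truth.tsv",
        "truth": truth,
    }
    write_fasta(genome, paths["genome"])
    write_known_gene_table(genes, paths["known_genes"])
    write_fastq(het, paths["het_fastq"])
    write_fastq(ko, paths["ko_fastq"])
    write_truth(truth, paths["truth_file"])
    return paths
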