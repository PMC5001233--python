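"""Independent test oracles and random-instance generators.

The brute-force matched-pair scan reproduces the pre-optimization behaviour
(compare every half alignment against every other) and stays deliberately
independent of the grouped implementation it checks.
"""

from __future__ import annotations

import random

from splicerescue.align import Alignment
from splicerescue.splitcore import MatchedPair, Params, parse_half_id


def brute_force_matched_pairs(alignments, params: Params) -> set[MatchedPair]:
    """All-pairs scan over every half alignment (quadratic in the pool)."""
    parsed = [(a, *parse_half_id(a.query_id)) for a in alignments]
    pairs: set[MatchedPair] = set()
    for a, read_a, off_a, side_a in parsed:
        if side_a != "L":
            continue
        for b, read_b, off_b, side_b in parsed:
            if side_b != "R" or read_a != read_b or off_a != off_b:
                continue
            if a.ref_name != b.ref_name or a.strand != b.strand:
                continue
            if a.strand == "+":
                left_end, right_start = a.end, b.start
            else:
                left_end, right_start = b.end, a.start
            gap = right_start - left_end
            if params.min_distance <= gap <= params.max_distance:
                pairs.add(MatchedPair(a.ref_name, left_end, right_start,
                                      a.strand, read_a, off_a))
    return pairs


def random_half_alignments(
    seed: int,
    n_halves: int = 1000,
    read_length: int = 33,
    min_split: int = 8,
    n_chrom: int = 3,
    chrom_length: int = 100_000,
    multi_hit_rate: float = 0.2,
) -> list[Alignment]:
    """A random pool of half alignments with realistic id structure.

    Roughly half the halves are left sides; a fraction get a second placement
    so that multi-mapping combinations are exercised.
    """
    rng = random.Random(seed)
    out: list[Alignment] = []
    read_idx = 0
    while len(out) < n_halves:
        read_idx += 1
        read_id = f"r{read_idx}"
        n_offsets = rng.randint(1, 4)
        offsets = rng.sample(range(min_split, read_length - min_split + 1), n_offsets)
        for off in offsets:
            for side, length in (("L", off), ("R", read_length - off)):
                if rng.random() < 0.15:  # this half failed to align
                    continue
                n_placements = 2 if rng.random() < multi_hit_rate else 1
                for _ in range(n_placements):
                    chrom = f"chr{rng.randint(1, n_chrom)}"
                    strand = rng.choice("+-")
                    start = rng.randrange(chrom_length - length)
                    out.append(
                        Alignment(f"{read_id}/{off}/{side}", chrom, strand,
                                  start, start + length)
                    )
    return out[:n_halves]
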