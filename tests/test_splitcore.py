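"""Split enumeration, matched-pair detection, clustering, filtering, ranking."""

import pytest
from hypothesis import given, strategies as st

from splicerescue.align import Alignment, Read
from splicerescue.splitcore import (
    Junction,
    MatchedPair,
    Params,
    annotate_known,
    cluster_junctions,
    filter_junctions,
    find_matched_pairs,
    parse_half_id,
    rank_junctions,
    split_read,
)
from tests.oracles import brute_force_matched_pairs, random_half_alignments

P = Params()  # MS 8, MD 40000, minCD 2, BB 5, minSupport 2, maxGood 8


def _read(length: int) -> Read:
    return Read("r", ("ACGT" * (length // 4 + 1))[:length])


@given(length=st.integers(0, 120), ms=st.integers(1, 40))
def test_split_count_law_and_reconstruction(length, ms):
    """Number of split pairs is max(0, L - 2*MS + 1); halves reconstruct the
    read and offsets run MS .. L - MS inclusive."""
    read = _read(length)
    pairs = split_read(read, ms)
    assert len(pairs) == max(0, length - 2 * ms + 1)
    offsets = [p.split_offset for p in pairs]
    assert offsets == list(range(ms, length - ms + 1))
    for p in pairs:
        assert p.left_seq + p.right_seq == read.seq
        assert len(p.left_seq) >= ms and len(p.right_seq) >= ms


@pytest.mark.parametrize("length, ms, expected", [(33, 8, 18), (16, 8, 1), (15, 8, 0)])
def test_split_count_examples(length, ms, expected):
    assert len(split_read(_read(length), ms)) == expected


def test_half_id_round_trip():
    pair = split_read(Read("read:7", "A" * 16), 8)[0]
    assert parse_half_id(pair.left_id) == ("read:7", 8, "L")
    assert parse_half_id(pair.right_id) == ("read:7", 8, "R")
    with pytest.raises(ValueError, match="unparseable"):
        parse_half_id("nonsense")


def _halves(read_id, offset, left, right):
    """Left/right half alignments: (chrom, strand, start, end) tuples."""
    return [
        Alignment(f"{read_id}/{offset}/L", *left),
        Alignment(f"{read_id}/{offset}/R", *right),
    ]


def test_matched_pair_gap_26_accepted():
    alns = _halves("r1", 10, ("chr1", "+", 100, 110), ("chr1", "+", 136, 159))
    (mp,) = find_matched_pairs(alns, P)
    assert (mp.chrom, mp.left_end, mp.right_start, mp.gap) == ("chr1", 110, 136, 26)
    assert brute_force_matched_pairs(alns, P) == {mp}


@pytest.mark.parametrize(
    "left, right",
    [
        (("chr1", "+", 100, 110), ("chr1", "+", 111, 134)),  # gap 1 < minCD 2
        (("chr1", "+", 100, 110), ("chr2", "+", 136, 159)),  # different chromosome
        (("chr1", "+", 100, 110), ("chr1", "+", 40111, 40134)),  # gap 40001 > MD
        (("chr1", "+", 100, 110), ("chr1", "-", 136, 159)),  # strand mismatch
        (("chr1", "+", 200, 210), ("chr1", "+", 100, 123)),  # anti-colinear
    ],
)
def test_matched_pair_rejections(left, right):
    assert find_matched_pairs(_halves("r1", 10, left, right), P) == []


def test_matched_pair_minus_strand_reports_genomic_orientation():
    """On '-' the read-order upstream (L) half has the larger coordinate."""
    alns = _halves("r1", 10, ("chr1", "-", 500, 510), ("chr1", "-", 450, 473))
    (mp,) = find_matched_pairs(alns, P)
    assert (mp.left_end, mp.right_start, mp.strand) == (473, 500, "-")


def test_matched_pairs_only_combine_same_split_offset():
    alns = [
        Alignment("r1/10/L", "chr1", "+", 100, 110),
        Alignment("r1/12/R", "chr1", "+", 136, 157),
    ]
    assert find_matched_pairs(alns, P) == []


@pytest.mark.parametrize("seed", range(20))
def test_grouped_matching_equals_brute_force_scan(seed):
    """Grouped detection is set-identical to the all-pairs quadratic scan on
    random pools of 1000 half alignments."""
    alns = random_half_alignments(seed, n_halves=1000)
    params = Params(max_distance=50_000)
    assert set(find_matched_pairs(alns, params)) == brute_force_matched_pairs(alns, params)


def test_matching_output_independent_of_input_order():
    alns = random_half_alignments(99, n_halves=200)
    assert find_matched_pairs(alns, P) == find_matched_pairs(list(reversed(alns)), P)


def _mp(read_id, left_end, gap=26, chrom="chr1", strand="+", offset=10):
    return MatchedPair(chrom, left_end, left_end + gap, strand, read_id, offset)


def test_cluster_within_buffer_counts_distinct_reads():
    pairs = [_mp("r1", 110), _mp("r2", 113)]
    (j,) = cluster_junctions(pairs, boundary_buffer=5)
    assert j.support_count == 2
    assert j.supporting_read_ids == ("r1", "r2")


def test_cluster_requires_equal_spliced_length():
    pairs = [_mp("r1", 110, gap=26), _mp("r2", 110, gap=27)]
    assert len(cluster_junctions(pairs, 5)) == 2


def test_one_read_with_two_offsets_counts_once():
    pairs = [_mp("r1", 110, offset=10), _mp("r1", 110, offset=12)]
    (j,) = cluster_junctions(pairs, 5)
    assert j.support_count == 1


def test_cluster_representative_is_modal_then_smallest_left_end():
    pairs = [_mp("r1", 110), _mp("r2", 110), _mp("r3", 112), _mp("r4", 114), _mp("r5", 114)]
    (j,) = cluster_junctions(pairs, 5)
    assert j.left_end == 110  # two-way modal tie 110 vs 114 -> smaller leftEnd


def test_cluster_chains_beyond_buffer_split():
    pairs = [_mp("r1", 100), _mp("r2", 104), _mp("r3", 120)]
    junctions = cluster_junctions(pairs, 5)
    assert [j.support_count for j in junctions] == [2, 1]


@given(st.lists(
    st.tuples(st.integers(0, 60), st.sampled_from(["a", "b", "c", "d"])),
    min_size=1, max_size=25,
))
def test_cluster_refinement_property(entries):
    """Single-linkage clusters at buffer b refine clusters at b' >= b."""
    pairs = [_mp(rid + str(i), le) for i, (le, rid) in enumerate(entries)]

    def memberships(bb):
        out = []
        for j in cluster_junctions(pairs, bb):
            out.append(frozenset(j.supporting_read_ids))
        return out

    for small, big in ((1, 4), (2, 8), (0, 2)):
        coarse = memberships(big)
        for cluster in memberships(small):
            assert sum(cluster <= c for c in coarse) >= 1


def test_filter_junctions_boundary_and_order():
    j1 = Junction("chr1", 10, 36, "+", 1, ("a",))
    j2 = Junction("chr1", 50, 76, "+", 2, ("a", "b"))
    assert filter_junctions([j1, j2], 2) == [j2]
    assert filter_junctions([j2, j1], 2) == [j2]
    assert filter_junctions([], 2) == []


def test_annotate_known_by_length_and_position(toy_genome):
    from splicerescue.refbuild import build_junction_flanks

    genome, genes = toy_genome
    flanks = build_junction_flanks(genes, genome, 33)
    rec = flanks[0]
    length = rec.right_start - rec.left_end
    reads = ("a", "b")
    exact = Junction(rec.chrom, rec.left_end, rec.right_start, "+", 2, reads)
    shifted_in = Junction(rec.chrom, rec.left_end + 5, rec.right_start + 5, "+", 2, reads)
    shifted_out = Junction(rec.chrom, rec.left_end + 6, rec.right_start + 6, "+", 2, reads)
    inside_exon = Junction(rec.chrom, rec.left_end - length - 40,
                           rec.left_end - 40, "+", 2, reads)
    out = annotate_known([exact, shifted_in, shifted_out, inside_exon], flanks, 5)
    assert [j.status for j in out] == ["known", "known", "novel", "novel"]


def test_rank_by_support_then_coordinate():
    js = [
        Junction("chr2", 10, 36, "+", 2, ("a", "b")),
        Junction("chr1", 90, 116, "+", 5, ("a", "b", "c", "d", "e")),
        Junction("chr1", 40, 66, "+", 2, ("a", "b")),
    ]
    ranked = rank_junctions(js)
    assert [(j.support_count, j.chrom, j.left_end) for j in ranked] == [
        (5, "chr1", 90), (2, "chr1", 40), (2, "chr2", 10),
    ]
    assert rank_junctions([js[0]]) == [js[0]]


def _call_at(half_alignments, read_lengths, params):
    admissible = []
    for a in half_alignments:
        read_id, offset, _side = parse_half_id(a.query_id)
        if (offset >= params.min_split_size
                and read_lengths[read_id] - offset >= params.min_split_size):
            admissible.append(a)
    return set(find_matched_pairs(admissible, params))


def test_parameter_monotonicity_on_synthetic_run(het_half_pool):
    """Matched-pair sets shrink as MS grows and grow as MD grows."""
    pool = het_half_pool["half_alignments"]
    lengths = {r.id: len(r.seq) for r in het_half_pool["unmapped"]}
    base = Params()
    by_ms = {ms: _call_at(pool, lengths, Params(min_split_size=ms)) for ms in (8, 10, 12, 14)}
    assert by_ms[8]  # the engineered junction produces pairs
    for lo, hi in ((8, 10), (10, 12), (12, 14)):
        assert by_ms[hi] <= by_ms[lo]
    by_md = {md: _call_at(pool, lengths, Params(max_distance=md)) for md in (30, 1000, 40_000)}
    assert by_md[30] <= by_md[1000] <= by_md[40_000]


def test_support_conservation(het_half_pool):
    """Total junction support never exceeds the number of unmapped reads."""
    pool = het_half_pool["half_alignments"]
    pairs = find_matched_pairs(pool, Params())
    junctions = cluster_junctions(pairs, 5)
    assert sum(j.support_count for j in junctions) <= len(het_half_pool["unmapped"])


def test_engineered_junction_ranked_first(het_half_pool):
    truth = het_half_pool["truth"]
    pairs = find_matched_pairs(het_half_pool["half_alignments"], Params())
    junctions = filter_junctions(cluster_junctions(pairs, 5), 2)
    top = rank_junctions(junctions)[0]
    assert (top.chrom, top.left_end, top.right_start) == (
        truth.chrom, truth.left_end, truth.right_start
    )
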