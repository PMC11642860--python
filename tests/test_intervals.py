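"""Interval set algebra against brute-force oracles and tool semantics."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riescreen.intervals import (
    GenomicInterval,
    IntervalSet,
    assert_mutually_disjoint,
    count_overlaps,
    intersect_any,
    merge_within_gap,
    read_bed,
    sort_intervals,
    subtract_nonoverlapping,
    write_bed,
)

from conftest import brute_count_overlaps, brute_merge, random_intervals


def iv(chrom, start, end, name=None):
    return GenomicInterval(chrom, start, end, name)


class TestGenomicInterval:
    def test_rejects_malformed_records(self):
        with pytest.raises(ValueError, match="start >= end"):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError, match="negative start"):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError, match="chrom"):
            GenomicInterval("", 0, 10)

    def test_bookended_intervals_do_not_overlap(self):
        assert not iv("chr1", 0, 10).overlaps(iv("chr1", 10, 20))
        assert iv("chr1", 0, 11).overlaps(iv("chr1", 10, 20))


class TestSort:
    def test_empty_and_idempotent(self):
        assert len(sort_intervals(IntervalSet())) == 0
        s = sort_intervals(IntervalSet([iv("chr1", 5, 9), iv("chr1", 1, 3)]))
        assert sort_intervals(s) == s

    def test_matches_naive_tuple_sort(self, rng):
        s = random_intervals(rng, 100)
        reversed_set = IntervalSet(list(s)[::-1])
        expected = sorted((x.chrom, x.start, x.end) for x in s)
        got = [(x.chrom, x.start, x.end) for x in sort_intervals(reversed_set)]
        assert got == expected
        assert sort_intervals(reversed_set).sorted_flag


class TestMergeWithinGap:
    def test_gap_at_most_300_merges(self):
        s = IntervalSet([iv("chr1", 100, 200), iv("chr1", 350, 400)])
        merged = merge_within_gap(s, 300)
        assert [(x.start, x.end) for x in merged] == [(100, 400)]

    def test_gap_above_300_does_not_merge(self):
        s = IntervalSet([iv("chr1", 100, 200), iv("chr1", 501, 600)])
        merged = merge_within_gap(s, 300)
        assert len(merged) == 2

    def test_bookended_merge_at_gap_zero(self):
        s = IntervalSet([iv("chr1", 0, 10), iv("chr1", 10, 20)])
        assert [(x.start, x.end) for x in merge_within_gap(s, 0)] == [(0, 20)]

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_within_gap(IntervalSet(), -1)

    @pytest.mark.parametrize("gap", [0, 300])
    def test_matches_union_find_oracle(self, gap):
        rng = np.random.default_rng(7)
        s = random_intervals(rng, 1000, max_pos=100_000)
        merged = merge_within_gap(s, gap)
        assert [(x.chrom, x.start, x.end) for x in merged] == brute_merge(s, gap)

    @given(st.integers(0, 500), st.integers(0, 5_000))
    @settings(max_examples=30, deadline=None)
    def test_idempotent(self, seed, gap):
        s = random_intervals(np.random.default_rng(seed), 40)
        once = merge_within_gap(s, gap)
        assert merge_within_gap(once, gap) == once

    @given(st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_smaller_gap_refines_larger(self, seed):
        s = random_intervals(np.random.default_rng(seed), 50)
        fine = merge_within_gap(s, 50)
        coarse = merge_within_gap(s, 400)
        for f in fine:
            containers = [
                c for c in coarse
                if c.chrom == f.chrom and c.start <= f.start and f.end <= c.end
            ]
            assert len(containers) == 1

    def test_output_separation_exceeds_gap(self, rng):
        merged = merge_within_gap(random_intervals(rng, 300), 120)
        by_chrom: dict = {}
        for x in merged:
            by_chrom.setdefault(x.chrom, []).append(x)
        for ivs in by_chrom.values():
            for a, b in zip(ivs, ivs[1:]):
                assert b.start - a.end > 120


class TestOverlapOps:
    def test_self_intersection_identity(self, rng):
        a = random_intervals(rng, 50)
        assert intersect_any(a, a) == a

    def test_chromosome_disjoint_sets(self):
        a = IntervalSet([iv("chr1", 0, 100)])
        b = IntervalSet([iv("chr2", 0, 100)])
        assert len(intersect_any(a, b)) == 0
        assert subtract_nonoverlapping(a, b) == a

    def test_subtract_empty_and_self(self, rng):
        a = random_intervals(rng, 30)
        assert subtract_nonoverlapping(a, IntervalSet()) == a
        assert len(subtract_nonoverlapping(a, a)) == 0

    def test_count_against_empty_and_nested(self):
        a = IntervalSet([iv("chr1", 100, 500)])
        assert list(count_overlaps(a, IntervalSet())) == [0]
        b = IntervalSet([iv("chr1", 100, 200), iv("chr1", 250, 300), iv("chr1", 400, 600)])
        assert list(count_overlaps(a, b)) == [3]

    def test_record_identity_preserved(self):
        rec = iv("chr1", 10, 20, "peak_7")
        a = IntervalSet([rec, rec])  # duplicates preserved by filtering ops
        b = IntervalSet([iv("chr1", 15, 30)])
        kept = intersect_any(a, b)
        assert len(kept) == 2 and kept[0] is rec

    @pytest.mark.parametrize("seed", range(8))
    def test_intersect_and_count_match_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_intervals(rng, 500)
        b = random_intervals(rng, 500)
        counts = brute_count_overlaps(a, b)
        assert list(count_overlaps(a, b)) == counts
        expect_keep = [x for x, c in zip(a, counts) if c > 0]
        assert list(intersect_any(a, b)) == expect_keep
        assert list(subtract_nonoverlapping(a, b)) == [x for x, c in zip(a, counts) if c == 0]

    @pytest.mark.parametrize("seed", range(200))
    def test_partition_identity_many_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = random_intervals(rng, int(rng.integers(1, 60)))
        b = random_intervals(rng, int(rng.integers(0, 60)))
        kept = intersect_any(a, b)
        dropped = subtract_nonoverlapping(a, b)
        assert len(kept) + len(dropped) == len(a)
        assert sorted((x.chrom, x.start, x.end) for x in list(kept) + list(dropped)) == sorted(
            (x.chrom, x.start, x.end) for x in a
        )


class TestMutualDisjointness:
    def test_disjoint_chromosomes(self):
        ok, violation = assert_mutually_disjoint(
            [IntervalSet([iv("chr1", 0, 10)]), IntervalSet([iv("chr2", 0, 10)])]
        )
        assert ok and violation is None

    def test_shared_interval_reports_witness(self):
        shared = iv("chr1", 100, 200)
        ok, violation = assert_mutually_disjoint(
            [IntervalSet([shared]), IntervalSet([iv("chr3", 0, 5)]), IntervalSet([shared])]
        )
        assert not ok
        i, j, witness = violation
        assert (i, j) == (0, 2)
        assert (witness.start, witness.end) == (100, 200)

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            assert_mutually_disjoint([IntervalSet()])


class TestBedIO:
    def test_roundtrip_with_header_junk(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text(
            "# comment\ntrack name=x\nbrowser position chr1\n"
            "chr1\t10\t20\tpeak1\t5\t+\nchr2\t0\t7\n"
        )
        s = read_bed(path)
        assert len(s) == 2
        assert s[0].name == "peak1" and s[0].score == 5.0
        out = tmp_path / "b.bed"
        write_bed(s, out)
        again = read_bed(out)
        assert [(x.chrom, x.start, x.end) for x in again] == [
            (x.chrom, x.start, x.end) for x in s
        ]

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t50\t50\n")
        with pytest.raises(ValueError, match="bad.bed:1"):
            read_bed(path)


def test_merge_and_intersect_agree_with_bedtools(tmp_path, rng):
    """Cross-check against the reference command-line implementation."""
    if subprocess.run(["which", "bedtools"], capture_output=True).returncode != 0:
        pytest.skip("bedtools not on PATH")
    a = sort_intervals(random_intervals(rng, 300, max_pos=50_000))
    b = sort_intervals(random_intervals(rng, 300, max_pos=50_000))
    fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
    write_bed(a, fa)
    write_bed(b, fb)
    merged = subprocess.run(
        ["bedtools", "merge", "-d", "300", "-i", str(fa)], capture_output=True, text=True
    ).stdout
    expect = [
        (p[0], int(p[1]), int(p[2]))
        for p in (line.split("\t") for line in merged.strip().splitlines())
    ]
    got = [(x.chrom, x.start, x.end) for x in merge_within_gap(a, 300)]
    assert got == expect
    hit = subprocess.run(
        ["bedtools", "intersect", "-wa", "-u", "-a", str(fa), "-b", str(fb)],
        capture_output=True,
        text=True,
    ).stdout
    expect_hit = [
        (p[0], int(p[1]), int(p[2]))
        for p in (line.split("\t") for line in hit.strip().splitlines())
    ]
    got_hit = sorted(set((x.chrom, x.start, x.end) for x in intersect_any(a, b)))
    assert sorted(set(expect_hit)) == got_hit
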