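"""Shared fixtures and independent brute-force oracles for the test suite.

The oracles here are deliberately naive (O(n*m) pairwise scans, union-find
merging) and share no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np
import pytest

from riescreen.intervals import GenomicInterval, IntervalSet


def random_intervals(
    rng: np.random.Generator,
    n: int,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
    max_pos: int = 20_000,
    max_len: int = 400,
) -> IntervalSet:
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(out)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def brute_count_overlaps(a: IntervalSet, b: IntervalSet) -> list[int]:
    """O(n*m) pairwise overlap counts, order of a."""
    return [sum(overlaps(x, y) for y in b) for x in a]


def brute_merge(s: IntervalSet, gap: int) -> list[tuple[str, int, int]]:
    """Union-find over pairwise within-gap tests; returns sorted merged spans."""
    items = list(s)
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i], items[j]
            if a.chrom != b.chrom:
                continue
            dist = max(a.start, b.start) - min(a.end, b.end)
            if dist <= gap:
                parent[find(i)] = find(j)
    groups: dict[int, list[GenomicInterval]] = {}
    for i, iv in enumerate(items):
        groups.setdefault(find(i), []).append(iv)
    spans = [
        (g[0].chrom, min(iv.start for iv in g), max(iv.end for iv in g))
        for g in groups.values()
    ]
    return sorted(spans)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
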