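"""Coordinate-sorted genomic interval sets and the set algebra of peak files.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Two intervals *overlap* when they share at least one base; bookended intervals
(``[a, b)`` and ``[b, c)``) do not overlap, but they *do* merge at gap 0, which
matches the behaviour of ``bedtools merge``.

The operations here deliberately implement record-filtering semantics: a record
retained by :func:`intersect_any` or :func:`subtract_nonoverlapping` is the
original input record, coordinates, name and score unchanged, and duplicate
records are preserved.  Only :func:`merge_within_gap` collapses records.  This
mirrors the distinction between ``cat | sort | bedtools merge`` pipelines and
``bedtools intersect -wa -u / -v`` filtering, on which every downstream
classification step relies.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "sort_intervals",
    "merge_within_gap",
    "intersect_any",
    "subtract_nonoverlapping",
    "count_overlaps",
    "assert_mutually_disjoint",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span; the atomic unit of all peak sets."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = field(default=None, compare=False)
    score: Optional[float] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval` with free-form metadata.

    Iteration preserves record identity; ``metadata`` carries provenance such as
    the source dataset id, factor and time-point.
    """

    __slots__ = ("intervals", "sorted_flag", "metadata")

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        sorted_flag: bool = False,
        metadata: Optional[Mapping] = None,
    ) -> None:
        self.intervals: tuple[GenomicInterval, ...] = tuple(intervals)
        self.sorted_flag = bool(sorted_flag)
        self.metadata: dict = dict(metadata or {})

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, sorted={self.sorted_flag})"

    def with_metadata(self, **kwargs) -> "IntervalSet":
        md = dict(self.metadata)
        md.update(kwargs)
        return IntervalSet(self.intervals, self.sorted_flag, md)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


def _sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


def sort_intervals(s: IntervalSet) -> IntervalSet:
    """Return ``s`` ordered by (chrom, start, end); the record multiset is unchanged."""
    if s.sorted_flag:
        return s
    return IntervalSet(sorted(s.intervals, key=_sort_key), True, s.metadata)


def merge_within_gap(s: IntervalSet, gap_bp: int = 0) -> IntervalSet:
    """Merge intervals whose inter-interval distance is at most ``gap_bp``.

    Distance between consecutive sorted intervals is ``next.start - prev.end``;
    overlapping or bookended intervals have distance <= 0 and always merge.
    Output intervals on a chromosome are pairwise separated by strictly more
    than ``gap_bp`` bases.  Names and scores are dropped (merged records are
    new spans, not input records).
    """
    if gap_bp < 0:
        raise ValueError(f"gap_bp must be non-negative, got {gap_bp}")
    ordered = sort_intervals(s)
    merged: list[GenomicInterval] = []
    cur: Optional[GenomicInterval] = None
    for iv in ordered:
        if cur is not None and iv.chrom == cur.chrom and iv.start - cur.end <= gap_bp:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
            continue
        if cur is not None:
            merged.append(cur)
        cur = GenomicInterval(iv.chrom, iv.start, iv.end)
    if cur is not None:
        merged.append(cur)
    return IntervalSet(merged, True, s.metadata)


class _ChromIndex:
    """Per-chromosome sorted start/end arrays for O(log n) overlap counting."""

    __slots__ = ("starts", "ends")

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.starts = np.sort(np.fromiter((iv.start for iv in intervals), dtype=np.int64))
        self.ends = np.sort(np.fromiter((iv.end for iv in intervals), dtype=np.int64))

    def n_overlapping(self, start: int, end: int) -> int:
        # records with start < end_query minus records with end <= start_query
        n_start = int(np.searchsorted(self.starts, end, side="left"))
        n_gone = int(np.searchsorted(self.ends, start, side="right"))
        return n_start - n_gone


def _index(b: IntervalSet) -> dict[str, _ChromIndex]:
    return {chrom: _ChromIndex(ivs) for chrom, ivs in b.by_chrom().items()}


def count_overlaps(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """For each record of ``a``, the number of records of ``b`` sharing >= 1 base.

    Output order matches ``a``.
    """
    idx = _index(b)
    counts = np.zeros(len(a), dtype=np.int64)
    for i, iv in enumerate(a):
        ci = idx.get(iv.chrom)
        if ci is not None:
            counts[i] = ci.n_overlapping(iv.start, iv.end)
    return counts


def intersect_any(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Records of ``a`` overlapping >= 1 record of ``b`` (``intersect -wa -u``).

    Each qualifying record of ``a`` is reported once, identity unchanged.
    """
    mask = count_overlaps(a, b) > 0
    kept = [iv for iv, m in zip(a, mask) if m]
    return IntervalSet(kept, a.sorted_flag, a.metadata)


def subtract_nonoverlapping(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Records of ``a`` sharing no base with any record of ``b`` (``intersect -v``)."""
    mask = count_overlaps(a, b) == 0
    kept = [iv for iv, m in zip(a, mask) if m]
    return IntervalSet(kept, a.sorted_flag, a.metadata)


def assert_mutually_disjoint(
    sets: Sequence[IntervalSet],
) -> tuple[bool, Optional[tuple[int, int, GenomicInterval]]]:
    """Check that no base is shared between records of two different sets.

    Returns ``(True, None)`` when disjoint, otherwise ``(False, (i, j, witness))``
    where ``witness`` is the shared region between the first violating pair.
    """
    if len(sets) < 2:
        raise ValueError("assert_mutually_disjoint requires at least two sets")
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            hit = _first_overlap(sets[i], sets[j])
            if hit is not None:
                return False, (i, j, hit)
    return True, None


def _first_overlap(a: IntervalSet, b: IntervalSet) -> Optional[GenomicInterval]:
    by_chrom = {
        chrom: sorted((iv.start, iv.end) for iv in ivs)
        for chrom, ivs in b.by_chrom().items()
    }
    for iv in a:
        spans = by_chrom.get(iv.chrom)
        if not spans:
            continue
        starts = [s for s, _ in spans]
        k = bisect.bisect_left(starts, iv.end)
        for s, e in spans[:k]:
            if e > iv.start:
                return GenomicInterval(iv.chrom, max(iv.start, s), min(iv.end, e))
    return None


# ---------------------------------------------------------------------------
# BED3/BED6 I/O


def read_bed(path, metadata: Optional[Mapping] = None) -> IntervalSet:
    """Read a BED3/BED6 file (tab-separated; ``#``/``track``/``browser`` skipped).

    Column 4 (name) and column 5 (score) are optional; a strand column is
    accepted and ignored (peaks are unstranded).
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            name = parts[3] if len(parts) > 3 and parts[3] not in ("", ".") else None
            score = None
            if len(parts) > 4 and parts[4] not in ("", "."):
                score = float(parts[4])
            try:
                intervals.append(
                    GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name, score)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals, False, metadata)


def write_bed(s: IntervalSet, path) -> None:
    """Write BED3, or BED6 when any record carries a name or score (no header)."""
    six = any(iv.name is not None or iv.score is not None for iv in s)
    with open(path, "w") as fh:
        for iv in s:
            if six:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t.\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
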