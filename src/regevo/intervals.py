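"""Genomic-interval primitives shared by every analysis stage.

All coordinates are 0-based half-open (BED convention). Strand is carried
through parsing and writing but ignored by overlap logic, because regulatory
region calls are strandless.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "GenomicInterval",
    "overlap_length",
    "overlap_fraction",
    "merge_intervals",
    "IntervalIndex",
    "edge_distance",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.seq_id}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.seq_id}:{self.start}-{self.end}"
            )

    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def __repr__(self) -> str:  # compact, BED-like
        return f"{self.seq_id}:{self.start}-{self.end}"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by ``a`` and ``b`` (0 on different sequences)."""
    if a.seq_id != b.seq_id:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of *a*'s length covered by ``b``.

    Asymmetric by design: overlap rules in this pipeline are phrased as
    "region X overlaps Y with at least 50% of its length", where the 50%
    refers to the subject region X.
    """
    return overlap_length(a, b) / a.length()


def edge_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Edge-to-edge distance in bp; 0 when overlapping; None across sequences."""
    if a.seq_id != b.seq_id:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start, b.start) - min(a.end, b.end)


def merge_intervals(xs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, pairwise-disjoint list.

    Bookended intervals ([0,10) and [10,20)) merge, matching the half-open
    convention where they cover contiguous bases.
    """
    by_pos = sorted(xs, key=lambda iv: (iv.seq_id, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_pos:
        if merged and merged[-1].seq_id == iv.seq_id and iv.start <= merged[-1].end:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.seq_id, prev.start, iv.end, prev.strand)
        else:
            merged.append(GenomicInterval(iv.seq_id, iv.start, iv.end, iv.strand))
    return merged


class IntervalIndex:
    """Query structure answering "which intervals overlap [start, end)?".

    Built once over a static interval list; queries use binary search over
    per-sequence sorted starts, with the maximum interval length per sequence
    bounding the left scan. Payloads are arbitrary objects carried alongside.
    """

    def __init__(self, items: Sequence[tuple[GenomicInterval, object]] = ()):
        self._by_seq: dict[str, tuple[list[int], list[tuple[GenomicInterval, object]], int]] = {}
        buckets: dict[str, list[tuple[GenomicInterval, object]]] = {}
        for iv, payload in items:
            buckets.setdefault(iv.seq_id, []).append((iv, payload))
        for seq_id, pairs in buckets.items():
            pairs.sort(key=lambda p: (p[0].start, p[0].end))
            starts = [p[0].start for p in pairs]
            max_len = max(p[0].length() for p in pairs)
            self._by_seq[seq_id] = (starts, pairs, max_len)

    @classmethod
    def from_intervals(cls, ivs: Iterable[GenomicInterval]) -> "IntervalIndex":
        return cls([(iv, iv) for iv in ivs])

    def overlapping(self, query: GenomicInterval) -> Iterator[tuple[GenomicInterval, object]]:
        entry = self._by_seq.get(query.seq_id)
        if entry is None:
            return
        starts, pairs, max_len = entry
        lo = bisect_left(starts, query.start - max_len)
        hi = bisect_right(starts, query.end - 1)
        for i in range(lo, hi):
            iv = pairs[i][0]
            if iv.end > query.start and iv.start < query.end:
                yield pairs[i]

    def any_overlap(self, query: GenomicInterval) -> bool:
        return next(self.overlapping(query), None) is not None

    def __len__(self) -> int:
        return sum(len(pairs) for _, pairs, _ in self._by_seq.values())
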