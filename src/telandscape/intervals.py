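"""Scaffold-anchored genomic intervals and elementary interval geometry.

All coordinates in this package are 0-based, half-open ``[start, end)``.
GFF3 input/output converts to and from the 1-based inclusive convention at
the file boundary, so length arithmetic inside the package is always
``end - start`` with no off-by-one corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class IncomparableIntervalsError(ValueError):
    """Raised when a distance is requested between intervals on different scaffolds."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open coordinate span ``[start, end)`` on one scaffold.

    Strand is carried for round-tripping annotation files but is ignored by
    every spatial statistic in the package.
    """

    scaffold_id: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) "
                f"on {self.scaffold_id}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint position, ``start + floor(length / 2)``.

        Even-length intervals round down; the convention is fixed so the
        midpoint rule used by the proximity statistics is deterministic.
        """
        return self.start + self.length // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 across scaffolds)."""
        if self.scaffold_id != other.scaffold_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_bp(self, other: "GenomicInterval") -> int:
        """Gap length between two intervals on the same scaffold (0 when overlapping)."""
        if self.scaffold_id != other.scaffold_id:
            raise IncomparableIntervalsError(
                f"cannot compute a distance between intervals on {self.scaffold_id!r} "
                f"and {other.scaffold_id!r}"
            )
        if self.overlap_bp(other) > 0:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)

    def contains_point(self, position: int) -> bool:
        """Half-open containment: start is inside, end is not."""
        return self.start <= position < self.end

    def shifted(self, new_start: int) -> "GenomicInterval":
        return GenomicInterval(
            self.scaffold_id, new_start, new_start + self.length, self.strand
        )


def interval_geometry(
    a: GenomicInterval, b: GenomicInterval
) -> tuple[int, int, int]:
    """Return ``(overlap_bp, distance_bp, midpoint_of_a)`` for two intervals.

    Raises :class:`IncomparableIntervalsError` for a cross-scaffold pair,
    because a gap distance is undefined there.
    """
    return a.overlap_bp(b), a.distance_bp(b), a.midpoint


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of ``(start, end)`` spans (or GenomicIntervals on one scaffold).

    Returns sorted, non-overlapping, non-adjacent-merged spans. Adjacent
    (abutting) spans are merged since they cover a contiguous run of bases.
    """
    spans = [
        (iv.start, iv.end) if isinstance(iv, GenomicInterval) else (iv[0], iv[1])
        for iv in intervals
    ]
    if not spans:
        return []
    spans.sort()
    merged = [spans[0]]
    for start, end in spans[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end:
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


def total_bp(merged_spans) -> int:
    return sum(end - start for start, end in merged_spans)


def intersect_merged(a_spans, b_spans) -> list[tuple[int, int]]:
    """Intersection of two already-merged span lists (linear sweep)."""
    out = []
    i = j = 0
    while i < len(a_spans) and j < len(b_spans):
        a_start, a_end = a_spans[i]
        b_start, b_end = b_spans[j]
        lo = max(a_start, b_start)
        hi = min(a_end, b_end)
        if lo < hi:
            out.append((lo, hi))
        if a_end <= b_end:
            i += 1
        else:
            j += 1
    return out


def subtract_merged(a_spans, b_spans) -> list[tuple[int, int]]:
    """Set difference ``a \\ b`` of two merged span lists."""
    out = []
    j = 0
    for a_start, a_end in a_spans:
        cursor = a_start
        while j < len(b_spans) and b_spans[j][1] <= cursor:
            j += 1
        k = j
        while k < len(b_spans) and b_spans[k][0] < a_end:
            b_start, b_end = b_spans[k]
            if b_start > cursor:
                out.append((cursor, b_start))
            cursor = max(cursor, b_end)
            k += 1
        if cursor < a_end:
            out.append((cursor, a_end))
    return out
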