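"""Half-open genomic intervals and the small arithmetic the region catalogs need.

Internally every coordinate is 0-based half-open; the GTF boundary converts
to/from the 1-based inclusive dialect.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware interval on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping (start, end) pairs into the minimal disjoint set.

    Abutting intervals (end == next start) are merged: the base-set union has
    no gap between them.
    """
    ordered = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ordered:
        if start >= end:
            raise ValueError(f"empty or inverted interval ({start}, {end})")
        if merged and start <= merged[-1][1]:
            prev_start, prev_end = merged[-1]
            merged[-1] = (prev_start, max(prev_end, end))
        else:
            merged.append((start, end))
    return merged


def interval_gaps(merged: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Gaps between consecutive disjoint sorted intervals; zero-length gaps dropped."""
    gaps: list[tuple[int, int]] = []
    for (_, left_end), (right_start, _) in zip(merged, merged[1:]):
        if right_start > left_end:
            gaps.append((left_end, right_start))
    return gaps


def subtract_intervals(
    keep: Sequence[tuple[int, int]], remove: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set-difference of two interval lists, result merged and sorted."""
    result: list[tuple[int, int]] = []
    cuts = merge_intervals(remove) if remove else []
    for start, end in merge_intervals(keep):
        cursor = start
        for cut_start, cut_end in cuts:
            if cut_end <= cursor or cut_start >= end:
                continue
            if cut_start > cursor:
                result.append((cursor, cut_start))
            cursor = max(cursor, cut_end)
            if cursor >= end:
                break
        if cursor < end:
            result.append((cursor, end))
    return result
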