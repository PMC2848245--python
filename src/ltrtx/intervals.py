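"""Genomic interval primitives.

All coordinates in this package are 0-based, half-open ``[start, end)``.
GFF3 input/output converts to and from 1-based inclusive coordinates at the
I/O boundary only (:mod:`ltrtx.genome_model`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

FORWARD = "+"
REVERSE = "-"
UNSTRANDED = "."

_STRANDS = (FORWARD, REVERSE, UNSTRANDED)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "need 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff *other* lies fully within this interval (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def with_strand(self, strand: str) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start, self.end, strand)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Merge overlapping/adjacent intervals into a sorted disjoint set.

    Strand information is discarded (result is unstranded).
    """
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: List[GenomicInterval] = []
    for iv in by_pos:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def complement(
    blocks: Sequence[GenomicInterval], chrom: str, chrom_length: int
) -> List[GenomicInterval]:
    """Intervals of *chrom* not covered by *blocks* (which may be unsorted)."""
    merged = [b for b in merge_intervals(blocks) if b.chrom == chrom]
    out: List[GenomicInterval] = []
    cursor = 0
    for b in merged:
        lo = max(0, b.start)
        if lo > cursor:
            out.append(GenomicInterval(chrom, cursor, lo))
        cursor = max(cursor, min(b.end, chrom_length))
    if cursor < chrom_length:
        out.append(GenomicInterval(chrom, cursor, chrom_length))
    return out


def clip(start: int, end: int, chrom_length: int) -> Tuple[int, int]:
    """Clip ``[start, end)`` to ``[0, chrom_length)`` bounds."""
    return max(0, start), min(end, chrom_length)
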