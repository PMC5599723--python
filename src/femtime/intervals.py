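"""Genomic interval primitives.

All coordinates are 0-based half-open ``[start, end)``. Conversion to and
from 1-based inclusive GTF coordinates happens only at the I/O boundary
(:mod:`femtime.genemodels`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

Span = Tuple[int, int]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"start >= end: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"unknown strand symbol: {self.strand!r}")

    @property
    def length(self) -> int:
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


def merge_spans(spans: Iterable[Span]) -> List[Span]:
    """Sort and merge overlapping or abutting ``(start, end)`` spans."""
    out: List[Span] = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def union_spans(a: Sequence[Span], b: Sequence[Span]) -> List[Span]:
    return merge_spans(list(a) + list(b))


def subtract_spans(a: Sequence[Span], b: Sequence[Span]) -> List[Span]:
    """Set difference a \\ b of merged span lists."""
    a = merge_spans(a)
    b = merge_spans(b)
    out: List[Span] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_spans(a: Sequence[Span], b: Sequence[Span]) -> List[Span]:
    a = merge_spans(a)
    b = merge_spans(b)
    out: List[Span] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(spans: Sequence[Span]) -> int:
    return sum(e - s for s, e in merge_spans(spans))


def spans_overlap_point(spans: Sequence[Span], pos: int) -> bool:
    return any(s <= pos < e for s, e in spans)
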