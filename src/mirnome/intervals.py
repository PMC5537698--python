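"""Closed genomic-interval algebra.

All coordinates are 1-based and inclusive on both ends, matching the hg19
region strings printed in SCNA catalogs and the GFF3 convention. Every
mapping, containment and span statistic in the pipeline reduces to the four
operations here, so this module is deliberately dependency-free and is
validated against a per-base brute-force oracle in the test suite.

Two distinct notions for touching intervals, both deliberate:

* ``overlaps`` requires >= 1 shared base, so (1, 100) and (101, 200) do NOT
  overlap;
* ``merge`` joins abutting intervals (end + 1 == next start), because under
  inclusive coordinates they cover one contiguous base run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Sequence

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored closed span ``chrom:start-end`` (1-based, inclusive).

    Strand is carried for annotation purposes but never participates in
    overlap or containment tests: copy-number events are strand-agnostic,
    and intragenic miRNAs may sit on the opposite strand of their host.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start}) "
                f"on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base.

    Chromosome names are compared as exact strings ("chr10" != "10");
    strand is ignored.
    """
    return a.chrom == b.chrom and max(a.start, b.start) <= min(a.end, b.end)


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by the two intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """True iff ``inner`` lies entirely within ``outer`` (strand ignored)."""
    return (
        outer.chrom == inner.chrom
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


def merge(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, disjoint, per-chromosome list.

    Overlapping and abutting (end + 1 == start) same-chromosome intervals
    are fused; strand information is dropped from the output.
    """
    merged: list[GenomicInterval] = []
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    for _, group in groupby(ordered, key=lambda iv: iv.chrom):
        current = None
        for iv in group:
            if current is None:
                current = [iv.chrom, iv.start, iv.end]
            elif iv.start <= current[2] + 1:
                current[2] = max(current[2], iv.end)
            else:
                merged.append(GenomicInterval(*current))
                current = [iv.chrom, iv.start, iv.end]
        if current is not None:
            merged.append(GenomicInterval(*current))
    return merged


def total_span(intervals: Sequence[GenomicInterval]) -> int:
    """Total number of distinct bases covered by the intervals.

    The input is merged first, so double-counting of overlapping
    intervals is impossible.
    """
    return sum(iv.length for iv in merge(intervals))
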