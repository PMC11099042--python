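"""Genomic intervals and the interval algebra shared by every pipeline stage.

Coordinates are 0-based, half-open (BED convention) throughout. Chromosome
names are compared as exact strings; there is no "chr" aliasing. Strand is
carried but ignored by all overlap operations: accessibility peaks and loop
anchors are unstranded, only gene TSS definitions consult strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree


class IntervalError(ValueError):
    """Raised for malformed coordinates or invalid interval arguments."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise IntervalError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise IntervalError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise IntervalError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 for different chromosomes or disjoint."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """An ordered, named collection of intervals (one BED track's worth).

    Duplicates are permitted on read and removable via :meth:`unique`.
    """

    name: str = ""
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def sorted(self) -> "PeakSet":
        ivs = sorted(self.intervals, key=lambda v: (v.chrom, v.start, v.end))
        return PeakSet(self.name, ivs)

    def unique(self) -> "PeakSet":
        seen: set[tuple] = set()
        out = []
        for iv in self.intervals:
            key = (iv.chrom, iv.start, iv.end)
            if key not in seen:
                seen.add(key)
                out.append(iv)
        return PeakSet(self.name, out)

    def chromosomes(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})


def _build_trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(peaks):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    return trees


def overlap_pairs(a: PeakSet, b: PeakSet, min_bp: int = 1) -> set[tuple[int, int]]:
    """Index pairs (i, j) where a[i] and b[j] share at least ``min_bp`` bases.

    Half-open adjacency ([0,10) vs [10,20)) never counts as overlap.
    """
    if min_bp < 1:
        raise IntervalError(f"min_bp must be >= 1, got {min_bp}")
    trees = _build_trees(b)
    pairs: set[tuple[int, int]] = set()
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_bp:
                pairs.add((i, hit.data))
    return pairs


def overlapping_indices(a: PeakSet, b: PeakSet, min_bp: int = 1) -> set[int]:
    """Indices of intervals in ``a`` overlapping at least one interval of ``b``."""
    return {i for i, _ in overlap_pairs(a, b, min_bp=min_bp)}


def merge_intervals(a: PeakSet, gap: int = 0) -> PeakSet:
    """Merge intervals closer than or book-ending within ``gap`` bases.

    At gap=0 book-ended intervals ([0,10) and [10,20)) merge, matching the
    common merge-tool default. Output is sorted and disjoint; at gap=0 its
    union of bases equals the input's.
    """
    if gap < 0:
        raise IntervalError(f"gap must be >= 0, got {gap}")
    merged: list[GenomicInterval] = []
    for iv in sorted(a.intervals, key=lambda v: (v.chrom, v.start, v.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + gap:
            if iv.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=iv.end, name=None, score=None)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return PeakSet(a.name, merged)


def intervals_from_coords(
    coords: Iterable[tuple[str, int, int]], name: str = ""
) -> PeakSet:
    """Convenience constructor from (chrom, start, end) triples."""
    return PeakSet(name, [GenomicInterval(c, s, e) for c, s, e in coords])
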