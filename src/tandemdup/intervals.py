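"""Genomic interval primitives.

All coordinates are 0-based half-open ``[start, end)`` on named sequences
(the BED convention). These primitives are the substrate for the union
arithmetic behind the nucleotide increase ratio and for the overlap
filters.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Sequence (chromosome/contig) name; non-empty.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

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
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


def merge_intervals(
    intervals: Iterable[GenomicInterval], *, stranded: bool = False
) -> list[GenomicInterval]:
    """Coalesce overlapping or touching intervals into disjoint runs.

    Touching intervals (``a.end == b.start``) merge into one, matching the
    default behaviour of ``bedtools merge``. Strand is ignored unless
    ``stranded`` is set; merged intervals carry strand ``.`` in the
    strand-blind mode (or the common strand when stranded).
    """
    key = (lambda iv: (iv.chrom, iv.strand)) if stranded else (lambda iv: (iv.chrom,))
    by_group: dict[tuple, list[GenomicInterval]] = {}
    for iv in intervals:
        by_group.setdefault(key(iv), []).append(iv)
    merged: list[GenomicInterval] = []
    for group, ivs in sorted(by_group.items()):
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        strand = ivs[0].strand if stranded else "."
        chrom = ivs[0].chrom
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or touch
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end, strand))
    return merged


def union_length(intervals: Iterable[GenomicInterval]) -> int:
    """Number of distinct genomic positions covered by at least one interval."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def intersect_length(
    region: GenomicInterval, features: Sequence[GenomicInterval]
) -> int:
    """Length of the intersection of ``region`` with the union of ``features``."""
    total = 0
    for iv in merge_intervals(features):
        total += region.overlap_length(iv)
    return total


def overlap_fraction(
    region: GenomicInterval, features: Sequence[GenomicInterval]
) -> float:
    """Fraction of ``region`` covered by the union of ``features``.

    Features are unioned first, so many small overlapping features count
    each covered base once.
    """
    if len(region) == 0:  # pragma: no cover - constructor forbids this
        raise ValueError("zero-length region")
    return intersect_length(region, features) / len(region)
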