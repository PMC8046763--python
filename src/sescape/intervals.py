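"""Interval algebra on half-open genomic intervals.

The merging convention throughout the package is that *touching* intervals
(``a.end == b.start``) belong to the same union locus: unions of enhancer
loci are maximal runs of covered or adjacent bases.
"""
from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Sequence

from .types import GenomicInterval

__all__ = [
    "merge_intervals",
    "total_covered_bp",
    "intervals_overlapping",
    "any_overlap",
]


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge intervals into maximal non-overlapping union loci.

    Overlapping *and touching* intervals are merged.  The result is sorted
    by ``(chrom, start)``.  Scores and sample tags are dropped: a union
    locus belongs to no single sample.
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        if not isinstance(iv, GenomicInterval):
            raise TypeError(f"not a GenomicInterval: {iv!r}")
        by_chrom[iv.chrom].append(iv)

    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or touch
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def total_covered_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Number of distinct bases covered by the interval set."""
    return sum(iv.length for iv in merge_intervals(intervals))


def intervals_overlapping(
    query: GenomicInterval, targets: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """All targets sharing >= 1 bp with ``query`` (linear scan)."""
    return [t for t in targets if query.overlaps(t)]


def any_overlap(
    query: GenomicInterval, targets: Sequence[GenomicInterval]
) -> bool:
    return any(query.overlaps(t) for t in targets)
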