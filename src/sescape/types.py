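"""Core domain types shared by every pipeline stage.

Coordinates are 0-based, half-open ``[start, end)`` everywhere in memory;
files on disk follow BED conventions (which are the same thing).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "BinnedSignalTrack",
    "EnhancerRegion",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally scored and sample-tagged."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    """A gene reduced to the fields the pipeline needs: TSS, strand, TF flag."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass
class BinnedSignalTrack:
    """Fixed-width binned read counts for one sample.

    ``counts`` maps chromosome name to an integer vector of reads per bin;
    bin *i* covers ``[i * bin_size, (i + 1) * bin_size)``.  ``total_mapped``
    is the library size used for rpm normalization and may exceed the sum of
    the binned counts (the bins need not tile the whole genome).
    """

    sample_id: str
    bin_size: int
    counts: dict[str, np.ndarray]
    total_mapped: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, vec in self.counts.items():
            arr = np.asarray(vec)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: counts must be a 1-D vector")
            if np.any(arr < 0):
                raise ValueError(f"{chrom}: counts must be non-negative")
            self.counts[chrom] = arr.astype(np.int64)

    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.counts.values()))

    def chrom_length(self, chrom: str) -> int:
        return len(self.counts[chrom]) * self.bin_size


@dataclass(frozen=True)
class EnhancerRegion:
    """A called enhancer with its quantified H3K27ac signal."""

    interval: GenomicInterval
    total_rpm: float
    density: float  # rpm per bp
    n_bins: int

    def __post_init__(self) -> None:
        if self.interval.length < 1:
            raise ValueError("enhancer region must span at least 1 bp")
        if self.total_rpm < 0:
            raise ValueError("signal must be non-negative")

    @property
    def length(self) -> int:
        return self.interval.length
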