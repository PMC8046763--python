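"""Per-sample enhancer calling from binned H3K27ac-like signal.

The sequence of steps: Poisson binarization of bin counts against the
per-sample global mean, two-state HMM segmentation, promoter-proximal
filtering (+/- 2.5 kb of any TSS by default), optional stitching, and
rpm/bp quantification of each surviving region.
"""
from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
from scipy import stats as sps

from .hmm import HMMParams, fit_two_state_hmm, viterbi_path
from .intervals import merge_intervals
from .io import get_logger
from .types import BinnedSignalTrack, EnhancerRegion, GeneRecord, GenomicInterval

__all__ = [
    "binarize_track",
    "decode_enriched_regions",
    "filter_promoter_proximal",
    "stitch_regions",
    "quantify_region_signal",
    "call_enhancers",
]

log = get_logger(__name__)


def binarize_track(
    track: BinnedSignalTrack, p_threshold: float = 1e-4
) -> dict[str, np.ndarray]:
    """Flag bins whose count is improbably high under Poisson background.

    The background rate is the per-sample global mean bin count; a bin is
    flagged iff the upper-tail probability P(X >= count) falls below
    ``p_threshold``.
    """
    if track.n_bins() == 0:
        raise ValueError("empty track")
    all_counts = np.concatenate([v for v in track.counts.values()])
    lam = float(all_counts.mean())
    if lam == 0:
        warnings.warn(f"{track.sample_id}: all-zero track; nothing flagged")
        return {c: np.zeros(len(v), dtype=np.int8) for c, v in track.counts.items()}
    # minimal count whose upper tail is below threshold
    min_flagged = int(sps.poisson.isf(p_threshold, lam)) + 1
    return {
        chrom: (vec >= min_flagged).astype(np.int8)
        for chrom, vec in track.counts.items()
    }


def decode_enriched_regions(
    binary_bins: dict[str, np.ndarray],
    params: HMMParams,
    bin_size: int,
) -> list[GenomicInterval]:
    """Viterbi-decode each chromosome and emit maximal enriched runs."""
    regions: list[GenomicInterval] = []
    for chrom in sorted(binary_bins):
        path = viterbi_path(binary_bins[chrom], params)
        if path.size == 0:
            continue
        padded = np.concatenate([[0], path, [0]])
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1)
        for s, e in zip(starts, ends):
            regions.append(GenomicInterval(chrom, int(s) * bin_size, int(e) * bin_size))
    return regions


def filter_promoter_proximal(
    regions: Sequence[GenomicInterval],
    annotation: Sequence[GeneRecord],
    halfwidth: int = 2500,
) -> list[GenomicInterval]:
    """Drop regions overlapping any promoter window [tss-hw, tss+hw) by >= 1 bp."""
    if not annotation:
        return list(regions)
    windows = merge_intervals(
        GenomicInterval(g.chrom, max(0, g.tss - halfwidth), g.tss + halfwidth)
        for g in annotation
    )
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    kept = []
    for r in regions:
        ws = by_chrom.get(r.chrom, ())
        if not any(r.start < w.end and w.start < r.end for w in ws):
            kept.append(r)
    return kept


def stitch_regions(
    regions: Sequence[GenomicInterval], gap: int
) -> list[GenomicInterval]:
    """Merge regions separated by at most ``gap`` bp; gap=0 is a plain union."""
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if not regions:
        return []
    widened = [
        GenomicInterval(r.chrom, r.start, r.end + gap, sample_id=r.sample_id)
        for r in regions
    ]
    return [
        GenomicInterval(m.chrom, m.start, m.end - gap)
        if m.end - gap > m.start
        else GenomicInterval(m.chrom, m.start, m.end)
        for m in merge_intervals(widened)
    ]


def quantify_region_signal(
    region: GenomicInterval, track: BinnedSignalTrack
) -> tuple[float, float]:
    """(total rpm, density rpm/bp) of reads falling in ``region``.

    Reads in partially overlapped bins are allocated proportionally to the
    overlap fraction.
    """
    if track.total_mapped <= 0:
        raise ValueError(f"{track.sample_id}: total_mapped must be positive")
    if region.chrom not in track.counts:
        raise ValueError(f"{track.sample_id}: no signal for {region.chrom}")
    vec = track.counts[region.chrom]
    bs = track.bin_size
    if region.start < 0 or region.end > len(vec) * bs:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} outside track bounds"
        )
    first = region.start // bs
    last = (region.end - 1) // bs  # inclusive
    reads = 0.0
    for b in range(first, last + 1):
        lo = max(region.start, b * bs)
        hi = min(region.end, (b + 1) * bs)
        reads += vec[b] * (hi - lo) / bs
    rpm = reads / (track.total_mapped / 1e6)
    density = rpm / region.length
    return rpm, density


def call_enhancers(
    track: BinnedSignalTrack,
    annotation: Sequence[GeneRecord],
    promoter_halfwidth: int = 2500,
    stitch_gap: int = 0,
    p_threshold: float = 1e-4,
    seed: int = 0,
) -> tuple[list[EnhancerRegion], HMMParams]:
    """Full per-sample enhancer call: binarize, segment, filter, quantify."""
    bits = binarize_track(track, p_threshold=p_threshold)
    concat = np.concatenate([bits[c] for c in sorted(bits)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = fit_two_state_hmm(concat, seed=seed)
    regions = decode_enriched_regions(bits, params, track.bin_size)
    regions = filter_promoter_proximal(regions, annotation, promoter_halfwidth)
    if stitch_gap > 0:
        regions = stitch_regions(regions, stitch_gap)
    out = []
    for r in regions:
        rpm, density = quantify_region_signal(r, track)
        n_bins = (r.end - r.start) // track.bin_size
        iv = GenomicInterval(r.chrom, r.start, r.end, score=density,
                             sample_id=track.sample_id)
        out.append(EnhancerRegion(iv, rpm, density, n_bins))
    log.debug("%s: %d enhancers after promoter filter", track.sample_id, len(out))
    return out, params
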