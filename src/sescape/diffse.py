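"""Subtype-specific super-enhancers.

Per-sample SE calls are merged into union loci, each locus is quantified
as H3K27ac density (rpm/bp, with 200-bp flanks) in every sample, loci are
tested between the two groups with a rank test, and classified as
group-specific when |log2 fold enrichment| > 1 at BH-adjusted p < 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .enhancers import quantify_region_signal
from .intervals import any_overlap, merge_intervals
from .stats import benjamini_hochberg, two_group_rank_test
from .types import BinnedSignalTrack, GenomicInterval

__all__ = [
    "VennCounts",
    "union_se_loci",
    "density_matrix",
    "differential_se_test",
    "classify_specific",
    "locus_id",
]


@dataclass(frozen=True)
class VennCounts:
    a_only: int
    b_only: int
    shared_a: int  # group-A union loci overlapping the B union
    shared_b: int


def locus_id(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def union_se_loci(
    se_sets: dict[str, list[GenomicInterval]], labels: dict[str, str]
) -> tuple[list[GenomicInterval], list[GenomicInterval], list[GenomicInterval], VennCounts]:
    """Merge per-sample SEs into per-group and overall union loci.

    Returns (unionA, unionB, union_all, venn); groups are taken in sorted
    label order.  A group-union locus is "shared" iff it overlaps any
    locus of the other group's union by >= 1 bp.
    """
    groups = sorted(set(labels[s] for s in se_sets))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    gA, gB = groups
    a_ivs = [iv for s, ivs in se_sets.items() if labels[s] == gA for iv in ivs]
    b_ivs = [iv for s, ivs in se_sets.items() if labels[s] == gB for iv in ivs]
    if not a_ivs or not b_ivs:
        raise ValueError("each group must contribute at least one SE")
    unionA = merge_intervals(a_ivs)
    unionB = merge_intervals(b_ivs)
    union_all = merge_intervals(a_ivs + b_ivs)
    shared_a = sum(any_overlap(u, unionB) for u in unionA)
    shared_b = sum(any_overlap(u, unionA) for u in unionB)
    venn = VennCounts(
        a_only=len(unionA) - shared_a,
        b_only=len(unionB) - shared_b,
        shared_a=shared_a,
        shared_b=shared_b,
    )
    return unionA, unionB, union_all, venn


def density_matrix(
    union_all: Sequence[GenomicInterval],
    tracks: dict[str, BinnedSignalTrack],
    flank: int = 200,
) -> pd.DataFrame:
    """Loci x samples H3K27ac density (rpm/bp) with flanked loci.

    Each locus is extended by ``flank`` bp on both sides, clipped at the
    chromosome bounds, before quantification.
    """
    samples = sorted(tracks)
    data = np.empty((len(union_all), len(samples)))
    ids = []
    for i, locus in enumerate(union_all):
        ids.append(locus_id(locus))
        for j, s in enumerate(samples):
            track = tracks[s]
            if locus.chrom not in track.counts:
                raise ValueError(f"locus {ids[-1]} not covered by track {s}")
            chrom_len = track.chrom_length(locus.chrom)
            ext = GenomicInterval(
                locus.chrom,
                max(0, locus.start - flank),
                min(chrom_len, locus.end + flank),
            )
            _, density = quantify_region_signal(ext, track)
            data[i, j] = density
    return pd.DataFrame(data, index=ids, columns=samples)


def differential_se_test(
    densities: pd.DataFrame,
    groups: dict[str, str],
    epsilon: float = 1e-4,
    mode: str = "rank_sum",
) -> pd.DataFrame:
    """Per-locus log2 fold enrichment and rank-test p between the groups.

    log2FE = log2((meanA + eps) / (meanB + eps)) with groups in sorted
    label order; p-values are BH-corrected across all loci.
    """
    names = sorted(set(groups[s] for s in densities.columns))
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {names}")
    gA, gB = names
    colsA = [s for s in densities.columns if groups[s] == gA]
    colsB = [s for s in densities.columns if groups[s] == gB]
    if len(colsA) < 3 or len(colsB) < 3:
        raise ValueError("need >= 3 samples per group for the rank test")
    meanA = densities[colsA].mean(axis=1)
    meanB = densities[colsB].mean(axis=1)
    log2fe = np.log2((meanA + epsilon) / (meanB + epsilon))
    pvals = [
        two_group_rank_test(
            densities.loc[i, colsA].to_numpy(),
            densities.loc[i, colsB].to_numpy(),
            mode=mode,
        )
        for i in densities.index
    ]
    out = pd.DataFrame(
        {
            "mean_" + gA: meanA,
            "mean_" + gB: meanB,
            "log2fe": log2fe,
            "p": pvals,
        },
        index=densities.index,
    )
    out["adj_p"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def classify_specific(
    log2fe: float,
    adj_p: float,
    diff_log2fe: float = 1.0,
    diff_alpha: float = 0.05,
    group_names: tuple[str, str] = ("groupA", "groupB"),
) -> str:
    """Label a union locus from its fold enrichment and adjusted p."""
    if not (np.isfinite(log2fe) and np.isfinite(adj_p)):
        raise ValueError("log2fe and adj_p must be finite")
    gA, gB = group_names
    if log2fe > diff_log2fe and adj_p < diff_alpha:
        return f"{gA}-specific"
    if log2fe < -diff_log2fe and adj_p < diff_alpha:
        return f"{gB}-specific"
    return "shared"
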