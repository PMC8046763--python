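"""From subtype-specific SEs to candidate target genes.

Differential expression on the log2 matrix (difference of group means as
log2FC, rank-test p, BH), strand-aware SE->gene assignment within a 500-kb
upstream window, hypergeometric geneset overrepresentation, and a
preranked weighted Kolmogorov-Smirnov enrichment score with a gene-label
permutation p-value.
"""
from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, hypergeom_upper_tail, two_group_rank_test
from .types import GeneRecord, GenomicInterval

__all__ = [
    "SETargetPair",
    "differential_expression",
    "upregulated_genes",
    "assign_se_targets",
    "geneset_overrepresentation",
    "preranked_enrichment",
]


@dataclass(frozen=True)
class SETargetPair:
    se_id: str
    gene_id: str
    distance: int  # bp from TSS to nearest SE base, upstream positive
    se_label: str
    gene_log2fc: float


def differential_expression(
    matrix: pd.DataFrame, groups: dict[str, str], mode: str = "rank_sum"
) -> pd.DataFrame:
    """Per-gene log2FC (mean A - mean B) and BH-corrected rank-test p.

    ``matrix`` is genes x samples on the log2 scale; group names are taken
    in sorted order, the first being the "up" direction.
    """
    names = sorted(set(groups[s] for s in matrix.columns))
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {names}")
    gA, gB = names
    colsA = [s for s in matrix.columns if groups[s] == gA]
    colsB = [s for s in matrix.columns if groups[s] == gB]
    if len(colsA) < 3 or len(colsB) < 3:
        raise ValueError("need >= 3 samples per group")
    A = matrix[colsA].to_numpy()
    B = matrix[colsB].to_numpy()
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    pvals = np.array(
        [two_group_rank_test(A[i], B[i], mode=mode) for i in range(len(matrix))]
    )
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "adj_p": benjamini_hochberg(pvals),
        },
        index=matrix.index,
    )
    out["direction"] = np.sign(out["log2fc"]).astype(int)
    return out


def upregulated_genes(
    de: pd.DataFrame, de_log2fc: float = 0.5, alpha: float = 0.05
) -> list[str]:
    """Genes up in group A: log2FC > threshold and adjusted p < alpha."""
    mask = (de["log2fc"] > de_log2fc) & (de["adj_p"] < alpha)
    return list(de.index[mask])


def _upstream_window(gene: GeneRecord, window: int) -> GenomicInterval | None:
    if gene.strand == "+":
        lo, hi = max(0, gene.tss - window), gene.tss
    else:
        lo, hi = gene.tss, gene.tss + window
    if lo >= hi:
        return None
    return GenomicInterval(gene.chrom, lo, hi)


def assign_se_targets(
    specific_ses: Sequence[tuple[GenomicInterval, str]],
    up_genes: Sequence[str],
    annotation: Sequence[GeneRecord],
    window: int = 500_000,
    de: pd.DataFrame | None = None,
) -> list[SETargetPair]:
    """Pair each upregulated gene with SEs in its upstream window.

    Strand-aware: for a + gene the window is [tss - window, tss), for a -
    gene [tss, tss + window); an SE pairs when it overlaps the window by
    at least 1 bp.  A gene may pair with several SEs and an SE with
    several genes.  ``distance`` is the bp gap from the TSS to the nearest
    SE base (0 when the SE spans the TSS side of the window boundary).
    """
    genes = {g.gene_id: g for g in annotation}
    pairs: list[SETargetPair] = []
    for gid in up_genes:
        if gid not in genes:
            continue
        gene = genes[gid]
        win = _upstream_window(gene, window)
        if win is None:
            continue
        log2fc = float(de.loc[gid, "log2fc"]) if de is not None else np.nan
        for se, label in specific_ses:
            if not se.overlaps(win):
                continue
            if gene.strand == "+":
                dist = gene.tss - min(se.end, gene.tss)
            else:
                dist = max(se.start, gene.tss) - gene.tss
            pairs.append(
                SETargetPair(
                    se_id=f"{se.chrom}:{se.start}-{se.end}",
                    gene_id=gid,
                    distance=int(dist),
                    se_label=label,
                    gene_log2fc=log2fc,
                )
            )
    return pairs


def geneset_overrepresentation(
    gene_list: Sequence[str],
    genesets: dict[str, set[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of ``gene_list`` in each geneset.

    Gene sets are intersected with the universe; BH across sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    if len(set(gene_list)) != len(gene_list):
        raise ValueError("gene_list contains duplicates")
    lst = set(gene_list)
    if not lst <= uni:
        raise ValueError("gene_list must be a subset of the universe")
    rows = []
    for name, members in genesets.items():
        S = members & uni
        k = len(lst & S)
        rows.append(
            {
                "geneset": name,
                "k": k,
                "K": len(S),
                "n": len(lst),
                "N": len(uni),
                "p": hypergeom_upper_tail(k, len(S), len(lst), len(uni)),
            }
        )
    out = pd.DataFrame(rows).set_index("geneset")
    out["adj_p"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def _running_es(in_set: np.ndarray, scores: np.ndarray, weight: float) -> float:
    """Signed max-magnitude deviation of the weighted KS running sum."""
    n = scores.size
    n_hit = int(in_set.sum())
    hit_w = np.abs(scores) ** weight
    hit_w = np.where(in_set, hit_w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit scores zero at weight>0: fall back to uniform
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~in_set) / (n - n_hit)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def preranked_enrichment(
    ranked_stats: pd.Series,
    geneset: set[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Preranked enrichment score with a gene-label permutation p-value.

    ``ranked_stats`` maps gene -> ranking score, sorted descending.  Hits
    advance the running sum proportionally to |score|^weight (normalized),
    misses retreat it by 1/(N - |S|); ES is the maximum-magnitude
    deviation.  The p-value is the add-one-smoothed fraction of random
    same-size genesets with |ES| at least as large.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = np.asarray(ranked_stats.index)
    scores = ranked_stats.to_numpy(dtype=float)
    if np.any(np.diff(scores) > 0):
        raise ValueError("ranked_stats must be sorted descending")
    in_set = np.isin(genes, list(geneset))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("geneset does not intersect the ranked list")
    if n_hit >= genes.size:
        raise ValueError("geneset must be smaller than the ranked list")
    es = _running_es(in_set, scores, weight)
    rng = np.random.default_rng(seed)
    n = genes.size
    exceed = 0
    for _ in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_hit, replace=False)] = True
        if abs(_running_es(perm, scores, weight)) >= abs(es):
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return es, p
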