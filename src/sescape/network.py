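"""SE co-occurrence network across samples: Jaccard edges on merged union
loci, hypergeometric edge significance with BH correction, and Markov
clustering (MCL) of the retained weighted graph.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .intervals import any_overlap, merge_intervals
from .stats import benjamini_hochberg, hypergeom_upper_tail, two_group_rank_test
from .types import GenomicInterval

__all__ = [
    "SESimilarityGraph",
    "se_jaccard",
    "se_cooccurrence_test",
    "build_similarity_network",
    "mcl_cluster",
    "within_between_similarity",
]


@dataclass
class SESimilarityGraph:
    """Sample-level SE similarity network.

    ``edges`` has one row per unordered sample pair with columns
    (a, b, jaccard, p, adj_p, retained); ``excluded`` lists samples with no
    retained edge; ``clusters`` maps sample -> cluster id once MCL has run.
    """

    samples: list[str]
    edges: pd.DataFrame
    excluded: list[str]
    clusters: dict[str, int] = field(default_factory=dict)

    def jaccard_matrix(self) -> pd.DataFrame:
        m = pd.DataFrame(
            np.eye(len(self.samples)), index=self.samples, columns=self.samples
        )
        for row in self.edges.itertuples():
            m.loc[row.a, row.b] = m.loc[row.b, row.a] = row.jaccard
        return m

    def retained_adjacency(self) -> pd.DataFrame:
        nodes = [s for s in self.samples if s not in self.excluded]
        m = pd.DataFrame(0.0, index=nodes, columns=nodes)
        for row in self.edges.itertuples():
            if row.retained:
                m.loc[row.a, row.b] = m.loc[row.b, row.a] = row.jaccard
        return m


def _hit_union(
    union_loci: Sequence[GenomicInterval], se_set: Sequence[GenomicInterval]
) -> np.ndarray:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in se_set:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    hits = np.zeros(len(union_loci), dtype=bool)
    for i, u in enumerate(union_loci):
        hits[i] = any_overlap(u, by_chrom.get(u.chrom, ()))
    return hits


def se_jaccard(
    setA: Sequence[GenomicInterval], setB: Sequence[GenomicInterval]
) -> tuple[float, int, int]:
    """Jaccard similarity of two SE sets on their merged union loci.

    The union of both sets is merged into loci; a locus counts as shared
    when at least one interval from each set overlaps it.  Returns
    (jaccard, n_shared, n_union).
    """
    if not setA and not setB:
        raise ValueError("Jaccard undefined: both SE sets are empty")
    union = merge_intervals(list(setA) + list(setB))
    both = _hit_union(union, setA) & _hit_union(union, setB)
    n_both, n_union = int(both.sum()), len(union)
    return n_both / n_union, n_both, n_union


def se_cooccurrence_test(
    setA: Sequence[GenomicInterval],
    setB: Sequence[GenomicInterval],
    universe_loci: Sequence[GenomicInterval],
) -> float:
    """Hypergeometric upper-tail p for SE co-occurrence on the cohort universe.

    The universe is the merged union of SEs over all samples (N loci); A
    hits K of them, B hits n, and k loci are hit by both.
    """
    hitsA = _hit_union(universe_loci, setA)
    hitsB = _hit_union(universe_loci, setB)
    K, n = int(hitsA.sum()), int(hitsB.sum())
    if K == 0 or n == 0:
        warnings.warn("one SE set hits no universe locus; p = 1")
        return 1.0
    k = int((hitsA & hitsB).sum())
    return hypergeom_upper_tail(k, K, n, len(universe_loci))


def build_similarity_network(
    se_sets: dict[str, list[GenomicInterval]],
    jaccard_min: float = 0.1,
    edge_alpha: float = 0.001,
) -> SESimilarityGraph:
    """All-pairs Jaccard + hypergeometric edges, BH-corrected, thresholded.

    An edge is retained iff jaccard > ``jaccard_min`` AND BH-adjusted
    p < ``edge_alpha``; samples with no retained edge are listed as
    excluded (they drop out of the clustered network).
    """
    samples = sorted(se_sets)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to build a network")
    universe = merge_intervals(
        iv for s in samples for iv in se_sets[s]
    )
    rows = []
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            jac, _, _ = se_jaccard(se_sets[a], se_sets[b])
            p = se_cooccurrence_test(se_sets[a], se_sets[b], universe)
            rows.append({"a": a, "b": b, "jaccard": jac, "p": p})
    edges = pd.DataFrame(rows)
    edges["adj_p"] = benjamini_hochberg(edges["p"].to_numpy())
    edges["retained"] = (edges["jaccard"] > jaccard_min) & (
        edges["adj_p"] < edge_alpha
    )
    connected = set(edges.loc[edges["retained"], "a"]) | set(
        edges.loc[edges["retained"], "b"]
    )
    excluded = [s for s in samples if s not in connected]
    return SESimilarityGraph(samples=samples, edges=edges, excluded=excluded)


def mcl_cluster(
    graph: SESimilarityGraph | pd.DataFrame,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 100,
) -> dict[str, int]:
    """Markov clustering of the retained weighted graph.

    Self-loops are added with the node's maximum incident weight, columns
    are normalized, then expansion (matrix power) and inflation
    (elementwise power + renormalization) alternate, pruning entries below
    ``prune``, until the matrix change falls below 1e-8.  Every node is
    assigned to the attractor row holding the largest share of its column
    mass.  Cluster ids are 0-based, ordered by first member.
    """
    adj = graph.retained_adjacency() if isinstance(graph, SESimilarityGraph) else graph
    nodes = list(adj.index)
    if not nodes:
        raise ValueError("empty graph: nothing to cluster")
    M = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(M, 0.0)
    incident_max = M.max(axis=1)
    # isolated nodes keep a unit self-loop so their column stays stochastic
    np.fill_diagonal(M, np.where(incident_max > 0, incident_max, 1.0))
    M = M / M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = np.linalg.matrix_power(M, expansion)
        inflated = expanded ** inflation
        inflated /= inflated.sum(axis=0, keepdims=True)
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.max(np.abs(inflated - M)) < 1e-8:
            M = inflated
            break
        M = inflated
    attractor_of = M.argmax(axis=0)  # per column: row with dominant mass
    cluster_ids: dict[int, int] = {}
    clusters: dict[str, int] = {}
    for j, node in enumerate(nodes):
        a = int(attractor_of[j])
        if a not in cluster_ids:
            cluster_ids[a] = len(cluster_ids)
        clusters[node] = cluster_ids[a]
    if isinstance(graph, SESimilarityGraph):
        graph.clusters = clusters
    return clusters


def within_between_similarity(
    graph: SESimilarityGraph, labels: dict[str, str]
) -> dict:
    """Mean pairwise Jaccard within each label group vs between groups.

    Returns the three stratum means and rank-sum p-values comparing each
    within-group stratum against the between-group stratum.
    """
    groups = sorted(set(labels[s] for s in graph.samples))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 label groups, got {groups}")
    gA, gB = groups
    within = {gA: [], gB: []}
    between = []
    for row in graph.edges.itertuples():
        la, lb = labels[row.a], labels[row.b]
        if la == lb:
            within[la].append(row.jaccard)
        else:
            between.append(row.jaccard)
    for g in (gA, gB):
        if len(within[g]) < 1:
            raise ValueError(f"group {g!r} has no within-group pair")
    if len(between) < 1:
        raise ValueError("no between-group pair")
    return {
        "groups": (gA, gB),
        "within_mean": {gA: float(np.mean(within[gA])), gB: float(np.mean(within[gB]))},
        "between_mean": float(np.mean(between)),
        "p_within_vs_between": {
            gA: two_group_rank_test(within[gA], between),
            gB: two_group_rank_test(within[gB], between),
        },
    }
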