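"""ARACNE-style regulatory network inference and master regulator analysis.

TF->target edges are scored by mutual information (copula-Gaussian by
default: Spearman rho mapped to the Gaussian MI closed form), tested by
sample permutation with BH correction, pruned by the data-processing
inequality (DPI), and the resulting regulons are tested for signature
overrepresentation with a hypergeometric test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import benjamini_hochberg, hypergeom_upper_tail

__all__ = [
    "select_regulators",
    "pairwise_mi",
    "mi_significance",
    "dpi_prune",
    "regulons_from_edges",
    "master_regulator_analysis",
]

_RHO_CAP = 1.0 - 1e-12


def _copula_mi_from_rho(rho) -> np.ndarray:
    """Gaussian MI implied by Spearman rho: rho_g = 2 sin(pi rho / 6)."""
    rho_g = 2.0 * np.sin(np.pi * np.asarray(rho, dtype=float) / 6.0)
    r2 = np.clip(rho_g**2, 0.0, _RHO_CAP)
    return -0.5 * np.log1p(-r2)


def pairwise_mi(x, y, estimator: str = "copula") -> float:
    """Mutual information (nats) between two expression vectors.

    ``copula`` (default) maps the Spearman correlation through the
    bivariate-Gaussian closed form; ``binned`` is the plug-in estimate on
    equal-frequency bins with B = floor(sqrt(n/5)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 10:
        raise ValueError("need n >= 10 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: MI = 0")
        return 0.0
    if estimator == "copula":
        rho = sps.spearmanr(x, y).statistic
        return float(_copula_mi_from_rho(rho))
    if estimator == "binned":
        B = max(2, int(np.sqrt(n / 5)))
        qx = np.searchsorted(np.quantile(x, np.linspace(0, 1, B + 1)[1:-1]), x)
        qy = np.searchsorted(np.quantile(y, np.linspace(0, 1, B + 1)[1:-1]), y)
        joint = np.zeros((B, B))
        np.add.at(joint, (qx, qy), 1.0)
        joint /= n
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = joint * np.log(joint / (px * py))
        return float(max(0.0, np.nansum(terms)))
    raise ValueError(f"unknown estimator {estimator!r}")


def select_regulators(
    pairs,
    de: pd.DataFrame,
    tf_flags: set[str],
    fe_log2fe_min: float = 1.0,
    fe_alpha: float = 0.05,
    tf_log2fc: float = 1.0,
    expr_alpha: float = 0.05,
    fe_table: pd.DataFrame | None = None,
) -> list[str]:
    """TFs regulated by group-specific SEs and strongly upregulated.

    A TF qualifies when it appears in an SE->target pair whose SE has
    log2FE > ``fe_log2fe_min`` at adjusted p < ``fe_alpha`` (looked up in
    ``fe_table`` by SE id), and its own expression shows
    log2FC > ``tf_log2fc`` at adjusted p < ``expr_alpha``.
    """
    chosen = []
    for pair in pairs:
        gid = pair.gene_id
        if gid not in tf_flags or gid in chosen:
            continue
        if fe_table is not None:
            if pair.se_id not in fe_table.index:
                continue
            fe_row = fe_table.loc[pair.se_id]
            if not (fe_row["log2fe"] > fe_log2fe_min and fe_row["adj_p"] < fe_alpha):
                continue
        if gid not in de.index:
            continue
        row = de.loc[gid]
        if row["log2fc"] > tf_log2fc and row["adj_p"] < expr_alpha:
            chosen.append(gid)
    if not chosen:
        warnings.warn("no TF passed the regulator thresholds")
    return chosen


def _rank_matrix(matrix: pd.DataFrame) -> np.ndarray:
    # centred, unit-norm ranks so rho is a plain dot product
    ranks = sps.rankdata(matrix.to_numpy(), axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return ranks / norms


def mi_significance(
    matrix: pd.DataFrame,
    regulators: list[str],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Permutation-tested copula MI for every TF x gene pair.

    For each regulator the sample labels of its vector are shuffled
    ``n_perm`` times; the permutation p is the add-one fraction of null MI
    values >= observed.  When ``groups`` maps samples to subtype labels,
    shuffling is stratified within each subtype, so MI explained purely by
    a subtype mean shift stays in the null and an edge must reflect
    within-subtype covariation — otherwise every differential gene would
    link to every differential TF.  BH across all pairs; edges kept at
    adjusted p < ``alpha``.  Returns the full edge table with a ``kept``
    flag.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    missing = [r for r in regulators if r not in matrix.index]
    if missing:
        raise ValueError(f"regulators not in matrix: {missing}")
    rng = np.random.default_rng(seed)
    n = matrix.shape[1]
    if groups is not None:
        strata = [
            np.flatnonzero(
                np.asarray([groups[s] for s in matrix.columns]) == g
            )
            for g in sorted(set(groups[s] for s in matrix.columns))
        ]
    else:
        strata = [np.arange(n)]

    def permute_rows(vec: np.ndarray) -> np.ndarray:
        out = np.tile(vec, (n_perm, 1))
        for idx in strata:
            for r in range(n_perm):
                out[r, idx] = out[r, idx[rng.permutation(idx.size)]]
        return out

    R = _rank_matrix(matrix)
    gene_index = {g: i for i, g in enumerate(matrix.index)}
    rows = []
    reg_set = set(regulators)
    for tf in regulators:
        t = R[gene_index[tf]]
        targets = [g for g in matrix.index if g not in reg_set]
        tgt_rows = np.array([gene_index[g] for g in targets])
        rho_obs = R[tgt_rows] @ t
        mi_obs = _copula_mi_from_rho(rho_obs)
        perms = permute_rows(t)
        rho_null = perms @ R[tgt_rows].T  # n_perm x targets
        mi_null = _copula_mi_from_rho(rho_null)
        exceed = (mi_null >= mi_obs[None, :]).sum(axis=0)
        pvals = (exceed + 1) / (n_perm + 1)
        for g, mi, p in zip(targets, mi_obs, pvals):
            rows.append({"tf": tf, "gene": g, "mi": float(mi), "p": float(p)})
    edges = pd.DataFrame(rows)
    edges["adj_p"] = benjamini_hochberg(edges["p"].to_numpy())
    edges["kept"] = edges["adj_p"] < alpha
    return edges


def dpi_prune(
    edges: pd.DataFrame,
    matrix: pd.DataFrame,
    tolerance: float = 0.01,
    estimator: str = "copula",
) -> pd.DataFrame:
    """Data-processing-inequality pruning of kept TF->gene edges.

    For every triplet (TF1, TF2, gene) where both TF->gene edges are kept,
    the TF-TF MI is computed on demand; the smallest of the three MIs is
    marked indirect when it is below min(other two) * (1 - tolerance).
    Only TF->gene edges are removable; marks are applied after scanning
    all triplets, so the result is order-independent.  Adds a
    ``kept_after_dpi`` column.
    """
    edges = edges.copy()
    kept = edges[edges["kept"]]
    mi_lookup: dict[tuple[str, str], float] = {
        (r.tf, r.gene): r.mi for r in kept.itertuples()
    }
    tfs = sorted(kept["tf"].unique())
    tf_mi: dict[tuple[str, str], float] = {}
    for i, t1 in enumerate(tfs):
        for t2 in tfs[i + 1 :]:
            m = pairwise_mi(
                matrix.loc[t1].to_numpy(), matrix.loc[t2].to_numpy(), estimator
            )
            tf_mi[(t1, t2)] = tf_mi[(t2, t1)] = m
    by_gene: dict[str, list[tuple[str, float]]] = {}
    for r in kept.itertuples():
        by_gene.setdefault(r.gene, []).append((r.tf, r.mi))
    to_remove: set[tuple[str, str]] = set()
    for gene, tf_edges in by_gene.items():
        for i in range(len(tf_edges)):
            for j in range(i + 1, len(tf_edges)):
                (t1, m1), (t2, m2) = tf_edges[i], tf_edges[j]
                m12 = tf_mi[(t1, t2)]
                triplet = [(m1, (t1, gene)), (m2, (t2, gene)), (m12, None)]
                triplet.sort(key=lambda z: z[0])
                smallest, key = triplet[0]
                if key is None:
                    continue  # the TF-TF link is weakest: nothing removable
                if smallest < min(triplet[1][0], triplet[2][0]) * (1 - tolerance):
                    to_remove.add(key)
    edges["kept_after_dpi"] = [
        bool(r.kept) and (r.tf, r.gene) not in to_remove for r in edges.itertuples()
    ]
    return edges


def regulons_from_edges(edges: pd.DataFrame) -> dict[str, set[str]]:
    """TF -> target set from the post-DPI edge table."""
    col = "kept_after_dpi" if "kept_after_dpi" in edges.columns else "kept"
    kept = edges[edges[col]]
    return {tf: set(sub["gene"]) for tf, sub in kept.groupby("tf")}


def master_regulator_analysis(
    regulons: dict[str, set[str]],
    signature: set[str],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of the signature in each regulon.

    Regulons and the signature are intersected with the universe; BH
    across TFs; the table is ranked by adjusted p, ties broken by larger
    overlap.
    """
    if not signature <= universe:
        raise ValueError("signature must be a subset of the universe")
    N = len(universe)
    K = len(signature)
    rows = []
    for tf, members in regulons.items():
        reg = members & universe
        k = len(reg & signature)
        if len(reg) == 0:
            warnings.warn(f"{tf}: empty regulon; p = 1")
            p = 1.0
        else:
            p = hypergeom_upper_tail(k, K, len(reg), N)
        rows.append(
            {"tf": tf, "regulon_size": len(reg), "signature_size": K,
             "overlap": k, "N": N, "p": p}
        )
    if not rows:
        return pd.DataFrame(
            columns=["tf", "regulon_size", "signature_size", "overlap", "N",
                     "p", "adj_p", "rank"]
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = benjamini_hochberg(out["p"].to_numpy())
    out = out.sort_values(
        ["adj_p", "overlap"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
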