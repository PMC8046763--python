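"""Synthetic multi-sample cohort with planted ground truth.

Emulates the statistical structure the SE landscape analysis assumes:
Poisson background signal with enriched enhancer clusters of varying
width, two sample groups (A standing in for TNBC, B for non-TNBC) that
share some SEs and own group-specific ones, a log2 expression matrix with
differential genes planted downstream of group-A-specific SEs, and
TF-driven regulons with one planted master regulator whose regulon
overlaps a signature geneset.

Every stochastic step derives its stream from one global seed plus the
sample index, so cohorts are reproducible and samples independent.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import merge_intervals
from .io import (
    write_annotation,
    write_bedgraph,
    write_expression,
    write_gmt,
    write_labels,
)
from .types import BinnedSignalTrack, GeneRecord, GenomicInterval

__all__ = [
    "CohortTruth",
    "simulate_genome",
    "simulate_chip_cohort",
    "simulate_expression",
    "write_cohort",
    "read_truth",
]


@dataclass
class CohortTruth:
    """Planted ground truth for one synthetic cohort."""

    seed: int
    bin_size: int
    background_rate: float
    enhancer_fold: float
    se_fold: float
    chrom_lengths: dict[str, int]
    group_labels: dict[str, str] = field(default_factory=dict)  # ChIP samples
    typical_enhancers: list[GenomicInterval] = field(default_factory=list)
    shared_ses: list[GenomicInterval] = field(default_factory=list)
    groupA_ses: list[GenomicInterval] = field(default_factory=list)
    groupB_ses: list[GenomicInterval] = field(default_factory=list)
    se_constituents: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    # filled by simulate_expression
    expr_labels: dict[str, str] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)
    regulator_tfs: list[str] = field(default_factory=list)
    regulons: dict[str, list[str]] = field(default_factory=dict)
    master_tf: str | None = None
    signature: list[str] = field(default_factory=list)

    def enriched_intervals(self, group: str) -> list[GenomicInterval]:
        """All bins truly above background for one group's samples."""
        ivs = list(self.typical_enhancers)
        for key in ("shared", "A" if group == "A" else "B"):
            ivs += self.se_constituents.get(key, [])
        return ivs

    def se_span_loci(self, group: str) -> list[GenomicInterval]:
        """Full SE spans (constituents + internal gaps) active in a group."""
        out = list(self.shared_ses)
        out += self.groupA_ses if group == "A" else self.groupB_ses
        return out


def simulate_genome(
    n_chrom: int = 1,
    chrom_length_bp: int = 5_000_000,
    n_genes: int = 300,
    tf_fraction: float = 0.1,
    seed: int = 0,
    min_spacing: int = 10_000,
    bin_size: int = 200,
) -> tuple[list[GeneRecord], dict[str, int]]:
    """Random gene annotation: uniform TSSs with a minimum spacing.

    Returns the gene list plus the chromosome length table.  TSSs are at
    least ``min_spacing`` apart; strands are fair coin flips; a
    ``tf_fraction`` share of genes is flagged as transcription factors.
    """
    if chrom_length_bp % bin_size != 0:
        raise ValueError("chrom_length_bp must be divisible by bin_size")
    if n_genes < 50:
        raise ValueError("need at least 50 genes")
    rng = np.random.default_rng(seed)
    per_chrom = [n_genes // n_chrom] * n_chrom
    for i in range(n_genes % n_chrom):
        per_chrom[i] += 1
    chrom_lengths = {f"chr{i + 1}": chrom_length_bp for i in range(n_chrom)}
    genes: list[GeneRecord] = []
    idx = 0
    for c, (chrom, L) in enumerate(chrom_lengths.items()):
        g = per_chrom[c]
        slack = L - (g - 1) * min_spacing
        if slack <= 0:
            raise ValueError(
                f"{chrom}: cannot place {g} genes {min_spacing} bp apart in {L} bp"
            )
        offsets = np.sort(rng.integers(0, slack, size=g))
        tss = offsets + np.arange(g) * min_spacing
        for t in tss:
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(f"g{idx:04d}", chrom, int(t), strand))
            idx += 1
    n_tf = int(round(n_genes * tf_fraction))
    tf_idx = set(rng.choice(n_genes, size=n_tf, replace=False).tolist())
    genes = [
        GeneRecord(g.gene_id, g.chrom, g.tss, g.strand, is_tf=(i in tf_idx))
        for i, g in enumerate(genes)
    ]
    return genes, chrom_lengths


def _forbidden_zones(
    annotation: list[GeneRecord], halfwidth: int
) -> list[GenomicInterval]:
    return merge_intervals(
        GenomicInterval(g.chrom, max(0, g.tss - halfwidth), g.tss + halfwidth)
        for g in annotation
    )


def _clashes(iv: GenomicInterval, zones: list[GenomicInterval]) -> bool:
    return any(iv.overlaps(z) for z in zones)


def _place_locus(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    span: int,
    bin_size: int,
    occupied: list[GenomicInterval],
    zones: list[GenomicInterval],
    max_tries: int = 2000,
    preferred: GenomicInterval | None = None,
) -> GenomicInterval:
    """Rejection-sample a bin-aligned locus avoiding promoters and other loci."""
    chroms = list(chrom_lengths)
    for attempt in range(max_tries):
        if preferred is not None and attempt < max_tries // 2:
            chrom = preferred.chrom
            lo = preferred.start
            hi = max(lo + 1, preferred.end - span)
        else:
            chrom = chroms[rng.integers(len(chroms))]
            lo, hi = 0, chrom_lengths[chrom] - span
        if hi <= lo:
            continue
        start = int(rng.integers(lo // bin_size, hi // bin_size + 1)) * bin_size
        iv = GenomicInterval(chrom, start, start + span)
        if iv.end > chrom_lengths[chrom]:
            continue
        if not _clashes(iv, zones) and not _clashes(iv, occupied):
            return iv
    raise ValueError(
        f"could not place a {span}-bp locus after {max_tries} tries: genome too crowded"
    )


def simulate_chip_cohort(
    annotation: list[GeneRecord],
    chrom_lengths: dict[str, int],
    n_per_group: int = 6,
    background_rate: float = 2.0,
    enhancer_fold: float = 8.0,
    se_cluster: tuple[int, int, int] = (6, 1000, 400),
    n_typical: int = 80,
    n_shared_se: int = 6,
    n_groupA_se: int = 8,
    n_groupB_se: int = 8,
    se_fold: float = 16.0,
    bin_size: int = 200,
    promoter_halfwidth: int = 2500,
    seed: int = 0,
) -> tuple[dict[str, BinnedSignalTrack], CohortTruth]:
    """Poisson signal tracks for two sample groups with planted enhancers.

    Typical enhancers (fold ``enhancer_fold`` over background) are shared
    by all samples; SEs are clusters of ``n_constituents`` enriched runs
    of ``constituent_width`` bp separated by ``gap`` bp, at ``se_fold``.
    Shared SEs are enriched in every sample, group-specific SEs only in
    their group.  All planted loci avoid promoter windows and each other.
    """
    if background_rate <= 0:
        raise ValueError("background_rate must be positive")
    if enhancer_fold <= 1 or se_fold <= 1:
        raise ValueError("enrichment folds must exceed 1")
    n_const, width, gap = se_cluster
    if width % bin_size or gap % bin_size:
        raise ValueError("constituent width and gap must be multiples of bin_size")
    rng = np.random.default_rng(seed)
    zones = _forbidden_zones(annotation, promoter_halfwidth)
    occupied: list[GenomicInterval] = []
    truth = CohortTruth(
        seed=seed,
        bin_size=bin_size,
        background_rate=background_rate,
        enhancer_fold=enhancer_fold,
        se_fold=se_fold,
        chrom_lengths=dict(chrom_lengths),
    )

    for _ in range(n_typical):
        w = int(rng.integers(5, 11)) * bin_size  # 1-2 kb
        iv = _place_locus(rng, chrom_lengths, w, bin_size, occupied, zones)
        occupied.append(iv)
        truth.typical_enhancers.append(iv)

    span = n_const * width + (n_const - 1) * gap
    tf_genes = [g for g in annotation if g.is_tf]
    tf_genes = [tf_genes[i] for i in rng.permutation(len(tf_genes))]
    tf_iter = iter(tf_genes)

    def upstream_window(g: GeneRecord, w: int = 400_000, margin: int = 5_000):
        if g.strand == "+":
            lo, hi = max(0, g.tss - w), max(0, g.tss - margin)
        else:
            lo, hi = g.tss + margin, min(chrom_lengths[g.chrom], g.tss + w)
        return GenomicInterval(g.chrom, lo, hi) if hi - lo > span else None

    def plant(n: int, key: str, bucket: list, near_tfs: bool) -> None:
        for _ in range(n):
            preferred = None
            if near_tfs:
                for g in tf_iter:
                    preferred = upstream_window(g)
                    if preferred is not None:
                        break
            iv = _place_locus(
                rng, chrom_lengths, span, bin_size, occupied, zones,
                preferred=preferred,
            )
            occupied.append(iv)
            bucket.append(iv)
            consts = truth.se_constituents.setdefault(key, [])
            for c in range(n_const):
                s = iv.start + c * (width + gap)
                consts.append(GenomicInterval(iv.chrom, s, s + width))

    plant(n_shared_se, "shared", truth.shared_ses, near_tfs=False)
    plant(n_groupA_se, "A", truth.groupA_ses, near_tfs=True)
    plant(n_groupB_se, "B", truth.groupB_ses, near_tfs=False)

    # per-group per-chromosome Poisson rate vectors
    def rate_vectors(group: str) -> dict[str, np.ndarray]:
        rates = {
            c: np.full(L // bin_size, background_rate)
            for c, L in chrom_lengths.items()
        }
        for iv in truth.typical_enhancers:
            rates[iv.chrom][iv.start // bin_size : iv.end // bin_size] = (
                background_rate * enhancer_fold
            )
        active = truth.se_constituents.get("shared", []) + truth.se_constituents.get(
            group, []
        )
        for iv in active:
            rates[iv.chrom][iv.start // bin_size : iv.end // bin_size] = (
                background_rate * se_fold
            )
        return rates

    tracks: dict[str, BinnedSignalTrack] = {}
    sample_idx = 0
    for group in ("A", "B"):
        rates = rate_vectors(group)
        for i in range(n_per_group):
            srng = np.random.default_rng([seed, sample_idx])
            counts = {c: srng.poisson(r).astype(np.int64) for c, r in rates.items()}
            sid = f"{group}{i + 1:02d}"
            total = int(sum(v.sum() for v in counts.values()))
            tracks[sid] = BinnedSignalTrack(
                sample_id=sid, bin_size=bin_size, counts=counts, total_mapped=total
            )
            truth.group_labels[sid] = group
            sample_idx += 1
    return tracks, truth


def _upstream_covers(
    gene: GeneRecord, se: GenomicInterval, window: int
) -> bool:
    if gene.chrom != se.chrom:
        return False
    if gene.strand == "+":
        lo, hi = max(0, gene.tss - window), gene.tss
    else:
        lo, hi = gene.tss, gene.tss + window
    return se.start < hi and lo < se.end


def simulate_expression(
    annotation: list[GeneRecord],
    truth: CohortTruth,
    n_per_group: int = 20,
    base_mean: float = 5.0,
    sd: float = 1.0,
    de_log2_effect: float = 1.5,
    tf_log2_effect: float = 2.0,
    n_regulons: int = 9,
    regulon_size: int = 20,
    beta: float = 0.8,
    noise_sd: float = 0.5,
    signature_overlap_fraction: float = 0.5,
    n_signature_extra: int = 30,
    target_window: int = 500_000,
    seed: int = 1,
) -> pd.DataFrame:
    """Log2 expression matrix with planted DE genes and TF regulons.

    Genes are Normal(base_mean, sd) on the log2 scale.  Genes downstream
    of a group-A-specific SE (the SE within their 500-kb upstream window)
    are shifted by ``de_log2_effect`` in group A; among them,
    ``n_regulons`` TFs become planted regulators whose (disjoint) regulons
    of ``regulon_size`` non-TF genes follow beta * standardized TF value
    plus noise.  Regulator TFs are planted as *notably* upregulated with
    the larger ``tf_log2_effect`` so their observed fold change clears the
    log2FC > 1 selection rule with margin at cohort-scale sample sizes.  The first regulator is the planted master TF: a
    ``signature_overlap_fraction`` share of its regulon joins the planted
    signature geneset.  Updates ``truth`` in place and returns the matrix.
    """
    rng = np.random.default_rng([seed, 10_000])
    genes = {g.gene_id: g for g in annotation}
    # candidate targets per group-A-specific SE
    tf_candidates: list[str] = []
    nontf_de: list[str] = []
    for se in truth.groupA_ses:
        cands = [
            g.gene_id for g in annotation if _upstream_covers(g, se, target_window)
        ]
        if not cands:
            raise ValueError(
                f"planted SE {se.chrom}:{se.start}-{se.end} has no gene within "
                f"{target_window} bp upstream windows"
            )
        for gid in cands:
            if genes[gid].is_tf and gid not in tf_candidates:
                tf_candidates.append(gid)
        nontf = [g for g in cands if not genes[g].is_tf and g not in nontf_de]
        picked = rng.choice(nontf, size=min(2, len(nontf)), replace=False)
        nontf_de.extend(picked.tolist())
    if not tf_candidates:
        raise ValueError("no TF gene lies downstream of any group-A-specific SE")
    k = min(n_regulons, len(tf_candidates))
    regulators = list(rng.choice(tf_candidates, size=k, replace=False))
    master = regulators[0]

    de_genes = {gid: tf_log2_effect for gid in regulators}
    de_genes.update({gid: de_log2_effect for gid in nontf_de})

    non_tf_pool = [
        g.gene_id
        for g in annotation
        if not g.is_tf and g.gene_id not in de_genes
    ]
    needed = len(regulators) * regulon_size
    if needed > len(non_tf_pool):
        raise ValueError(
            f"regulon_size too large: need {needed} member genes, "
            f"only {len(non_tf_pool)} available"
        )
    pool = list(rng.permutation(non_tf_pool))
    regulons = {
        tf: pool[i * regulon_size : (i + 1) * regulon_size]
        for i, tf in enumerate(regulators)
    }
    leftover = pool[needed:]
    n_overlap = int(round(signature_overlap_fraction * regulon_size))
    if n_signature_extra > len(leftover):
        raise ValueError("not enough genes outside regulons for the signature")
    signature = list(regulons[master][:n_overlap]) + list(
        rng.choice(leftover, size=n_signature_extra, replace=False)
    )

    sample_ids = [f"T{g}{i + 1:02d}" for g in ("A", "B") for i in range(n_per_group)]
    labels = {s: s[1] for s in sample_ids}
    gene_ids = [g.gene_id for g in annotation]
    gidx = {g: i for i, g in enumerate(gene_ids)}
    mat = np.empty((len(gene_ids), len(sample_ids)))
    for j, s in enumerate(sample_ids):
        srng = np.random.default_rng([seed, 20_000 + j])
        mat[:, j] = srng.normal(base_mean, sd, size=len(gene_ids))
    a_cols = np.array([labels[s] == "A" for s in sample_ids])
    for gid, eff in de_genes.items():
        mat[gidx[gid], a_cols] += eff
    for tf, members in regulons.items():
        tf_vals = mat[gidx[tf]]
        z = (tf_vals - tf_vals.mean()) / tf_vals.std()
        mrng = np.random.default_rng([seed, 30_000 + gidx[tf]])
        for m in members:
            mat[gidx[m]] = base_mean + beta * z + mrng.normal(
                0, noise_sd, size=len(sample_ids)
            )

    truth.expr_labels = labels
    truth.de_genes = de_genes
    truth.regulator_tfs = regulators
    truth.regulons = regulons
    truth.master_tf = master
    truth.signature = signature
    return pd.DataFrame(mat, index=gene_ids, columns=sample_ids)


# ---------------------------------------------------------------------------
# on-disk cohort


def write_cohort(
    out_dir: str | Path,
    annotation: list[GeneRecord],
    tracks: dict[str, BinnedSignalTrack],
    truth: CohortTruth,
    expression: pd.DataFrame,
    n_decoy_genesets: int = 5,
    decoy_size: int = 40,
) -> None:
    """Write the full cohort (tracks, annotation, labels, expression,
    genesets, TF list, truth tables) under ``out_dir``."""
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    for sid, track in tracks.items():
        write_bedgraph(track, out / "tracks" / f"{sid}.bedgraph")
    write_annotation(annotation, out / "genes.bed")
    write_labels(truth.group_labels, out / "labels.tsv")
    write_labels(truth.expr_labels, out / "expr_labels.tsv")
    write_expression(expression, out / "expression.tsv")
    tf_ids = sorted(g.gene_id for g in annotation if g.is_tf)
    (out / "tfs.txt").write_text("\n".join(tf_ids) + "\n")

    rng = np.random.default_rng([truth.seed, 40_000])
    gene_ids = [g.gene_id for g in annotation]
    sets = {"SIG_PLANTED_HALLMARK": set(truth.signature)}
    for i in range(n_decoy_genesets):
        sets[f"SIG_DECOY_{i + 1}"] = set(
            rng.choice(gene_ids, size=decoy_size, replace=False)
        )
    write_gmt(sets, out / "hallmarks.gmt")
    write_truth(truth, out / "truth")


def write_truth(truth: CohortTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    loci_rows = []
    for cat, ivs in (
        ("typical", truth.typical_enhancers),
        ("shared_se", truth.shared_ses),
        ("groupA_se", truth.groupA_ses),
        ("groupB_se", truth.groupB_ses),
    ):
        loci_rows += [
            {"category": cat, "chrom": iv.chrom, "start": iv.start, "end": iv.end}
            for iv in ivs
        ]
    for key, ivs in truth.se_constituents.items():
        loci_rows += [
            {
                "category": f"constituent_{key}",
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
            }
            for iv in ivs
        ]
    pd.DataFrame(loci_rows).to_csv(out / "loci.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene": g, "log2_effect": e} for g, e in truth.de_genes.items()]
    ).to_csv(out / "de_genes.tsv", sep="\t", index=False)
    reg_rows = [
        {"tf": tf, "member": m} for tf, ms in truth.regulons.items() for m in ms
    ]
    pd.DataFrame(reg_rows).to_csv(out / "regulons.tsv", sep="\t", index=False)
    meta = {
        "seed": truth.seed,
        "bin_size": truth.bin_size,
        "background_rate": truth.background_rate,
        "enhancer_fold": truth.enhancer_fold,
        "se_fold": truth.se_fold,
        "master_tf": truth.master_tf or "",
        "chrom_lengths": ";".join(f"{c}={L}" for c, L in truth.chrom_lengths.items()),
        "signature": ";".join(truth.signature),
        "regulator_tfs": ";".join(truth.regulator_tfs),
    }
    pd.DataFrame([{"key": k, "value": v} for k, v in meta.items()]).to_csv(
        out / "meta.tsv", sep="\t", index=False
    )


def read_truth(out_dir: str | Path) -> CohortTruth:
    out = Path(out_dir)
    meta = dict(
        pd.read_csv(out / "meta.tsv", sep="\t", dtype=str).itertuples(
            index=False, name=None
        )
    )
    chrom_lengths = {
        kv.split("=")[0]: int(kv.split("=")[1])
        for kv in meta["chrom_lengths"].split(";")
    }
    truth = CohortTruth(
        seed=int(meta["seed"]),
        bin_size=int(meta["bin_size"]),
        background_rate=float(meta["background_rate"]),
        enhancer_fold=float(meta["enhancer_fold"]),
        se_fold=float(meta["se_fold"]),
        chrom_lengths=chrom_lengths,
    )
    truth.master_tf = meta["master_tf"] or None
    truth.signature = meta["signature"].split(";") if meta["signature"] else []
    truth.regulator_tfs = (
        meta["regulator_tfs"].split(";") if meta["regulator_tfs"] else []
    )
    loci = pd.read_csv(out / "loci.tsv", sep="\t")
    buckets = {
        "typical": truth.typical_enhancers,
        "shared_se": truth.shared_ses,
        "groupA_se": truth.groupA_ses,
        "groupB_se": truth.groupB_ses,
    }
    for row in loci.itertuples():
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        if row.category in buckets:
            buckets[row.category].append(iv)
        elif row.category.startswith("constituent_"):
            key = row.category.removeprefix("constituent_")
            truth.se_constituents.setdefault(key, []).append(iv)
    de = pd.read_csv(out / "de_genes.tsv", sep="\t")
    truth.de_genes = dict(zip(de["gene"], de["log2_effect"].astype(float)))
    reg = pd.read_csv(out / "regulons.tsv", sep="\t")
    if len(reg):
        for tf, sub in reg.groupby("tf", sort=False):
            truth.regulons[tf] = list(sub["member"])
    return truth
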