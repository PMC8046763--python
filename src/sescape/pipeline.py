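"""End-to-end orchestration of the SE landscape analysis.

Stages run in the order of the original analysis: simulate (optional) ->
enhancer calling -> SE calling -> similarity network -> differential SEs
-> target genes -> regulatory network / master regulators.  Each stage
writes plain TSV/BED outputs with parameter header comments, and a JSON
manifest records the configuration, seed and output digests.
"""
from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffse as dse
from . import network as net
from . import regnet, secall, targets
from .config import PipelineConfig
from .enhancers import call_enhancers
from .io import (
    get_logger,
    read_annotation,
    read_bedgraph,
    read_expression,
    read_gmt,
    read_labels,
    read_tf_list,
    write_bed,
)
from .synth import (
    simulate_chip_cohort,
    simulate_expression,
    simulate_genome,
    write_cohort,
)
from .types import EnhancerRegion, GenomicInterval

__all__ = ["SimulationParams", "run_all", "stage_seed"]

log = get_logger(__name__)


@dataclass
class SimulationParams:
    """Demo cohort conditions: one 5-Mb chromosome, 6+6 ChIP samples,
    Poisson(2) background with 8x typical enhancers and 16x SEs, a 20+20
    expression cohort with 9 planted regulons."""

    n_chrom: int = 1
    chrom_length_bp: int = 5_000_000
    n_genes: int = 300
    tf_fraction: float = 0.1
    n_per_group: int = 6
    background_rate: float = 2.0
    enhancer_fold: float = 8.0
    se_cluster: tuple[int, int, int] = (6, 1000, 400)
    n_typical: int = 80
    n_shared_se: int = 6
    n_groupA_se: int = 8
    n_groupB_se: int = 8
    se_fold: float = 16.0
    bin_size: int = 200
    expr_n_per_group: int = 20
    base_mean: float = 5.0
    sd: float = 1.0
    de_log2_effect: float = 1.5
    tf_log2_effect: float = 2.0
    n_regulons: int = 9
    regulon_size: int = 20
    beta: float = 0.8
    noise_sd: float = 0.5
    signature_overlap_fraction: float = 0.5


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed from the global seed."""
    return (int(base_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _write_tsv(df: pd.DataFrame, path: Path, params: dict | None = None,
               index: bool = True, index_label: str | None = None) -> None:
    header = "".join(f"# {k}={v}\n" for k, v in (params or {}).items())
    body = df.to_csv(sep="\t", index=index, index_label=index_label,
                     float_format="%.8g")
    path.write_text(header + body)


def simulate_stage(cfg: PipelineConfig, sim: SimulationParams, out: Path) -> Path:
    seed = stage_seed(cfg.seed, "simulate")
    annotation, chrom_lengths = simulate_genome(
        n_chrom=sim.n_chrom,
        chrom_length_bp=sim.chrom_length_bp,
        n_genes=sim.n_genes,
        tf_fraction=sim.tf_fraction,
        seed=seed,
        bin_size=sim.bin_size,
    )
    tracks, truth = simulate_chip_cohort(
        annotation,
        chrom_lengths,
        n_per_group=sim.n_per_group,
        background_rate=sim.background_rate,
        enhancer_fold=sim.enhancer_fold,
        se_cluster=sim.se_cluster,
        n_typical=sim.n_typical,
        n_shared_se=sim.n_shared_se,
        n_groupA_se=sim.n_groupA_se,
        n_groupB_se=sim.n_groupB_se,
        se_fold=sim.se_fold,
        bin_size=sim.bin_size,
        promoter_halfwidth=cfg.promoter_halfwidth,
        seed=seed,
    )
    expr = simulate_expression(
        annotation,
        truth,
        n_per_group=sim.expr_n_per_group,
        base_mean=sim.base_mean,
        sd=sim.sd,
        de_log2_effect=sim.de_log2_effect,
        tf_log2_effect=sim.tf_log2_effect,
        n_regulons=sim.n_regulons,
        regulon_size=sim.regulon_size,
        beta=sim.beta,
        noise_sd=sim.noise_sd,
        signature_overlap_fraction=sim.signature_overlap_fraction,
        target_window=cfg.target_window,
        seed=seed,
    )
    cohort = out / "cohort"
    write_cohort(cohort, annotation, tracks, truth, expr)
    log.info("simulate: %d samples, %d genes", len(tracks), len(annotation))
    return cohort


def enhancer_stage(cfg: PipelineConfig, tracks_dir: Path, annotation_path: Path,
                   out: Path) -> dict[str, list[EnhancerRegion]]:
    annotation = read_annotation(annotation_path)
    out.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(cfg.seed, "call-enhancers")
    result: dict[str, list[EnhancerRegion]] = {}
    for path in sorted(tracks_dir.glob("*.bedgraph")):
        track = read_bedgraph(path)
        regions, _ = call_enhancers(
            track,
            annotation,
            promoter_halfwidth=cfg.promoter_halfwidth,
            stitch_gap=cfg.stitch_gap,
            seed=seed,
        )
        result[track.sample_id] = regions
        write_bed(
            [
                GenomicInterval(r.interval.chrom, r.interval.start, r.interval.end,
                                score=r.density, sample_id=track.sample_id)
                for r in regions
            ],
            out / f"{track.sample_id}.bed",
            header_comments=[f"sample={track.sample_id}",
                             f"promoter_halfwidth={cfg.promoter_halfwidth}",
                             f"stitch_gap={cfg.stitch_gap}"],
        )
    if not result:
        raise FileNotFoundError(f"no *.bedgraph tracks found in {tracks_dir}")
    return result


def se_stage(cfg: PipelineConfig, enhancers: dict[str, list[EnhancerRegion]],
             out: Path, metric: str = "length") -> dict[str, secall.SECallResult]:
    out.mkdir(parents=True, exist_ok=True)
    calls: dict[str, secall.SECallResult] = {}
    summary = []
    for sid in sorted(enhancers):
        res = secall.call_superenhancers(
            enhancers[sid], metric=metric, span=cfg.loess_span, sample_id=sid
        )
        calls[sid] = res
        write_bed(
            [
                GenomicInterval(e.interval.chrom, e.interval.start, e.interval.end,
                                score=e.density, sample_id=sid)
                for e in res.superenhancers
            ],
            out / f"{sid}.se.bed",
            header_comments=[f"metric={metric}", f"cutoff={res.cutoff}"],
        )
        summary.append(
            {"sample": sid, "n_enhancers": len(enhancers[sid]),
             "n_se": res.n_se, "cutoff": res.cutoff}
        )
    _write_tsv(pd.DataFrame(summary), out / "summary.tsv",
               {"metric": metric, "span": cfg.loess_span}, index=False)
    return calls


def network_stage(cfg: PipelineConfig, se_calls: dict[str, secall.SECallResult],
                  labels: dict[str, str], out: Path) -> net.SESimilarityGraph:
    out.mkdir(parents=True, exist_ok=True)
    se_sets = {
        sid: [e.interval for e in res.superenhancers]
        for sid, res in se_calls.items()
    }
    graph = net.build_similarity_network(
        se_sets, jaccard_min=cfg.jaccard_min, edge_alpha=cfg.edge_alpha
    )
    net.mcl_cluster(graph, inflation=cfg.mcl_inflation)
    _write_tsv(graph.edges, out / "edges.tsv",
               {"jaccard_min": cfg.jaccard_min, "edge_alpha": cfg.edge_alpha},
               index=False)
    _write_tsv(
        pd.DataFrame(
            [{"sample": s, "cluster": c, "group": labels.get(s, "")}
             for s, c in graph.clusters.items()]
        ),
        out / "clusters.tsv", {"inflation": cfg.mcl_inflation}, index=False,
    )
    (out / "excluded.txt").write_text("\n".join(graph.excluded) + "\n")
    sim = net.within_between_similarity(graph, labels)
    gA, gB = sim["groups"]
    _write_tsv(
        pd.DataFrame([{
            "within_" + gA: sim["within_mean"][gA],
            "within_" + gB: sim["within_mean"][gB],
            "between": sim["between_mean"],
            "p_" + gA: sim["p_within_vs_between"][gA],
            "p_" + gB: sim["p_within_vs_between"][gB],
        }]),
        out / "similarity_summary.tsv", index=False,
    )
    return graph


def diffse_stage(cfg: PipelineConfig, se_calls, tracks: dict, labels, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    se_sets = {
        sid: [e.interval for e in res.superenhancers]
        for sid, res in se_calls.items()
    }
    unionA, unionB, union_all, venn = dse.union_se_loci(se_sets, labels)
    densities = dse.density_matrix(union_all, tracks, flank=cfg.flank)
    table = dse.differential_se_test(
        densities, labels, epsilon=cfg.density_epsilon
    )
    gA, gB = sorted(set(labels.values()))
    table["label"] = [
        dse.classify_specific(r.log2fe, r.adj_p, cfg.diff_log2fe, cfg.diff_alpha,
                              group_names=(gA, gB))
        for r in table.itertuples()
    ]
    # per-group co-occurrence: samples whose SEs overlap each union locus
    for grp in (gA, gB):
        members = [s for s in se_sets if labels[s] == grp]
        table[f"n_samples_{grp}"] = [
            sum(
                any(iv.overlaps(_parse_locus(lid)) for iv in se_sets[s])
                for s in members
            )
            for lid in table.index
        ]
    _write_tsv(table, out / "union_se.tsv",
               {"flank": cfg.flank, "epsilon": cfg.density_epsilon,
                "diff_log2fe": cfg.diff_log2fe, "diff_alpha": cfg.diff_alpha,
                "venn_a_only": venn.a_only, "venn_b_only": venn.b_only,
                "venn_shared_a": venn.shared_a, "venn_shared_b": venn.shared_b},
               index_label="locus")
    for name, ivs in (("union_" + gA, unionA), ("union_" + gB, unionB),
                      ("union_all", union_all)):
        write_bed(ivs, out / f"{name}.bed")
    for lab in (f"{gA}-specific", f"{gB}-specific", "shared"):
        ivs = [_parse_locus(lid) for lid in table.index[table["label"] == lab]]
        write_bed(ivs, out / f"{lab}.bed")
    return union_all, table, venn


def _parse_locus(lid: str) -> GenomicInterval:
    chrom, rest = lid.rsplit(":", 1)
    s, e = rest.split("-")
    return GenomicInterval(chrom, int(s), int(e))


def targets_stage(cfg: PipelineConfig, diff_table: pd.DataFrame,
                  expr: pd.DataFrame, expr_labels: dict, annotation_path: Path,
                  gmt_path: Path, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    annotation = read_annotation(annotation_path)
    de = targets.differential_expression(expr, expr_labels)
    _write_tsv(de, out / "de.tsv", {"de_log2fc": cfg.de_log2fc,
                                    "alpha": cfg.diff_alpha},
               index_label="gene_id")
    up = targets.upregulated_genes(de, cfg.de_log2fc, cfg.diff_alpha)
    gA = sorted(set(expr_labels.values()))[0]
    specific = [
        (_parse_locus(lid), row.label)
        for lid, row in diff_table.iterrows()
        if row.label == f"{gA}-specific"
    ]
    pairs = targets.assign_se_targets(specific, up, annotation,
                                      window=cfg.target_window, de=de)
    _write_tsv(pd.DataFrame([vars(p) for p in pairs]), out / "pairs.tsv",
               {"target_window": cfg.target_window}, index=False)
    genesets = read_gmt(gmt_path)
    universe = list(expr.index)
    enrich = targets.geneset_overrepresentation(up, genesets, universe)
    _write_tsv(enrich, out / "genesets.tsv", index_label="geneset")
    ranked = de["log2fc"].sort_values(ascending=False)
    target_genes = {p.gene_id for p in pairs}
    gsea_rows = []
    if target_genes and len(target_genes) < len(ranked):
        es, p = targets.preranked_enrichment(
            ranked, target_genes, weight=1.0, n_perm=1000,
            seed=stage_seed(cfg.seed, "gsea"),
        )
        gsea_rows.append({"geneset": "se_target_genes", "es": es, "p": p,
                          "size": len(target_genes)})
    _write_tsv(pd.DataFrame(gsea_rows), out / "gsea.tsv", index=False)
    return de, pairs


def regnet_stage(cfg: PipelineConfig, de: pd.DataFrame, pairs, diff_table,
                 expr: pd.DataFrame, tf_path: Path, gmt_path: Path, out: Path,
                 expr_labels: dict[str, str] | None = None):
    out.mkdir(parents=True, exist_ok=True)
    tf_flags = read_tf_list(tf_path)
    regulators = regnet.select_regulators(
        pairs, de, tf_flags,
        fe_log2fe_min=cfg.diff_log2fe, fe_alpha=cfg.diff_alpha,
        tf_log2fc=cfg.tf_log2fc, expr_alpha=cfg.diff_alpha,
        fe_table=diff_table,
    )
    if not regulators:
        raise RuntimeError("regnet: no regulator TF passed the thresholds")
    up = targets.upregulated_genes(de, cfg.de_log2fc, cfg.diff_alpha)
    pool = sorted(set(up) | set(regulators))
    sub = expr.loc[pool]
    edges = regnet.mi_significance(
        sub, regulators, n_perm=1000, alpha=cfg.diff_alpha,
        seed=stage_seed(cfg.seed, "regnet"), groups=expr_labels,
    )
    edges = regnet.dpi_prune(edges, sub)
    _write_tsv(edges, out / "edges.tsv",
               {"regulators": ",".join(regulators)}, index=False)
    regulons = regnet.regulons_from_edges(edges)
    from .io import write_gmt

    write_gmt({tf: set(m) for tf, m in regulons.items()}, out / "regulons.gmt")
    genesets = read_gmt(gmt_path)
    universe = set(sub.index)
    mra_tables = []
    for name, sig in genesets.items():
        sig_u = sig & universe
        if not sig_u:
            continue
        mra = regnet.master_regulator_analysis(regulons, sig_u, universe)
        mra.insert(0, "signature", name)
        mra_tables.append(mra)
    mra_all = pd.concat(mra_tables, ignore_index=True)
    _write_tsv(mra_all, out / "mra.tsv", index=False)
    return regulators, regulons, mra_all


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    cfg: PipelineConfig,
    out_dir: str | Path,
    sim: SimulationParams | None = None,
    cohort_dir: str | Path | None = None,
) -> dict:
    """Run every stage; simulate a cohort first unless one is supplied.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if cohort_dir is None:
        cohort = simulate_stage(cfg, sim or SimulationParams(), out)
    else:
        cohort = Path(cohort_dir)
    for required in ("labels.tsv", "genes.bed", "expression.tsv",
                     "expr_labels.tsv", "tfs.txt", "hallmarks.gmt"):
        if not (cohort / required).exists():
            raise FileNotFoundError(f"missing cohort input: {cohort / required}")
    labels = read_labels(cohort / "labels.tsv")
    tracks = {
        p.stem: read_bedgraph(p) for p in sorted((cohort / "tracks").glob("*.bedgraph"))
    }
    stage = "call-enhancers"
    try:
        enhancers = enhancer_stage(cfg, cohort / "tracks", cohort / "genes.bed",
                                   out / "enhancers")
        stage = "call-se"
        se_calls = se_stage(cfg, enhancers, out / "se")
        stage = "network"
        network_stage(cfg, se_calls, labels, out / "network")
        stage = "diffse"
        _, diff_table, _ = diffse_stage(cfg, se_calls, tracks, labels,
                                        out / "diffse")
        stage = "targets"
        expr = read_expression(cohort / "expression.tsv")
        expr_labels = read_labels(cohort / "expr_labels.tsv")
        de, pairs = targets_stage(cfg, diff_table, expr, expr_labels,
                                  cohort / "genes.bed", cohort / "hallmarks.gmt",
                                  out / "targets")
        stage = "regnet"
        regnet_stage(cfg, de, pairs, diff_table, expr, cohort / "tfs.txt",
                     cohort / "hallmarks.gmt", out / "regnet",
                     expr_labels=expr_labels)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "elapsed_s": round(time.time() - t0, 2),
        "outputs": {
            str(p.relative_to(out)): _digest(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    log.info("run-all finished in %.1f s", manifest["elapsed_s"])
    return manifest
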