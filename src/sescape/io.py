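"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything on disk is BED-convention (0-based half-open) and tab-separated.
bedGraph tracks carry their sample metadata in ``#`` header comments so a
track file is self-describing; runs of equal bin values are run-length
encoded as bedGraph permits.
"""
from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BinnedSignalTrack, GeneRecord, GenomicInterval

__all__ = [
    "get_logger",
    "setup_logging",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_annotation",
    "write_annotation",
    "read_labels",
    "write_labels",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_tf_list",
]

_LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s: %(message)s"


def get_logger(name: str = "sescape") -> logging.Logger:
    return logging.getLogger(name)


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(_LOG_FORMAT))
    root = logging.getLogger("sescape")
    root.handlers[:] = [handler]
    root.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# BED intervals


def read_bed(path: str | Path, sample_id: str | None = None) -> list[GenomicInterval]:
    """Read BED3/BED6; the score column (5th) becomes the interval score."""
    out: list[GenomicInterval] = []
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith(("#", "track", "browser")):
            continue
        f = raw.rstrip("\n").split("\t")
        score = None
        if len(f) >= 5 and f[4] not in (".", ""):
            score = float(f[4])
        out.append(
            GenomicInterval(f[0], int(f[1]), int(f[2]), score=score, sample_id=sample_id)
        )
    return out


def write_bed(
    intervals, path: str | Path, header_comments: list[str] | None = None
) -> None:
    lines = [f"# {c}" for c in (header_comments or [])]
    for i, iv in enumerate(intervals):
        name = iv.sample_id or f"region_{i}"
        score = f"{iv.score:.6g}" if iv.score is not None else "."
        lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# bedGraph signal tracks


def write_bedgraph(track: BinnedSignalTrack, path: str | Path) -> None:
    lines = [
        f"# sample_id={track.sample_id}",
        f"# bin_size={track.bin_size}",
        f"# total_mapped={track.total_mapped}",
    ]
    bs = track.bin_size
    for chrom in sorted(track.counts):
        vec = track.counts[chrom]
        if len(vec) == 0:
            continue
        # run-length encode equal adjacent bin values
        change = np.flatnonzero(np.diff(vec)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(vec)]])
        for s, e in zip(starts, ends):
            lines.append(f"{chrom}\t{s * bs}\t{e * bs}\t{int(vec[s])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bedgraph(path: str | Path) -> BinnedSignalTrack:
    """Read a binned bedGraph written by :func:`write_bedgraph`.

    Intervals spanning several bins are expanded; a partial last bin is
    allowed and padded to a full bin.
    """
    meta: dict[str, str] = {}
    rows: list[tuple[str, int, int, int]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        if line.startswith(("track", "browser")):
            continue
        f = line.split("\t")
        rows.append((f[0], int(f[1]), int(f[2]), int(float(f[3]))))
    for key in ("sample_id", "bin_size", "total_mapped"):
        if key not in meta:
            raise ValueError(f"{path}: missing '# {key}=' header")
    bs = int(meta["bin_size"])
    chrom_len: dict[str, int] = {}
    for chrom, _s, e, _v in rows:
        chrom_len[chrom] = max(chrom_len.get(chrom, 0), e)
    counts = {
        chrom: np.zeros(-(-L // bs), dtype=np.int64) for chrom, L in chrom_len.items()
    }
    for chrom, s, e, v in rows:
        if s % bs != 0:
            raise ValueError(f"{path}: interval start {s} not on a {bs}-bp bin edge")
        counts[chrom][s // bs : -(-e // bs)] = v
    return BinnedSignalTrack(
        sample_id=meta["sample_id"],
        bin_size=bs,
        counts=counts,
        total_mapped=int(meta["total_mapped"]),
    )


# ---------------------------------------------------------------------------
# gene annotation (BED6: chrom, tss, tss+1, gene_id, is_tf, strand)


def write_annotation(genes, path: str | Path) -> None:
    lines = []
    for g in genes:
        lines.append(
            f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t{int(g.is_tf)}\t{g.strand}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation(path: str | Path) -> list[GeneRecord]:
    out = []
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        f = raw.rstrip("\n").split("\t")
        out.append(
            GeneRecord(
                gene_id=f[3],
                chrom=f[0],
                tss=int(f[1]),
                strand=f[5],
                is_tf=bool(int(f[4])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# labels, expression, genesets


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    lines = ["sample\tgroup"] + [f"{s}\t{g}" for s, g in labels.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ValueError(f"{path}: expected header 'sample\\tgroup'")
    return dict(zip(df["sample"], df["group"]))


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    """Genes x samples matrix of log2 values, gene ids as the index."""
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT genesets: name <tab> description <tab> member genes."""
    sets: dict[str, set[str]] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        f = raw.rstrip("\n").split("\t")
        if len(f) < 3:
            raise ValueError(f"{path}: GMT line needs name, description, >=1 gene")
        sets[f[0]] = set(f[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = ".") -> None:
    lines = [
        "\t".join([name, description, *sorted(members)])
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_tf_list(path: str | Path) -> set[str]:
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
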