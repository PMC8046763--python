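"""Pipeline configuration: the thresholds of the published analysis,
with the units they are stated in.
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["PipelineConfig", "read_config", "write_config"]


@dataclass
class PipelineConfig:
    """All tunable thresholds of the SE landscape analysis.

    Defaults are the published cut-offs: promoter exclusion +/- 2.5 kb of
    TSS, 200-bp flanks for density quantification, SE->target windows of
    500 kb upstream, network edges at Jaccard > 0.1 and BH-adjusted
    p < 0.001, subtype-specific SEs at |log2FE| > 1 and adjusted p < 0.05,
    upregulated genes at log2FC > 0.5, regulator TFs at log2FC > 1.
    """

    promoter_halfwidth: int = 2500  # bp either side of the TSS
    flank: int = 200  # bp added to each SE end before density
    target_window: int = 500_000  # bp upstream for SE->gene pairing
    jaccard_min: float = 0.1
    edge_alpha: float = 0.001
    diff_alpha: float = 0.05
    diff_log2fe: float = 1.0
    de_log2fc: float = 0.5
    tf_log2fc: float = 1.0
    mcl_inflation: float = 2.0
    loess_span: float = 0.25
    seed: int = 0
    stitch_gap: int = 0  # 0 = no stitching of called enhancers
    density_epsilon: float = 1e-4  # rpm/bp pseudo-density for fold ratios

    def __post_init__(self) -> None:
        for name in (
            "promoter_halfwidth",
            "flank",
            "target_window",
            "jaccard_min",
            "diff_log2fe",
            "de_log2fc",
            "tf_log2fc",
            "mcl_inflation",
            "loess_span",
            "density_epsilon",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("edge_alpha", "diff_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.stitch_gap < 0:
            raise ValueError("stitch_gap must be >= 0")


def read_config(path: str | Path) -> PipelineConfig:
    """Parse a ``key: value`` text file into a PipelineConfig.

    Blank lines and ``#`` comments are ignored; unknown keys are an error.
    """
    known = {f.name: f.type for f in fields(PipelineConfig)}
    kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key, val = (s.strip() for s in line.split(":", 1))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        ann = known[key]
        kwargs[key] = int(val) if ann == "int" else float(val)
    return PipelineConfig(**kwargs)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    lines = [f"{f.name}: {getattr(cfg, f.name)}" for f in fields(PipelineConfig)]
    Path(path).write_text("\n".join(lines) + "\n")
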