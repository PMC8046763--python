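"""Separating super-enhancers from typical enhancers.

Enhancers are ranked by a size metric (genomic length by default, total
H3K27ac load optionally), both axes are min-max scaled to [0, 1], the
curve is LOESS-smoothed, and the cut is placed at the rightmost point
where the smoothed slope rises through 1.  Enhancers above the cut are
super-enhancers — the classic "hockey stick" geometry.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np

from .stats import loess_fit
from .types import EnhancerRegion

__all__ = ["SECurve", "SECallResult", "build_rank_curve", "find_inflection",
           "call_superenhancers"]


@dataclass
class SECurve:
    """Ranked, scaled and smoothed enhancer size curve."""

    values: np.ndarray          # metric values, ascending
    order: np.ndarray           # permutation mapping input index -> rank
    x: np.ndarray               # rank / (n-1), in [0, 1]
    y: np.ndarray               # (value - min) / (max - min)
    metric: str = "length"
    degenerate: bool = False
    smoothed: np.ndarray | None = None
    slope: np.ndarray | None = None
    inflection_x: float | None = None
    cutoff: float = np.inf

    @property
    def n(self) -> int:
        return self.values.size

    def unscale(self, y_scaled: float) -> float:
        vmin, vmax = self.values[0], self.values[-1]
        return float(vmin + y_scaled * (vmax - vmin))


@dataclass
class SECallResult:
    sample_id: str | None
    superenhancers: list[EnhancerRegion]
    typical: list[EnhancerRegion]
    cutoff: float
    metric: str
    curve: SECurve = field(repr=False, default=None)

    @property
    def n_se(self) -> int:
        return len(self.superenhancers)


def _metric_values(enhancers: Sequence[EnhancerRegion], metric: str) -> np.ndarray:
    if metric == "length":
        return np.array([e.length for e in enhancers], dtype=float)
    if metric == "signal":
        return np.array([e.total_rpm for e in enhancers], dtype=float)
    raise ValueError(f"unknown metric {metric!r}; expected 'length' or 'signal'")


def build_rank_curve(
    enhancers: Sequence[EnhancerRegion], metric: str = "length"
) -> SECurve:
    """Sort the metric ascending and min-max scale both axes to [0, 1]."""
    vals = _metric_values(enhancers, metric)
    n = vals.size
    if n < 10:
        raise ValueError(f"need >= 10 enhancers to build a rank curve, got {n}")
    order = np.argsort(vals, kind="stable")
    values = vals[order]
    x = np.arange(n, dtype=float) / (n - 1)
    vmin, vmax = values[0], values[-1]
    if vmax == vmin:
        return SECurve(values, order, x, np.zeros(n), metric, degenerate=True)
    y = (values - vmin) / (vmax - vmin)
    return SECurve(values, order, x, y, metric)


def find_inflection(curve: SECurve, span: float = 0.25) -> tuple[float | None, float]:
    """Locate the slope-1 inflection on the smoothed scaled curve.

    The slope is the central finite difference of the LOESS-smoothed scaled
    curve; the cut sits at the rightmost upward crossing through 1
    (slope <= 1 just before, > 1 at the crossing, with a 1e-8 guard so a
    perfectly linear curve never crosses by float noise).  The cutoff is
    the smoothed curve value at the crossing mapped back to metric units —
    the tangent-line rule of hockey-stick ranking.  If the slope never
    exceeds 1 there is no inflection and the cutoff is +inf (zero SEs).
    """
    if curve.degenerate:
        curve.cutoff = np.inf
        return None, np.inf
    sm = loess_fit(curve.x, curve.y, span=span)
    slope = np.gradient(sm, curve.x)
    curve.smoothed, curve.slope = sm, slope
    eps = 1e-8
    crossing = None
    for i in range(1, curve.n):
        if slope[i - 1] <= 1.0 + eps < slope[i]:
            crossing = i
    if crossing is None:
        curve.inflection_x, curve.cutoff = None, np.inf
        return None, np.inf
    x_star = float(curve.x[crossing])
    cutoff = curve.unscale(float(sm[crossing]))
    curve.inflection_x, curve.cutoff = x_star, cutoff
    return x_star, cutoff


def call_superenhancers(
    enhancers: Sequence[EnhancerRegion],
    metric: str = "length",
    span: float = 0.25,
    sample_id: str | None = None,
) -> SECallResult:
    """Split enhancers into SEs (metric > cutoff) and typical enhancers."""
    curve = build_rank_curve(enhancers, metric)
    _, cutoff = find_inflection(curve, span=span)
    vals = _metric_values(enhancers, metric)
    se = [e for e, v in zip(enhancers, vals) if v > cutoff]
    typ = [e for e, v in zip(enhancers, vals) if v <= cutoff]
    if sample_id is None and enhancers:
        sample_id = enhancers[0].interval.sample_id
    return SECallResult(sample_id, se, typ, cutoff, metric, curve)
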