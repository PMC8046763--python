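"""Statistical primitives: hypergeometric tails, BH correction, rank tests,
and tricube-weighted local linear (LOESS) smoothing.

Two-sided p-values are formed by doubling the smaller tail and capping at 1.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats as sps

__all__ = [
    "hypergeom_upper_tail",
    "benjamini_hochberg",
    "two_group_rank_test",
    "loess_fit",
]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` successes observed among ``n`` draws, from a universe of ``N``
    items of which ``K`` are successes.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require K, n <= N; got K={K}, n={n}, N={N}")
    if k < 0 or k > min(K, n):
        raise ValueError(f"impossible configuration: k={k} > min(K={K}, n={n})")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); exact in scipy for these sizes
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values, input order preserved.

    NaN entries are ignored for the correction and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def two_group_rank_test(x, y, mode: str = "rank_sum") -> float:
    """Two-sided nonparametric comparison of two groups of values.

    ``rank_sum`` (default) is the unpaired Wilcoxon/Mann-Whitney test:
    exact permutation distribution when the combined size is <= 25 with no
    ties, normal approximation with tie and continuity corrections
    otherwise.  ``signed_rank`` is the paired Wilcoxon test and requires
    equal group sizes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one value")

    if mode == "rank_sum":
        combined = np.concatenate([x, y])
        if np.ptp(combined) == 0:
            return 1.0  # all values identical: no evidence either way
        has_ties = len(np.unique(combined)) < combined.size
        if combined.size <= 25 and not has_ties:
            method = "exact"
        else:
            method = "asymptotic"
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=True
        )
        return float(min(res.pvalue, 1.0))

    if mode == "signed_rank":
        if x.size != y.size:
            raise ValueError(
                "signed_rank requires paired groups of equal size; "
                "use mode='rank_sum' for unpaired groups"
            )
        d = x - y
        if np.all(d == 0):
            return 1.0
        n_nonzero = int(np.count_nonzero(d))
        absd = np.abs(d[d != 0])
        has_ties = len(np.unique(absd)) < absd.size
        method = "exact" if (n_nonzero <= 25 and not has_ties) else "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sps.wilcoxon(
                x, y, alternative="two-sided", zero_method="wilcox", method=method
            )
        return float(min(res.pvalue, 1.0))

    raise ValueError(f"unknown mode {mode!r}; expected 'rank_sum' or 'signed_rank'")


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess_fit(x, y, span: float = 0.25) -> np.ndarray:
    """LOESS: tricube-weighted local *linear* fit, evaluated at each x.

    One pass, no robustness iterations.  At each abscissa the
    ``ceil(span * n)`` nearest neighbours define the local window; weights
    are tricube in distance scaled by the window radius.  Deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"need >= 10 points to smooth, got {n}")
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    if np.any(np.diff(x) < 0):
        raise ValueError("x must be sorted ascending")

    k = max(2, int(math.ceil(span * n)))
    k = min(k, n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = _tricube(d[idx] / dmax)
        if w.sum() <= 0:
            w = np.ones_like(w)
        xi, yi = x[idx], y[idx]
        xbar = np.average(xi, weights=w)
        ybar = np.average(yi, weights=w)
        sxx = np.sum(w * (xi - xbar) ** 2)
        if sxx <= 0:
            out[i] = ybar
            continue
        slope = np.sum(w * (xi - xbar) * (yi - ybar)) / sxx
        out[i] = ybar + slope * (x[i] - xbar)
    return out
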