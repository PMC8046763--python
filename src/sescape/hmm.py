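"""Two-state hidden Markov model on binarized chromatin signal.

The enhancer-calling front-end: per-bin presence/absence calls are
segmented into background vs enriched runs with a Bernoulli-emission HMM
fitted by Baum-Welch and decoded with Viterbi.  State 1 is canonically the
*enriched* state (higher probability of emitting a 1).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["HMMParams", "fit_two_state_hmm", "viterbi_path"]


@dataclass
class HMMParams:
    """Fitted two-state Bernoulli HMM.

    ``transition[i, j]`` is P(state j at t+1 | state i at t); ``emission[s]``
    is P(bin = 1 | state s).  State 0 = background, state 1 = enriched.
    """

    transition: np.ndarray
    emission: np.ndarray
    start: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        self.start = np.asarray(self.start, dtype=float)
        if self.transition.shape != (2, 2):
            raise ValueError("transition must be 2x2")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")


def _canonicalize(params: HMMParams) -> HMMParams:
    """Relabel states so that state 1 has the higher P(emit 1)."""
    if params.emission[1] >= params.emission[0]:
        return params
    perm = [1, 0]
    return HMMParams(
        transition=params.transition[np.ix_(perm, perm)],
        emission=params.emission[perm],
        start=params.start[perm],
        loglik_trace=params.loglik_trace,
        converged=params.converged,
    )


def _emission_matrix(bits: np.ndarray, emission: np.ndarray) -> np.ndarray:
    # b[t, s] = P(x_t | state s)
    b = np.empty((bits.size, 2))
    b[:, 0] = np.where(bits == 1, emission[0], 1.0 - emission[0])
    b[:, 1] = np.where(bits == 1, emission[1], 1.0 - emission[1])
    return np.clip(b, 1e-300, None)


def _forward_backward(bits, start, trans, emission):
    n = bits.size
    b = _emission_matrix(bits, emission)
    alpha = np.empty((n, 2))
    c = np.empty(n)
    alpha[0] = start * b[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ trans) * b[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.empty((n, 2))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (trans @ (b[t + 1] * beta[t + 1])) / c[t + 1]
    loglik = float(np.log(c).sum())
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    # xi summed over t: expected transition counts
    xi_sum = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            xi_sum[i, j] = np.sum(
                alpha[:-1, i] * trans[i, j] * b[1:, j] * beta[1:, j] / c[1:]
            )
    return gamma, xi_sum, loglik


def fit_two_state_hmm(
    binary_bins,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> HMMParams:
    """Baum-Welch fit of the two-state Bernoulli HMM.

    Initial parameters are mildly jittered from a persistent-state prior so
    reruns with the same seed are identical.  Degenerate inputs (all zeros
    or all ones) return fixed trivial parameters with a warning.
    """
    bits = np.asarray(binary_bins, dtype=np.int8).ravel()
    if bits.size < 100:
        raise ValueError(f"need >= 100 bins to fit the HMM, got {bits.size}")
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("binary_bins must contain only 0/1")

    frac1 = float(bits.mean())
    if frac1 in (0.0, 1.0):
        warnings.warn(
            "degenerate binarized track (all %d); returning trivial parameters"
            % int(frac1)
        )
        p_enr = 0.99 if frac1 == 1.0 else 0.5
        params = HMMParams(
            transition=np.array([[0.99, 0.01], [0.01, 0.99]]),
            emission=np.array([0.01, p_enr]),
            start=np.array([1.0 - frac1, frac1]),
            converged=True,
        )
        return _canonicalize(params)

    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.02, 0.02, size=4)
    trans = np.array(
        [[0.95 + jitter[0], 0.05 - jitter[0]], [0.05 - jitter[1], 0.95 + jitter[1]]]
    )
    emission = np.clip(
        np.array([frac1 * 0.2 + jitter[2] * 0.1, 0.7 + jitter[3]]), 1e-4, 1 - 1e-4
    )
    start = np.array([0.9, 0.1])

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        gamma, xi_sum, loglik = _forward_backward(bits, start, trans, emission)
        if trace and loglik - trace[-1] < tol:
            trace.append(loglik)
            converged = True
            break
        trace.append(loglik)
        # M step
        start = gamma[0] / gamma[0].sum()
        trans = xi_sum / np.clip(xi_sum.sum(axis=1, keepdims=True), 1e-300, None)
        denom = gamma.sum(axis=0)
        emission = np.clip((gamma * bits[:, None]).sum(axis=0) / denom, 1e-6, 1 - 1e-6)

    params = HMMParams(
        transition=trans,
        emission=emission,
        start=start,
        loglik_trace=trace,
        converged=converged,
    )
    return _canonicalize(params)


def viterbi_path(binary_bins, params: HMMParams) -> np.ndarray:
    """Most probable state sequence (0 = background, 1 = enriched)."""
    bits = np.asarray(binary_bins, dtype=np.int8).ravel()
    n = bits.size
    if n == 0:
        return np.zeros(0, dtype=np.int8)
    logb = np.log(_emission_matrix(bits, params.emission))
    logt = np.log(np.clip(params.transition, 1e-300, None))
    logs = np.log(np.clip(params.start, 1e-300, None))
    delta = logs + logb[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        cand = delta[:, None] + logt  # cand[i, j]
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], [0, 1]] + logb[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path
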