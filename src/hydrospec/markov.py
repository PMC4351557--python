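"""Transition-probability estimation and the degree of non-Markovianity.

For an ensemble of two-state (+/-1) series, the two-time transition
probability P(i, t | j, s) is estimated as the fraction of ensemble members
in state i at frame t among those in state j at frame s = t - Delta.  A
Markov process satisfies the Chapman-Kolmogorov equation: the lag-Delta
transition probability equals the composition of the intermediate one-step
probabilities.  The degree of non-Markovianity quantifies the violation,

    G(Delta, T) = 1/(M^2 |T_D|) * sum_{t in T_D} sum_{i,j}
                  | P(i, t | j, t-Delta) - P_CK(i, t | j, t-Delta) |,

with M = 2 states, T_D the frames in [Delta, T) where the estimate is
defined, and P_CK the Chapman-Kolmogorov prediction composed from the
directly estimated (time-inhomogeneous) one-step probabilities.  G -> 0
with ensemble size for a genuinely Markov ensemble; residual G for a
12,800-member iid baseline sets the resolution floor of the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransitionEstimate",
    "NonMarkovianityResult",
    "estimate_transitions",
    "compose_chapman_kolmogorov",
    "degree_of_non_markovianity",
    "segment_ensemble",
]


@dataclass
class TransitionEstimate:
    """P(i, t | j, t - delta) over t in [delta, T).

    ``probs[t - delta, j, i]`` is the estimated probability of state i at
    frame t given state j at frame t - delta, with j, i indexed as
    0 -> state -1, 1 -> state +1.  Undefined entries (no member in state j
    at t - delta) are NaN.  ``counts[t - delta, j]`` is the number of
    members conditioning each row.
    """

    probs: np.ndarray
    counts: np.ndarray
    delta: int
    T: int
    n_ensemble: int


@dataclass
class NonMarkovianityResult:
    """G(Delta, T) per lag, with the maximum and its argmax."""

    lags: np.ndarray
    G_of_delta: np.ndarray
    T: int
    n_ensemble: int

    @property
    def G_max(self) -> float:
        return float(np.nanmax(self.G_of_delta))

    @property
    def argmax_lag(self) -> int:
        return int(self.lags[np.nanargmax(self.G_of_delta)])

    @property
    def G_mean(self) -> float:
        return float(np.nanmean(self.G_of_delta))


def _as_matrix(ensemble) -> np.ndarray:
    """Stack an ensemble (array or sequence of series) as (n, T) of 0/1."""
    if isinstance(ensemble, np.ndarray):
        mat = ensemble
    else:
        mat = np.stack(
            [np.asarray(getattr(s, "states", s)) for s in ensemble]
        )
    if mat.ndim != 2:
        raise ValueError("ensemble must be two-dimensional (members x frames)")
    if not np.all(np.abs(mat) == 1):
        raise ValueError("states must be +1/-1")
    return (mat == 1).astype(np.float64)


def segment_ensemble(ensemble, n_segments: int) -> np.ndarray:
    """Split each series into equal consecutive segments, pooled as members.

    128 series split into 100 segments each yield a 12,800-member ensemble,
    the bookkeeping used to estimate transition probabilities at every
    frame of the segment window.
    """
    if isinstance(ensemble, np.ndarray):
        mat = ensemble
    else:
        mat = np.stack([np.asarray(getattr(s, "states", s)) for s in ensemble])
    n, length = mat.shape
    seg_len = length // n_segments
    if seg_len < 1:
        raise ValueError("series shorter than the number of segments")
    return mat[:, : seg_len * n_segments].reshape(n * n_segments, seg_len)


def _pair_counts(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Joint counts of (state at s, state at t) for all frame pairs.

    ``S`` is the (n, T) 0/1 matrix.  Returns (n11, col1) where
    ``n11[s, t]`` counts members on at both s and t and ``col1[t]`` counts
    members on at t.  A single BLAS product covers all pairs.
    """
    n11 = S.T @ S
    col1 = S.sum(axis=0)
    return n11, col1


def estimate_transitions(ensemble, delta: int, T: int) -> TransitionEstimate:
    """Estimate P(i, t | j, t - delta) for every t in [delta, T)."""
    S = _as_matrix(ensemble)
    n, length = S.shape
    if length < T:
        raise ValueError(f"ensemble members shorter ({length}) than T ({T})")
    if not 1 <= delta < T:
        raise ValueError("delta must lie in [1, T)")
    S = S[:, :T]
    n11, col1 = _pair_counts(S)
    t = np.arange(delta, T)
    s = t - delta
    c11 = n11[s, t]
    c1_ = col1[s]
    c_1 = col1[t]
    probs = np.full((t.size, 2, 2), np.nan)
    counts = np.empty((t.size, 2))
    counts[:, 1] = c1_
    counts[:, 0] = n - c1_
    with np.errstate(invalid="ignore", divide="ignore"):
        p_1g1 = np.where(c1_ > 0, c11 / c1_, np.nan)
        p_1g0 = np.where(n - c1_ > 0, (c_1 - c11) / (n - c1_), np.nan)
    probs[:, 1, 1] = p_1g1
    probs[:, 1, 0] = 1.0 - p_1g1
    probs[:, 0, 1] = p_1g0
    probs[:, 0, 0] = 1.0 - p_1g0
    return TransitionEstimate(probs=probs, counts=counts, delta=delta, T=T, n_ensemble=n)


def compose_chapman_kolmogorov(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Compose one-step transition probabilities along the chain.

    ``a[t]`` = P(on at t+1 | on at t), ``b[t]`` = P(on at t+1 | off at t),
    for t = 0..T-2.  Returns (pck1, pck0) where ``pck1[s, t]`` is the
    composed probability of being on at frame t given on at frame s < t
    (and ``pck0`` conditions on off).  Entries with t <= s are NaN.

    For a homogeneous chain (constant a, b) the composition equals the
    analytic Delta-step matrix power.
    """
    T = a.size + 1
    pck1 = np.full((T, T), np.nan)
    pck0 = np.full((T, T), np.nan)
    prev1 = np.ones(T)  # running P(on at t | on at s) for each s
    prev0 = np.zeros(T)
    for t in range(1, T):
        s = np.arange(t)
        prev1[s] = b[t - 1] + (a[t - 1] - b[t - 1]) * prev1[s]
        prev0[s] = b[t - 1] + (a[t - 1] - b[t - 1]) * prev0[s]
        pck1[s, t] = prev1[s]
        pck0[s, t] = prev0[s]
    return pck1, pck0


def degree_of_non_markovianity(ensemble, T: int, lags=None) -> NonMarkovianityResult:
    """Mean absolute Chapman-Kolmogorov deviation per lag, over [1, T).

    Undefined conditional entries (zero-count conditions, or one-step
    probabilities unavailable along the composition path) are excluded from
    the average rather than imputed.
    """
    S = _as_matrix(ensemble)
    n, length = S.shape
    if length < T:
        raise ValueError(f"ensemble members shorter ({length}) than T ({T})")
    S = S[:, :T]
    n11, col1 = _pair_counts(S)
    with np.errstate(invalid="ignore", divide="ignore"):
        # empirical two-time conditionals for all (s, t): P(on at t | . at s)
        c1 = col1[:, None]
        p1g1 = np.where(c1 > 0, n11 / c1, np.nan)  # [s, t]
        p1g0 = np.where(n - c1 > 0, (col1[None, :] - n11) / (n - c1), np.nan)
        a = np.diagonal(p1g1, offset=1).copy()  # one-step, length T-1
        b = np.diagonal(p1g0, offset=1).copy()
    pck1, pck0 = compose_chapman_kolmogorov(a, b)
    # |P - P_CK| summed over i is twice the deviation of the "on" entry
    d1 = np.abs(p1g1 - pck1)  # conditioned on on at s
    d0 = np.abs(p1g0 - pck0)  # conditioned on off at s
    lags = np.arange(1, T) if lags is None else np.asarray(lags, dtype=int)
    G = np.full(lags.size, np.nan)
    for k, delta in enumerate(lags):
        s = np.arange(0, T - delta)
        dev1 = d1[s, s + delta]
        dev0 = d0[s, s + delta]
        dev = np.concatenate([dev1, dev0])
        defined_t = ~np.isnan(dev1) | ~np.isnan(dev0)
        n_t = int(np.count_nonzero(defined_t))
        if n_t == 0:
            continue
        # sum over i,j of |dP| = 2 * (|d1| + |d0|); prefactor 1/M^2 = 1/4
        G[k] = np.nansum(2.0 * dev) / (4.0 * n_t)
    return NonMarkovianityResult(lags=lags, G_of_delta=G, T=T, n_ensemble=n)
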