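"""Residence-time statistics: densities, MLE, surrogates, correlations.

The sojourn durations of the on/off process carry two signatures analysed
here: a heavy-tailed marginal (power law with exponential cutoff, fitted by
maximum likelihood) and long-range serial correlation (probed by shuffled
surrogates, conditional averages of the next duration given the previous
one, and spectra of the duration sequence itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .dichotomize import OFF, ON, ResidenceSequence
from .distributions import CutoffPowerLaw, upper_gamma
from .spectral import PowerSpectrum

__all__ = [
    "CutoffPowerLawFit",
    "ConditionalAverages",
    "logbinned_pdf",
    "fit_cutoff_powerlaw",
    "shuffle_residences",
    "conditional_average",
    "residence_sequence_psd",
]

_PAIR_KINDS = ("on->on", "off->off", "on->off", "off->on")


@dataclass
class CutoffPowerLawFit:
    """MLE of ``P(tau) = A tau^(-1-alpha) exp(-tau/tau_c)`` on [tau_min, inf)."""

    alpha: float
    tau_c: float
    A: float
    tau_min: float
    loglik: float
    n: int
    ci_alpha: tuple[float, float]
    ci_tau_c: tuple[float, float]

    def dist(self) -> CutoffPowerLaw:
        return CutoffPowerLaw(self.alpha, self.tau_c, self.tau_min)


@dataclass
class ConditionalAverages:
    """Blocked conditional means of the next duration given the previous.

    Pairs (tau_i, tau_{i+1}) are sorted by ascending previous duration and
    grouped into consecutive blocks of ``block_size`` pairs; per block the
    mean previous duration (bin center) and mean next duration are
    reported.  A flat profile indicates independent sojourns.
    """

    pair_kind: str
    block_size: int
    bin_centers: np.ndarray
    cond_means: np.ndarray
    block_counts: np.ndarray
    n_pairs: int
    short_input: bool = False


def logbinned_pdf(
    durations, bins_per_decade: int = 8, tau_min: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram density estimate on logarithmically spaced bins.

    Returns (bin centers, density); density = count / (n * bin width), so
    the estimate integrates to one over the occupied range.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("no durations to bin")
    lo = tau_min if tau_min is not None else d.min()
    hi = d.max()
    if lo <= 0:
        raise ValueError("durations must be positive")
    if lo == hi:  # degenerate sample: a single bin holding all mass
        width = lo * (10 ** (1 / bins_per_decade) - 1)
        return np.array([lo]), np.array([1.0 / width])
    n_bins = max(int(np.ceil(np.log10(hi / lo) * bins_per_decade)), 1)
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    edges[-1] *= 1 + 1e-12
    counts, _ = np.histogram(d, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    occupied = counts > 0
    density = counts[occupied] / (d.size * widths[occupied])
    return centers[occupied], density


_BIG = 1e300  # finite penalty keeps simplex arithmetic NaN-free


def _negloglik(theta: np.ndarray, logsum: float, xsum: float, n: int, tau_min: float) -> float:
    alpha, log_tau_c = theta
    if alpha <= 0 or log_tau_c > 700 or math.exp(log_tau_c) <= tau_min:
        return _BIG
    tau_c = math.exp(log_tau_c)
    g = upper_gamma(-alpha, tau_min / tau_c)
    if not np.isfinite(g) or g <= 0:
        return _BIG
    log_a = alpha * math.log(tau_c) - math.log(g)
    ll = n * log_a - (1 + alpha) * logsum - xsum / tau_c
    return -ll


def fit_cutoff_powerlaw(
    durations, tau_min: float = 1.0, ci: bool = True
) -> CutoffPowerLawFit:
    """Maximum-likelihood fit of the cutoff power law to sojourn durations.

    The normalization uses the upper incomplete gamma at negative shape,
    ``A**-1 = tau_c**(-alpha) Gamma(-alpha, tau_min/tau_c)``.  95%
    profile-likelihood intervals are reported for both parameters.  For
    samples whose likelihood keeps increasing with tau_c (no detectable
    cutoff) tau_c runs to the upper bound and the fit reduces to the pure
    Pareto MLE, alpha = n / sum(log(tau/tau_min)).
    """
    d = np.asarray(durations, dtype=float)
    if d.size < 100:
        raise ValueError("need at least 100 durations for a stable fit")
    if np.any(d < tau_min):
        raise ValueError("durations below tau_min")
    n = d.size
    logsum = float(np.sum(np.log(d)))
    xsum = float(np.sum(d))
    hill = n / float(np.sum(np.log(d / tau_min))) if np.any(d > tau_min) else 1.0
    log_tc_hi = math.log(tau_min) + 27.0  # ~ tau_min * 5e11: pure-Pareto regime
    best = None
    for tc0 in (np.quantile(d, 0.98), 10 * np.mean(d), math.exp(log_tc_hi - 1)):
        res = optimize.minimize(
            _negloglik,
            x0=np.array([max(hill, 0.1), math.log(max(tc0, tau_min * 2))]),
            args=(logsum, xsum, n, tau_min),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= _BIG:
        raise RuntimeError(f"cutoff power-law MLE failed to converge: {best.message}")
    alpha_hat = float(best.x[0])
    tau_c_hat = float(math.exp(min(best.x[1], log_tc_hi)))
    loglik = -float(best.fun)
    g = upper_gamma(-alpha_hat, tau_min / tau_c_hat)
    A = math.exp(alpha_hat * math.log(tau_c_hat) - math.log(g))

    def profile(fix_alpha: float | None = None, fix_log_tc: float | None = None) -> float:
        if fix_alpha is not None:
            obj = lambda ltc: _negloglik(np.array([fix_alpha, ltc[0]]), logsum, xsum, n, tau_min)
            x0 = [math.log(tau_c_hat)]
        else:
            obj = lambda al: _negloglik(np.array([al[0], fix_log_tc]), logsum, xsum, n, tau_min)
            x0 = [alpha_hat]
        r = optimize.minimize(obj, x0=np.array(x0), method="Nelder-Mead", options={"xatol": 1e-6})
        return -float(r.fun)

    ci_alpha = (math.nan, math.nan)
    ci_tau_c = (math.nan, math.nan)
    if ci:
        drop = 1.920729  # chi2(1) 95% / 2

        def bound(param: str, direction: int) -> float:
            if param == "alpha":
                center, step = alpha_hat, 0.02 * alpha_hat + 1e-3
                f = lambda v: profile(fix_alpha=v) - (loglik - drop)
            else:
                center, step = math.log(tau_c_hat), 0.05
                f = lambda v: profile(fix_log_tc=v) - (loglik - drop)
            lo, hi = center, center + direction * step
            for _ in range(60):
                if f(hi) < 0:
                    break
                lo, hi = hi, hi + direction * step * 2
                step *= 1.5
            else:
                return math.inf * direction
            a, b = sorted((lo, hi))
            try:
                return optimize.brentq(f, a, b, xtol=1e-5)
            except ValueError:
                return math.nan
        ci_alpha = (bound("alpha", -1), bound("alpha", +1))
        lo_t, hi_t = bound("tau_c", -1), bound("tau_c", +1)
        ci_tau_c = (
            math.exp(lo_t) if np.isfinite(lo_t) else lo_t,
            math.exp(hi_t) if np.isfinite(hi_t) else hi_t,
        )
    return CutoffPowerLawFit(
        alpha=alpha_hat,
        tau_c=tau_c_hat,
        A=A,
        tau_min=tau_min,
        loglik=loglik,
        n=n,
        ci_alpha=ci_alpha,
        ci_tau_c=ci_tau_c,
    )


def fit_cutoff_powerlaw_discrete(
    durations, dt: float = 1.0, kmin: int = 2, ci: bool = True
) -> CutoffPowerLawFit:
    """MLE for frame-quantized durations via the discrete likelihood.

    Run-length extraction yields integer frame counts k = ceil(tau/dt); for
    heavy-tailed sojourns most runs span only a few frames, where evaluating
    the continuous density at the quantized values biases alpha severely.
    This variant maximizes the exact cell probabilities

        P(k) = [G(k-1) - G(k)] / G(kmin - 1),   G(t) = Gamma(-alpha, t dt/tau_c),

    conditioned on k >= kmin (kmin = 2 by default: one-frame runs are pure
    quantization).  The lower support bound cancels from the likelihood.
    Returned tau_c and intervals are in ps; A normalizes the continuous
    density on [dt, inf).
    """
    k = np.round(np.asarray(durations, dtype=float) / dt).astype(np.int64)
    k = k[k >= kmin]
    if k.size < 100:
        raise ValueError("need at least 100 durations of >= kmin frames")
    vals, counts = np.unique(k, return_counts=True)
    grid = np.union1d(vals - 1, vals).astype(float)

    def negloglik(theta: np.ndarray) -> float:
        alpha, log_tau_c = theta
        if alpha <= 0 or alpha > 6 or log_tau_c > 27:
            return _BIG
        tau_c = math.exp(log_tau_c)
        g = upper_gamma(-alpha, grid * dt / tau_c)
        g = np.asarray(g)
        if not np.all(np.isfinite(g)):
            return _BIG
        lookup = dict(zip(grid, g))
        cell = np.array([lookup[v - 1] - lookup[v] for v in vals.astype(float)])
        norm = lookup[float(kmin - 1)]
        if norm <= 0 or np.any(cell <= 0):
            return _BIG
        return -float(np.sum(counts * np.log(cell)) - k.size * math.log(norm))

    best = None
    for x0 in ([1.0, math.log(100 * dt)], [1.5, math.log(1000 * dt)]):
        res = optimize.minimize(
            negloglik, x0=np.array(x0), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best.fun >= _BIG:
        raise RuntimeError("discrete cutoff power-law MLE failed to converge")
    alpha_hat = float(best.x[0])
    tau_c_hat = float(math.exp(best.x[1])) * dt
    loglik = -float(best.fun)
    g0 = upper_gamma(-alpha_hat, dt / tau_c_hat)
    A = math.exp(alpha_hat * math.log(tau_c_hat) - math.log(g0))

    ci_alpha = (math.nan, math.nan)
    ci_tau_c = (math.nan, math.nan)
    if ci:
        drop = 1.920729

        def profile_alpha(a: float) -> float:
            r = optimize.minimize(
                lambda v: negloglik(np.array([a, v[0]])),
                x0=np.array([math.log(tau_c_hat / dt)]),
                method="Nelder-Mead",
                options={"xatol": 1e-5},
            )
            return -float(r.fun)

        def profile_ltc(v: float) -> float:
            r = optimize.minimize(
                lambda a: negloglik(np.array([a[0], v])),
                x0=np.array([alpha_hat]),
                method="Nelder-Mead",
                options={"xatol": 1e-5},
            )
            return -float(r.fun)

        def bound(f, center, step, direction):
            lo, hi = center, center + direction * step
            for _ in range(60):
                if f(hi) < loglik - drop:
                    break
                lo, hi = hi, hi + direction * step * 2
                step *= 1.5
            else:
                return math.inf * direction
            a, b = sorted((lo, hi))
            try:
                return optimize.brentq(lambda v: f(v) - (loglik - drop), a, b, xtol=1e-5)
            except ValueError:
                return math.nan

        ci_alpha = (
            bound(profile_alpha, alpha_hat, 0.02 * alpha_hat + 1e-3, -1),
            bound(profile_alpha, alpha_hat, 0.02 * alpha_hat + 1e-3, +1),
        )
        lo_t = bound(profile_ltc, math.log(tau_c_hat / dt), 0.05, -1)
        hi_t = bound(profile_ltc, math.log(tau_c_hat / dt), 0.05, +1)
        ci_tau_c = (
            math.exp(lo_t) * dt if np.isfinite(lo_t) else lo_t,
            math.exp(hi_t) * dt if np.isfinite(hi_t) else hi_t,
        )
    return CutoffPowerLawFit(
        alpha=alpha_hat,
        tau_c=tau_c_hat,
        A=A,
        tau_min=dt,
        loglik=loglik,
        n=int(k.size),
        ci_alpha=ci_alpha,
        ci_tau_c=ci_tau_c,
    )


def shuffle_residences(
    r: ResidenceSequence, seed: int | np.random.Generator | None = None
) -> ResidenceSequence:
    """Permute on-durations among on slots and off-durations among off slots.

    The state alternation and both duration multisets are preserved exactly;
    only the serial ordering — hence any long-term correlation — is
    destroyed.  This is the surrogate whose rasterized spectrum reverts to
    the independent-renewal exponent.
    """
    if len(r) == 0:
        raise ValueError("empty residence sequence")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    durations = r.durations.copy()
    for state in (ON, OFF):
        idx = np.flatnonzero(r.states == state)
        durations[idx] = durations[rng.permutation(idx)]
    return ResidenceSequence(
        durations,
        r.states.copy(),
        dt=r.dt,
        censored_first=r.censored_first,
        censored_last=r.censored_last,
    )


def _extract_pairs(residences, pair_kind: str) -> tuple[np.ndarray, np.ndarray]:
    if pair_kind not in _PAIR_KINDS:
        raise ValueError(f"pair_kind must be one of {_PAIR_KINDS}")
    first_state = ON if pair_kind.startswith("on") else OFF
    same = pair_kind in ("on->on", "off->off")
    seqs = [residences] if isinstance(residences, ResidenceSequence) else list(residences)
    prev_all, next_all = [], []
    for r in seqs:
        r = r.interior() if (r.censored_first or r.censored_last) else r
        d, s = r.durations, r.states
        if same:
            idx = np.flatnonzero(s == first_state)
            if idx.size >= 2:
                prev_all.append(d[idx[:-1]])
                next_all.append(d[idx[1:]])
        else:
            idx = np.flatnonzero(s[:-1] == first_state)
            if idx.size:
                prev_all.append(d[idx])
                next_all.append(d[idx + 1])
    if not prev_all:
        return np.empty(0), np.empty(0)
    return np.concatenate(prev_all), np.concatenate(next_all)


def conditional_average(
    residences, pair_kind: str, l: int = 1000
) -> ConditionalAverages:
    """Blocked conditional mean of the next duration given the previous.

    ``residences`` may be a single ResidenceSequence, an iterable of them
    (pairs pooled across sites), or a tuple ``(prev, next)`` of duration
    arrays.  Pairs are sorted ascending by previous duration and grouped in
    blocks of l; the final partial block is reported with its actual count.
    """
    if l < 1:
        raise ValueError("block size l must be >= 1")
    if isinstance(residences, tuple) and len(residences) == 2:
        prev, nxt = (np.asarray(a, dtype=float) for a in residences)
    else:
        prev, nxt = _extract_pairs(residences, pair_kind)
    if prev.size == 0:
        raise ValueError("no pairs available for the requested kind")
    order = np.argsort(prev, kind="stable")
    prev, nxt = prev[order], nxt[order]
    n_pairs = prev.size
    short = n_pairs < l
    edges = list(range(0, n_pairs, l)) + [n_pairs]
    centers, means, counts = [], [], []
    for a, b in zip(edges[:-1], edges[1:]):
        centers.append(prev[a:b].mean())
        means.append(nxt[a:b].mean())
        counts.append(b - a)
    return ConditionalAverages(
        pair_kind=pair_kind,
        block_size=l,
        bin_centers=np.asarray(centers),
        cond_means=np.asarray(means),
        block_counts=np.asarray(counts),
        n_pairs=n_pairs,
        short_input=short,
    )


def residence_sequence_psd(residences, which: str = "interleaved") -> PowerSpectrum:
    """Ensemble PSD of duration sequences indexed by occurrence number.

    ``which`` selects the on-only, off-only, or interleaved duration
    sequence per site.  Sequences are mean-subtracted and transformed with
    unit sampling interval in index space; sites are truncated to the
    shortest sequence so the ensemble can be averaged pointwise.
    """
    if which not in ("on-only", "off-only", "interleaved"):
        raise ValueError("which must be 'on-only', 'off-only' or 'interleaved'")
    seqs = [residences] if isinstance(residences, ResidenceSequence) else list(residences)
    arrays = []
    for r in seqs:
        r = r.interior() if (r.censored_first or r.censored_last) else r
        if which == "on-only":
            arrays.append(r.by_state(ON))
        elif which == "off-only":
            arrays.append(r.by_state(OFF))
        else:
            arrays.append(r.durations)
    n_min = min(a.size for a in arrays)
    if n_min < 16:
        raise ValueError("need at least 16 durations per site")
    from .spectral import ensemble_psd

    return ensemble_psd([a[:n_min] for a in arrays], dt=1.0)
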