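"""Power law with exponential cutoff: the residence-time distribution.

The density on ``[tau_min, inf)`` is

    P(tau) = A * tau**(-1 - alpha) * exp(-tau / tau_c),

with normalization ``A**-1 = tau_c**(-alpha) * Gamma(-alpha, tau_min/tau_c)``,
where ``Gamma(s, x)`` is the (non-regularized) upper incomplete gamma
function, here needed at *negative* shape ``s = -alpha``.  ``alpha`` sets the
power-law tail, ``tau_c`` truncates it so that all moments are finite; for
``tau_c -> inf`` the distribution degenerates to the Pareto law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special


def upper_gamma(s: float, x) -> np.ndarray | float:
    """Non-regularized upper incomplete gamma ``Gamma(s, x)`` for real s.

    scipy's ``gammaincc`` only accepts positive shape parameters; negative
    (and zero) shapes are reached through the downward recurrence

        Gamma(s, x) = (Gamma(s + 1, x) - x**s * exp(-x)) / s.

    ``x`` may be an array; ``x > 0`` is required when ``s <= 0``.
    """
    x = np.asarray(x, dtype=float)
    if s > 0:
        out = special.gammaincc(s, x) * special.gamma(s)
        return float(out) if out.ndim == 0 else out
    if np.any(x <= 0):
        raise ValueError("upper_gamma requires x > 0 when s <= 0")
    # climb to a strictly positive (or zero) shape, then recurse back down
    m = int(math.floor(-s)) + 1  # number of recurrence steps; s + m in (0, 1]
    s_top = s + m
    if s_top == 0.0:  # alpha integer: Gamma(0, x) = E1(x)
        g = special.exp1(x)
        start = 0.0
    else:
        g = special.gammaincc(s_top, x) * special.gamma(s_top)
        start = s_top
    sj = start
    for _ in range(m):
        sj -= 1.0
        if sj == 0.0:
            g = special.exp1(x)
            continue
        g = (g - x**sj * np.exp(-x)) / sj
    out = np.asarray(g, dtype=float).copy()
    # the recurrence can suffer cancellation for moderate-to-large x; repair
    # failed entries with the asymptotic series (large x) or with
    # arbitrary-precision arithmetic (moderate x)
    bad = ~np.isfinite(out) | (out <= 0)
    if np.any(bad):
        xs = np.broadcast_to(x, out.shape)
        large = bad & (xs > 30.0)
        if np.any(large):
            xl = xs[large]
            # Gamma(s, x) ~ x^(s-1) e^-x [1 + (s-1)/x + (s-1)(s-2)/x^2 + ...]
            series = 1.0 + (s - 1) / xl + (s - 1) * (s - 2) / xl**2 + (s - 1) * (s - 2) * (s - 3) / xl**3
            out[large] = np.exp((s - 1) * np.log(xl) - xl) * series
        rest = bad & ~large
        if np.any(rest):
            import mpmath

            flat = out.reshape(-1)
            xf = xs.reshape(-1)
            for i in np.nonzero(rest.reshape(-1))[0]:
                flat[i] = float(mpmath.gammainc(s, a=float(xf[i]), b=mpmath.inf))
            out = flat.reshape(out.shape)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CutoffPowerLaw:
    """``P(tau) = A tau^(-1-alpha) exp(-tau/tau_c)`` on ``[tau_min, inf)``.

    Parameters
    ----------
    alpha : float
        Power-law exponent, > 0.
    tau_c : float
        Exponential cutoff (ps).  ``math.inf`` gives the pure Pareto law
        (only valid as a sampling/CDF object; the mean diverges for
        ``alpha <= 1``).
    tau_min : float
        Lower support bound (ps), default 1.
    """

    alpha: float
    tau_c: float
    tau_min: float = 1.0
    _lognorm: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.tau_min <= 0:
            raise ValueError(f"tau_min must be > 0, got {self.tau_min}")
        if not self.tau_c > self.tau_min:
            raise ValueError("tau_c must exceed tau_min")
        if math.isinf(self.tau_c):
            log_a = math.log(self.alpha) + self.alpha * math.log(self.tau_min)
        else:
            g = upper_gamma(-self.alpha, self.tau_min / self.tau_c)
            log_a = self.alpha * math.log(self.tau_c) - math.log(g)
        object.__setattr__(self, "_lognorm", log_a)

    @property
    def A(self) -> float:
        """Normalization constant of the density."""
        return math.exp(self._lognorm)

    def logpdf(self, tau) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        out = np.full(tau.shape, -np.inf)
        ok = tau >= self.tau_min
        rate = 0.0 if math.isinf(self.tau_c) else 1.0 / self.tau_c
        out[ok] = self._lognorm - (1 + self.alpha) * np.log(tau[ok]) - tau[ok] * rate
        return out

    def pdf(self, tau) -> np.ndarray:
        return np.exp(self.logpdf(tau))

    def sf(self, tau) -> np.ndarray:
        """Survival function P(T > tau)."""
        tau = np.asarray(tau, dtype=float)
        tau = np.maximum(tau, self.tau_min)
        if math.isinf(self.tau_c):
            return (tau / self.tau_min) ** (-self.alpha)
        num = upper_gamma(-self.alpha, tau / self.tau_c)
        den = upper_gamma(-self.alpha, self.tau_min / self.tau_c)
        return np.asarray(num / den)

    def cdf(self, tau) -> np.ndarray:
        return 1.0 - self.sf(tau)

    def mean(self) -> float:
        """First moment, finite whenever tau_c < inf or alpha > 1."""
        if math.isinf(self.tau_c):
            if self.alpha <= 1:
                return math.inf
            return self.alpha * self.tau_min / (self.alpha - 1)
        num = upper_gamma(1 - self.alpha, self.tau_min / self.tau_c)
        den = upper_gamma(-self.alpha, self.tau_min / self.tau_c)
        return self.tau_c * num / den

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n samples by rejection from a Pareto(alpha, tau_min) proposal.

        The proposal density is proportional to tau^(-1-alpha); accepting
        with probability exp(-tau/tau_c) yields the exact target marginal.
        Efficient because tau_min << tau_c, so most proposals are accepted.
        """
        if n < 0:
            raise ValueError("n must be >= 0")
        if n == 0:
            return np.empty(0)
        rate = 0.0 if math.isinf(self.tau_c) else 1.0 / self.tau_c
        out = np.empty(n)
        filled = 0
        while filled < n:
            m = max(n - filled, 1024)
            u = rng.random(m)
            prop = self.tau_min * u ** (-1.0 / self.alpha)
            if rate == 0.0:
                acc = prop
            else:
                acc = prop[rng.random(m) < np.exp(-prop * rate)]
            take = min(acc.size, n - filled)
            out[filled : filled + take] = acc[:take]
            filled += take
        return out

    def ppf(self, q) -> np.ndarray:
        """Quantile function, by monotone interpolation of log-survival.

        Accurate to ~1e-10 relative on the grid range; used by the copula
        generator, where only the rank structure matters.
        """
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q >= 1)):
            raise ValueError("quantiles must lie in [0, 1)")
        hi = self.tau_min * 1e9 if math.isinf(self.tau_c) else self.tau_c * 60.0
        grid = np.logspace(np.log10(self.tau_min), np.log10(hi), 4096)
        log_sf = np.log(np.maximum(self.sf(grid), 1e-300))
        # sf is decreasing in tau; interpolate log tau against log sf
        target = np.log(np.maximum(1.0 - q, 1e-300))
        log_tau = np.interp(-target, -log_sf, np.log(grid))
        return np.exp(log_tau)
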