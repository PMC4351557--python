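"""Fractional Gaussian noise by circulant embedding (Davies–Harte).

fGn is the stationary increment process of fractional Brownian motion with
Hurst index H; its autocovariance at lag k is

    gamma(k) = 0.5 * (|k+1|^2H - 2|k|^2H + |k-1|^2H).

For 0.5 < H < 1 the lag-1 autocorrelation is 2^(2H-1) - 1 > 0 and the
autocorrelation decays as k^(2H-2) (long memory).  Circulant embedding is
exact: the 2n-point circulant extension of the covariance has nonnegative
eigenvalues for fGn, so the synthesized series has exactly the target
covariance.
"""

from __future__ import annotations

import numpy as np


def fgn_autocovariance(n: int, hurst: float) -> np.ndarray:
    k = np.arange(n, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


def fractional_gaussian_noise(
    n: int, hurst: float, rng: np.random.Generator, n_series: int = 1
) -> np.ndarray:
    """Sample ``n_series`` independent unit-variance fGn paths of length n.

    Returns an array of shape ``(n_series, n)`` (squeezed to ``(n,)`` when
    ``n_series == 1``).  Requires ``0.5 <= hurst < 1``; H = 0.5 reduces to
    white noise.
    """
    if not (0.5 <= hurst < 1.0):
        raise ValueError(f"hurst must lie in [0.5, 1), got {hurst}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if hurst == 0.5:
        out = rng.standard_normal((n_series, n))
        return out[0] if n_series == 1 else out

    gamma = fgn_autocovariance(n + 1, hurst)
    # first row of the 2n-circulant: gamma(0..n) then gamma(n-1..1) mirrored
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    m = row.size  # == 2n
    lam = np.fft.fft(row).real
    lam = np.maximum(lam, 0.0)  # clip tiny negative round-off

    out = np.empty((n_series, n))
    scale = np.sqrt(lam / m)
    for s in range(n_series):
        # z_k iid complex normal with E|z|^2 = 2, E z^2 = 0; the real part of
        # FFT(sqrt(lam/m) z) is then Gaussian with exactly the circulant
        # covariance, whose leading n x n block is the fGn covariance.
        z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        out[s] = np.fft.fft(scale * z).real[:n]
    return out[0] if n_series == 1 else out
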