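"""Shuffled-surrogate test for long-term memory in residence times.

Simulates a correlated renewal process (latent fGn copula, H = 0.85, with
negative cross-state coupling), then destroys the serial ordering by
permuting on-durations among on slots and off-durations among off slots.
The marginals are untouched, so any spectral change is attributable to the
inter-sojourn memory.
"""

import numpy as np

from hydrospec import (
    CorrelatedRenewalParams,
    RenewalParams,
    build_correlated_renewal,
    detect_transition,
    ensemble_psd,
    extract_residences,
    fit_loglog_slope,
    high_frequency_band,
    rasterize,
    shuffle_residences,
)

rng = np.random.default_rng(3)
params = CorrelatedRenewalParams(
    base=RenewalParams(alpha=1.2, tau_c_on=60.0, tau_c_off=1000.0, n_steps=2**17),
    hurst=0.85,
    cross_rho=-0.5,
)
series = [build_correlated_renewal(params, rng=rng) for _ in range(32)]
shuffled = [rasterize(shuffle_residences(extract_residences(s), rng)) for s in series]


def beta(ens):
    psd = ensemble_psd(ens, 1.0)
    try:
        f_t = detect_transition(psd)
    except ValueError:
        f_t = None
    return fit_loglog_slope(psd, *high_frequency_band(psd, f_t)).beta


b_u, b_s = beta(series), beta(shuffled)
print(f"beta (correlated process)  = {b_u:.3f}")
print(f"beta (shuffled surrogate)  = {b_s:.3f}   (2 - alpha = {2 - params.base.alpha:.1f})")
print()
print("The correlated process is steeper than the independent-renewal value")
print("2 - alpha; shuffling removes the memory and the exponent falls back")
print("toward it — the long-term correlation between sojourns, not the")
print("marginal alone, sets the high-frequency 1/f exponent.")
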