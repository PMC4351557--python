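"""Residence-time density estimation, MLE, surrogates and correlations."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from hydrospec import (
    CorrelatedRenewalParams,
    CutoffPowerLaw,
    RenewalParams,
    ResidenceSequence,
    build_correlated_renewal,
    conditional_average,
    extract_residences,
    fit_cutoff_powerlaw,
    fractional_gaussian_noise,
    logbinned_pdf,
    residence_sequence_psd,
    shuffle_residences,
)
from hydrospec.spectral import fit_loglog_slope


# ------------------------------------------------------------------ pdf ----
def test_logbinned_pdf_matches_exponential_density(rng):
    rate = 0.2
    sample = rng.exponential(1 / rate, size=50_000) + 1.0
    centers, density = logbinned_pdf(sample, bins_per_decade=6, tau_min=1.0)
    for c, d in zip(centers, density):
        true = rate * np.exp(-rate * (c - 1.0))
        # Poisson error of the bin count propagated to the density
        se = np.sqrt(max(true, d) / (50_000 * c * 0.3))
        assert abs(d - true) < 4 * se + 0.1 * true


def test_logbinned_pdf_degenerate_sample():
    centers, density = logbinned_pdf(np.full(10, 7.0))
    assert centers.size == 1
    width = 7.0 * (10 ** (1 / 8) - 1)
    assert density[0] * width == pytest.approx(1.0)


def test_logbinned_pdf_integrates_to_one(rng):
    sample = CutoffPowerLaw(1.2, 1074.0).rvs(40_000, rng)
    centers, density = logbinned_pdf(sample, bins_per_decade=8, tau_min=1.0)
    edges_width = np.diff(np.logspace(0, np.log10(sample.max()), 1))  # unused helper
    # integrate with the trapezoid on the log grid underestimates; use the
    # bin-width weighted sum reconstructed from consecutive centers
    ratio = centers[1] / centers[0]
    widths = centers * (np.sqrt(ratio) - 1 / np.sqrt(ratio))
    assert np.sum(density * widths) == pytest.approx(1.0, abs=0.05)


def test_logbinned_pdf_midrange_slope_matches_tail_exponent(rng):
    """alpha=1.2, tau_c=1074 ps: log-log density slope ~ -2.2 mid-range."""
    sample = CutoffPowerLaw(1.2, 1074.0).rvs(200_000, rng)
    centers, density = logbinned_pdf(sample, bins_per_decade=6, tau_min=1.0)
    sel = (centers > 2) & (centers < 100)
    slope = stats.linregress(np.log10(centers[sel]), np.log10(density[sel])).slope
    assert slope == pytest.approx(-2.2, abs=0.25)


def test_logbinned_pdf_empty_raises():
    with pytest.raises(ValueError):
        logbinned_pdf(np.empty(0))


# ------------------------------------------------------------------ MLE ----
def test_mle_recovers_generator_parameters(rng):
    d = CutoffPowerLaw(1.2, 1000.0)
    fit = fit_cutoff_powerlaw(d.rvs(100_000, rng), 1.0, ci=False)
    assert fit.alpha == pytest.approx(1.2, abs=0.05)
    assert fit.tau_c == pytest.approx(1000.0, rel=0.5)  # single-fit spread; see CI test
    norm, _ = quad(lambda t: float(fit.dist().pdf(t)), 1.0, np.inf, limit=300)
    assert norm == pytest.approx(1.0, abs=1e-6)


def test_mle_profile_intervals_cover_truth(rng):
    d = CutoffPowerLaw(1.2, 1000.0)
    fit = fit_cutoff_powerlaw(d.rvs(50_000, rng), 1.0)
    assert fit.ci_alpha[0] < 1.2 < fit.ci_alpha[1]
    assert fit.ci_tau_c[0] < 1000.0 < fit.ci_tau_c[1]


def test_mle_error_shrinks_with_sample_size():
    """Consistency: replicate-averaged error decreases from n=1e4 to 1e5."""
    errs = {}
    for n in (10_000, 100_000):
        e = []
        for seed in range(6):
            rng = np.random.default_rng(1000 + seed)
            fit = fit_cutoff_powerlaw(CutoffPowerLaw(1.2, 1000.0).rvs(n, rng), 1.0, ci=False)
            e.append(abs(fit.alpha - 1.2))
        errs[n] = np.mean(e)
    assert errs[100_000] < errs[10_000]


def test_mle_pure_pareto_limit_matches_hill(rng):
    sample = CutoffPowerLaw(1.3, 1e8).rvs(30_000, rng)
    fit = fit_cutoff_powerlaw(sample, 1.0, ci=False)
    hill = sample.size / np.sum(np.log(sample))
    assert fit.alpha == pytest.approx(hill, rel=0.01)


def test_discrete_mle_recovers_rasterized_parameters(rng):
    """Frame-quantized runs: the cell-probability MLE recovers (alpha, tau_c)
    where the continuous likelihood collapses (most runs span 2-3 frames)."""
    from hydrospec import RenewalParams, build_alternating_renewal, extract_residences
    from hydrospec.residence import fit_cutoff_powerlaw_discrete

    tel = build_alternating_renewal(
        RenewalParams(alpha=1.2, tau_c_on=59.0, tau_c_off=1074.0, n_steps=2**18), rng=rng
    )
    res = extract_residences(tel).interior()
    fit_on = fit_cutoff_powerlaw_discrete(res.by_state(1), dt=1.0)
    assert fit_on.alpha == pytest.approx(1.2, abs=0.1)
    assert fit_on.ci_tau_c[0] < 59.0 < fit_on.ci_tau_c[1]
    fit_off = fit_cutoff_powerlaw_discrete(res.by_state(-1), dt=1.0, ci=False)
    assert fit_off.alpha == pytest.approx(1.2, abs=0.1)
    assert fit_off.tau_c == pytest.approx(1074.0, rel=0.6)


def test_mle_input_validation(rng):
    with pytest.raises(ValueError):
        fit_cutoff_powerlaw(np.ones(50), 1.0)  # too few
    with pytest.raises(ValueError):
        fit_cutoff_powerlaw(np.full(200, 0.5), 1.0)  # below tau_min


# -------------------------------------------------------------- shuffle ----
def test_shuffle_preserves_multisets_and_states(rng):
    r = ResidenceSequence(
        np.array([3.0, 1.0, 5.0, 2.0, 4.0, 7.0, 1.0]),
        np.array([1, -1, 1, -1, 1, -1, 1]),
    )
    s = shuffle_residences(r, rng)
    np.testing.assert_array_equal(s.states, r.states)
    assert sorted(s.by_state(1)) == sorted(r.by_state(1))
    assert sorted(s.by_state(-1)) == sorted(r.by_state(-1))
    assert s.durations.sum() == r.durations.sum()


def test_shuffle_twice_same_law_as_once(rng):
    """Involution in distribution: rank correlation with the original is
    equally absent after one or two shuffles."""
    n = 4000
    durs = np.empty(2 * n)
    durs[0::2] = np.sort(CutoffPowerLaw(1.2, 60.0).rvs(n, rng))  # strongly ordered
    durs[1::2] = np.sort(CutoffPowerLaw(1.2, 1000.0).rvs(n, rng))
    states = np.tile([1, -1], n)
    r = ResidenceSequence(durs, states)
    once = shuffle_residences(r, rng)
    twice = shuffle_residences(once, rng)
    for s in (once, twice):
        rho = stats.spearmanr(r.by_state(1), s.by_state(1)).statistic
        assert abs(rho) < 4 / np.sqrt(n)


# -------------------------------------------------- conditional average ----
def test_conditional_average_identity_coupling():
    prev = np.linspace(1, 100, 5000)
    ca = conditional_average((prev, prev.copy()), "on->on", l=500)
    np.testing.assert_allclose(ca.cond_means, ca.bin_centers)
    assert np.all(np.diff(ca.bin_centers) > 0)


def test_conditional_average_independent_pairs_flat(rng):
    """Independent pairs: block profile flat within MC error of an oracle."""
    n = 30_000
    prev = CutoffPowerLaw(1.2, 60.0).rvs(n, rng)
    nxt = CutoffPowerLaw(1.2, 60.0).rvs(n, rng)
    ca = conditional_average((prev, nxt), "on->on", l=1000)
    res = stats.linregress(np.log10(ca.bin_centers), ca.cond_means)
    assert abs(res.slope) < 3 * res.stderr


def test_conditional_average_block_bookkeeping(rng):
    prev = rng.random(2500)
    ca = conditional_average((prev, rng.random(2500)), "off->off", l=1000)
    np.testing.assert_array_equal(ca.block_counts, [1000, 1000, 500])
    assert ca.n_pairs == 2500
    short = conditional_average((prev[:10], prev[:10]), "on->on", l=1000)
    assert short.short_input and short.bin_centers.size == 1


def test_conditional_average_pooled_mean_permutation_invariant(rng):
    prev, nxt = rng.random(5000), rng.random(5000)
    ca = conditional_average((prev, nxt), "on->on", l=700)
    perm = rng.permutation(5000)
    cb = conditional_average((prev[perm], nxt[perm]), "on->on", l=700)
    pooled_a = np.sum(ca.cond_means * ca.block_counts) / ca.n_pairs
    pooled_b = np.sum(cb.cond_means * cb.block_counts) / cb.n_pairs
    assert pooled_a == pytest.approx(pooled_b, rel=1e-12)


def test_conditional_average_signs_for_correlated_generator(rng):
    """H=0.85, cross_rho<0: same-state curves rise, cross-state curves fall."""
    params = CorrelatedRenewalParams(base=RenewalParams(n_steps=2**18))
    r = extract_residences(build_correlated_renewal(params, rng=rng)).interior()
    t_stats = {}
    for kind in ("on->on", "off->off", "on->off", "off->on"):
        ca = conditional_average(r, kind, l=1000)
        res = stats.linregress(np.log10(ca.bin_centers), ca.cond_means)
        t_stats[kind] = res.slope / res.stderr
    assert t_stats["on->on"] > 3 and t_stats["off->off"] > 3
    assert t_stats["on->off"] < -3 and t_stats["off->on"] < -3


# ------------------------------------------------- residence-series PSD ----
def test_residence_psd_constant_and_iid(rng):
    const = ResidenceSequence(np.full(64, 3.0), np.tile([1, -1], 32))
    sp = residence_sequence_psd(const, "interleaved")
    assert np.allclose(sp.power, 0.0)
    iid = ResidenceSequence(rng.exponential(5, 4096) + 1, np.tile([1, -1], 2048))
    sp2 = residence_sequence_psd(iid, "on-only")
    fit = fit_loglog_slope(sp2, sp2.freqs[2], sp2.nyquist / 2)
    assert abs(fit.beta) < 0.15


def test_residence_psd_fgn_copula_slope_matches_oracle(rng):
    """Hurst-H duration sequence: PSD slope ~ 2H-1, vs a direct fGn oracle."""
    from scipy.special import ndtr

    h = 0.85
    dist = CutoffPowerLaw(1.2, 60.0)
    seqs, raws = [], []
    for _ in range(24):
        z = fractional_gaussian_noise(2048, h, rng)
        tau = np.ceil(dist.ppf(np.clip(ndtr(z), 0, 1 - 1e-12)))
        seqs.append(ResidenceSequence(tau, np.where(np.arange(2048) % 2, -1, 1)))
        raws.append(z)
    sp = residence_sequence_psd(seqs, "interleaved")
    band = (4 / 2048, 0.1)
    beta_impl = fit_loglog_slope(sp, *band).beta
    from hydrospec.spectral import ensemble_psd

    beta_fgn = fit_loglog_slope(ensemble_psd(raws, 1.0), *band).beta
    assert beta_fgn == pytest.approx(2 * h - 1, abs=0.12)
    # the monotone copula map attenuates but preserves the long-memory sign
    assert beta_impl > 0.3
    assert beta_impl == pytest.approx(beta_fgn, abs=0.3)


def test_residence_psd_too_few_durations():
    tiny = ResidenceSequence(np.arange(1.0, 9.0), np.tile([1, -1], 4))
    with pytest.raises(ValueError):
        residence_sequence_psd(tiny, "interleaved")
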