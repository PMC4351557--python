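# Methods

## The process model

The object of study is a two-state ("on/off") reduction of a hydration
count series N(t): a site is *on* at a frame when its water count is
strictly above the site's own time-averaged count, *off* otherwise (ties go
to off, which makes integer series deterministic).  The durations of
uninterrupted stays — residence or sojourn times τ — are modeled by a power
law with exponential cutoff,

    P(τ) = A τ^−(1+α) exp(−τ/τ_c),   τ ≥ τ_min,
    A⁻¹ = τ_c^−α Γ(−α, τ_min/τ_c),

where Γ(s, x) is the non-regularized upper incomplete gamma function at
negative shape.  α controls the tail (α > 1 ⇒ finite mean ⇒ stationarity
and no aging), τ_c truncates it, and τ_min is the resolution floor.  For an
*alternating renewal* process (independent sojourns, state-specific
cutoffs) with 1 < α < 2, the power spectrum obeys S(f) ∝ f^−(2−α) in the
band 1/τ_c ≪ 2πf ≪ 1/μ̄ (μ̄ the mean sojourn), flattening into a plateau
below the cutoff scale.  A *correlated renewal* process keeps the same
marginals but couples successive sojourns; its spectrum is steeper than
f^−(2−α), and the excess is removed by shuffling the sojourns — the basis
of the surrogate test.

## Synthetic generators and what they emulate

The generators stand in for per-lipid MD hydration-count series (128 sites,
131 ns at 1 ps frames in the reference system, no deposited trajectories).
Conditions follow the reference analysis throughout: α = 1.2, on/off
cutoffs 60/1000 ps, dt = 1 ps, and 2^17-frame series for spectral work.

- **Sampler.**  Rejection sampling with a Pareto(α, τ_min) proposal and
  acceptance exp(−τ/τ_c): exact marginal, ~90% acceptance at the reference
  settings, no numerical inversion in the hot loop.  τ_c = ∞ gives the pure
  Pareto law (used for the aging control at α = 0.7).
- **Rasterization.**  Durations are continuous internally and rounded up to
  whole frames (minimum one frame) when a telegraph series is built; the
  final sojourn is truncated at the horizon and flagged censored.  The
  generator also returns its rasterized sojourn log, which run-length
  extraction must reproduce exactly (a round-trip test).
- **Correlated renewal.**  A Gaussian copula over a latent long-memory
  driver: per state channel, fractional Gaussian noise with Hurst index H
  synthesized by circulant embedding (exact covariance); the off channel is
  ρ× the on channel plus an independent fGn complement, which is again
  exactly fGn.  Each latent value maps through Φ and the numerical quantile
  of the cutoff power law, so sojourn marginals are untouched while
  same-state sojourns correlate positively and cross-state sojourns
  negatively.  The data give no generative model for these correlations;
  this construction is the simplest stationary mechanism with the right
  sign structure.  H defaults to 0.85 (a clearly super-diffusive latent
  memory that reproduces the qualitative conditional-average curves) and
  the cross-channel correlation to −0.5 (mid-range; only its sign is
  constrained by the observations).
- **Markov baseline.**  iid ±1 frames with P(+1) = p = 1/2, arranged as
  12,800 segments of 600 frames (128 series × 100 segments) — the
  memoryless reference for the non-Markovianity statistic.
- **Count emulator.**  N(t) = Σ_k 1[site_k on] + rounded Gaussian noise
  over 20 independent renewal sites.  Site cutoffs (on 10^4 ps, off
  2.3556 ps at α = 1.2) were chosen so the *frame-resolution* occupancy
  E[⌈τ_on⌉]/(E[⌈τ_on⌉]+E[⌈τ_off⌉]) is 0.70, giving a mean count of 14;
  the rasterized mean E[⌈τ⌉] = 1 + Σ_k sf(k) differs appreciably from the
  continuous mean because off sojourns span only a few frames.

What the generators do *not* emulate: the spatial structure of the membrane
(site-site coupling — emulator sites are independent), the microscopic
mechanism of the sojourn correlations, sub-frame dynamics, and drifts of
the per-site mean.  Passing tests therefore validate the analysis chain and
the stochastic theory, not any claim about real membranes.

## Estimators and numerical choices

- **Spectra.**  One-sided mean-subtracted periodograms with density scaling
  (units²·ps), S(f_k) for k = 1…N/2; Parseval holds exactly
  (Σ S Δf = variance).  Ensembles are averaged pointwise without tapering
  or Welch segmenting, mirroring averaging over lipids.  Internal frequency
  unit is ps⁻¹ (1 ps⁻¹ = 10¹² Hz); files are written in Hz.
- **Slope fits.**  Least squares of log S on log f after averaging the
  log-transformed points in quarter-decade bins (equal leverage per decade;
  exact power laws are recovered to machine precision; a constant log
  offset from averaging noise cancels in the slope).
- **Transition detection.**  Two-segment continuous model in log–log space
  (flat level below the breakpoint, free slope above), least squares over
  breakpoint candidates on a log-rebinned grid, accepted only if it beats a
  single line on AIC.  Validated against a dense grid-search oracle and a
  Lorentzian knee (within a factor 2 of f₀).
- **Default fit band.**  3× the detected transition frequency up to
  Nyquist/4, configurable.  At the reference renewal settings this yields
  β ≈ 0.74 ± 0.02 against the asymptotic 0.8: the local slope varies across
  the band because the power-law window between τ_min = 1 ps and
  τ_c,on = 60 ps is narrow (verified against the exact renewal-theory
  spectrum computed from characteristic functions).  The asymptote
  β = 2 − α is approached only slowly — the leading correction decays as
  ω^(2−α) — so for α near 2 no practical series length displays it; tests
  of that relation are sharpest at α close to 1.
- **Aging check.**  Ensemble PSDs on nested prefixes (default ratios
  1:4:16:64 of the record); spectra are smoothed by quarter-decade
  rebinning, interpolated onto a common log-frequency grid, and compared by
  the maximum pairwise |log₁₀ S₁ − log₁₀ S₂|.  "Coincide" means an offset
  below log₁₀ 2.  Finite-mean processes pass; the α = 0.7 pure power law
  fails, as weak ergodicity breaking requires.
- **Residence-time MLE.**  Continuous likelihood with the normalization
  above; Γ(−α, x) is computed by the downward recurrence from scipy's
  positive-shape gammaincc, with an asymptotic series for large x and an
  arbitrary-precision (mpmath) fallback where cancellation is detected.
  Profile-likelihood 95% intervals by bisection on the likelihood-ratio
  boundary.  For *frame-quantized* runs the continuous likelihood is badly
  biased — most runs span 2–3 frames — so the package fits those with the
  exact discrete cell probabilities P(k) ∝ Γ(−α,(k−1)dt/τ_c) −
  Γ(−α,k dt/τ_c), conditioned on k ≥ 2 (one-frame runs are pure
  quantization; the support bound cancels from the conditional likelihood).
  The τ_c estimate is intrinsically noisy (log-sd ≈ 0.22 at n = 10⁵,
  α = 1.2, τ_c = 1000: few observations ever sample the cutoff region), so
  recovery claims are made on replicate geometric means.
- **Censoring.**  The first and last runs of every series touch the window
  boundary and are length-biased: they are excluded from distribution fits
  and conditional averages but retained when rasterizing for spectra.
- **Conditional averages.**  Pairs (τ_i, τ_{i+1}) of a given state pattern
  are sorted by the previous duration and grouped in blocks of l = 1000;
  block means of previous and next duration form the curve.  A final
  partial block is reported with its count.  Pooling blocks across *many*
  long-memory series leaves a residual slope even after shuffling (series-
  level mean heterogeneity), so memory-vs-surrogate comparisons are best
  made within one long series.
- **Non-Markovianity.**  G(Δ, T) = (1/(M²|𝒯|)) Σ_t Σ_{i,j} |P(i,t|j,t−Δ) −
  P_CK(i,t|j,t−Δ)| with M = 2, where P_CK chains the time-inhomogeneous
  one-step estimates from t−Δ to t; undefined conditionals (zero-count
  states) are excluded, not imputed.  All pairwise counts come from a
  single S·Sᵀ-type matrix product, so the 12,800 × 600 ensemble is
  processed in seconds.  At Δ = 1, CK holds identically and G = 0; the iid
  baseline floor at the reference ensemble size measures ≈ 0.005 (max over
  Δ), the resolution below which non-Markovianity is not detectable.  Both
  the maximum of G over Δ and its mean are reported.

## Finite-window effects worth knowing about

Two real, scale-dependent effects show up in desk-scale runs and are
covered by the tests rather than hidden.  First, a finite observation
window under long-memory sojourns underweights long-duration epochs
(an inspection-paradox effect decaying only as m^(H−1) in the number of
sojourns), so the retained duration marginal of the correlated process is
slightly short-biased, and the shuffled surrogate built from it sits a few
hundredths *below* the independent-renewal exponent.  Second, single-path
statistics of long-memory sequences converge at n^(H−1), not n^(−1/2):
tests of marginal correctness must aggregate across independent paths.

## Limitations

- Orthorhombic boxes only in the counting step; hydrogen positions and
  angle criteria are not used.
- The G(Δ, T) statistic is a reconstruction of a deviation-from-CK measure
  from its symbol definitions; absolute values depend on ensemble size and
  should be compared against the iid baseline computed at the same size.
- The correlated-renewal generator is a phenomenological stand-in; its H
  and cross-correlation are calibration knobs, not measured quantities.
- MLE standard intervals assume independent sojourns; under long memory the
  effective sample size is smaller and the intervals are anti-conservative.
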