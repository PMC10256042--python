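# Methods

## The paradigm and its model of the data

A recording covers three contiguous behavioural conditions — Rest (~60 s),
a 100-s random-number-generation task, and a 60-s post-task rest — during
which the R–R interval series is treated as a locally stationary process
whose oscillatory content in two bands indexes autonomic control: LF
(0.04–0.15 Hz, baroreflex/blood-pressure-related modulation) and HF
(0.15–0.40 Hz, respiratory modulation, parasympathetically mediated).
Very-low-frequency power (< 0.04 Hz) is never computed: the 30-s analysis
window cannot resolve it.

The diagnostic construct is *reactivity*: healthy subjects suppress HF
(and raise LF/HF) under task load and rebound afterwards, whereas
depression and chronic-fatigue phenotypes show a reduced baseline and a
blunted response. The nine-feature vector (Rest levels plus Task/Rest and
After/Rest ratios of HF, LF, LF/HF) encodes level, response, and recovery
in one subject-wise summary.

## Preprocessing

- **Range filter.** Intervals outside 273–1500 ms (instantaneous rate
  above ~220 or below 40 bpm) are artifacts. Each is replaced by the mean
  of the nearest valid interval on each side; an edge beat with only one
  valid neighbour copies it (preserves length with minimal bias), and
  runs of artifacts all use the flanking valid values (deterministic,
  order-independent). Onset times are rebuilt cumulatively from the
  corrected intervals before any resampling. Recordings with more than
  50% out-of-range beats are rejected as unusable.
- **Resampling.** The tachogram is interpolated on a uniform grid at
  `fs = 1/mean(RR)` — one sample per mean beat, so ~1.25 Hz at 75 bpm,
  giving a Nyquist of ~0.625 Hz that comfortably covers the HF band.
  Cubic splines are the default (common HRV practice; the choice is not
  critical at these band edges); a linear mode exists where exactness
  matters. The grid starts at the first beat onset and spans the whole
  recording in one pass — conditions are assumed contiguous.

## Spectral estimation

Maximum-entropy spectra are computed per window by Burg's method:
reflection coefficients minimise the summed forward/backward prediction
error under the Levinson constraint, guaranteeing `|k| ≤ 1` (stability).
Windows are mean-detrended only — removing DC without distorting LF.
Defaults, all configurable:

- **AR order** `min(⌊N/3⌋, 20)` for an `N`-sample window (~12 at
  75 bpm): high enough to place one resonance per band, low enough to
  stay stable on ~37 samples.
- **PSD and integration.** One-sided
  `S(f) = 2σ²/(fs·|1 + Σ aₖe^(−i2πkf/fs)|²)`, normalised so
  `∫₀^{fs/2} S = variance`. The integration grid is uniform at 0.001 Hz
  *plus* geometrically spaced refinement points around each pole within
  radius 0.9 of the unit circle: AR peaks are near-Lorentzian with
  half-width `(1−|p|)·fs/2π`, far narrower than any fixed grid at high
  SNR, and the refinement keeps the trapezoidal integral (and hence the
  Parseval identity) accurate to well under 1% regardless of peak
  sharpness. Band edges are included by interpolating the PSD at the
  exact endpoints, so the shared 0.15-Hz boundary splits consistently
  between LF and HF.
- **Sliding trend.** Estimates every 2 s from the trailing 30-s window,
  from t = 30 s to the end of the recording; heart rate per estimate is
  `60000/mean(RR)` of the window. LF/HF is flagged undefined (NaN)
  whenever HF < 10⁻⁶ ms² rather than returned as a number.
- **Period averaging.** A trend estimate is assigned to a condition by
  its timestamp; the first 30 s of every condition are skipped, which
  exactly covers the trailing window's memory of the previous condition,
  so no window straddling a boundary contributes.

## Synthetic data: what it emulates and what it does not

`generate_rr_trace` builds beats iteratively —
`RR = mean_rr(c) + a_LF sin(2πf_LF t) + a_HF sin(2πf_HF t) + N(0, σ)`
with condition-wise parameters and cumulative onsets — and then
optionally replaces a fraction of beats with out-of-range values (the
timeline is kept from the clean values, so condition boundaries do not
move). Fixed-frequency sinusoids were chosen over band-limited noise
because they give the closed-form band power `a²/2`, which calibrates the
whole spectral chain; a real HF peak wanders with respiration, so
recovery on real data will be somewhat worse than these tests show. A
``band_noise`` mode replaces each sinusoid by 20 random-phase tones
spread over the band (unit variance overall, so an amplitude ``a`` still
targets ``a²/2`` of band power, though a single realisation fluctuates by
tens of percent); it is the more realistic but uncalibratable
alternative.
Condition transitions are instantaneous (no adaptation period is
simulated — the analysis consumes only the 220-s paradigm window).

The calibration suite uses beat noise σ = 3 ms. White beat noise raises a
band's power by `σ²·Δf/(fs/2)` (its share of the flat floor); at 3 ms the
floor contributes < 8% of the weakest tested modulation (amplitude 10 ms,
power 50 ms²), keeping the 15% recovery tolerance meaningful. At σ = 5 ms
the floor alone would add ~20% to that cell — a physical effect, not an
estimator defect.

`generate_cohort` draws each feature independently from a moment-matched
lognormal (`σ² = ln(1+sd²/mean²)`, `μ = ln mean − σ²/2`) — published
power features are positive and right-skewed with sd of the order of the
mean — or from a zero-truncated normal where symmetry is wanted (HR,
test cohorts). The published tables give only marginal (mean, sd) per
group, so within-subject correlations across the nine features are *not*
reproduced by default (an optional Gaussian-copula correlation matrix
exists, but has no data-derived value; note that skewed margins attenuate
the realised Pearson correlation relative to the copula's), and
ratio-feature moments are delta-method approximations (ratio of means;
CVs added in quadrature). Discriminant results on such
cohorts therefore demonstrate better-than-chance separation driven by
the marginal differences, not the published sensitivity/specificity,
which depend on the unknown joint structure.

`generate_digit_sequence` chooses, per step: a ±1 move with probability
`p_count` (uniform over the directions that stay inside 0–9 — at the
edges only one direction is feasible, so a pure counter attains CB = 1),
a repeat of the previous inter-digit step with probability
`p_repeat_interval` (when feasible), else a uniform digit.

## Randomness indices

CB and IB are plain frequencies: of |step| = 1 among the `n−1` steps, and
of repeated signed steps among the `n−2` adjacent step pairs — signed,
because "the same interval" most naturally means the same step repeated.
CB is non-modular (9→0 is not counting). RNG is Evans' digram
concentration, `Σ n_ij ln n_ij / Σ n_i ln n_i` over the occupied cells of
the 10×10 first-order pair table with row marginals `n_i`; the ratio is
base-invariant (natural log used), 0 when every occupied digram is a
singleton (denominator 0 is also mapped to 0, flagged by convention), 1
when each digit determines its successor. Alternative historical variants
of CB/IB exist; these definitions are the package's fixed, documented
choice.

## Discriminant analysis

Fisher LDA with equal priors and the midpoint cut: `w = S⁻¹(μ₊ − μ₋)`,
cut `w·(μ₊+μ₋)/2`, where `S` is the pooled within-group covariance
(ridge `10⁻⁶·tr(S)/p` added only if singular). No feature
standardisation — LDA is affine-invariant and the coefficients stay in
raw units. Scores of exactly zero count as positive: the report bins
(D > 0 / D < 0) must be exhaustive and the rule total. Reported
sensitivity/specificity are resubstitution (training-set) values, the
convention of the published tables; they are optimistic relative to
held-out performance. The Mahalanobis distance uses the same pooled
covariance; its p-value comes from Hotelling's T² mapped to
`F(p, n₁+n₂−p−1)`.

## Summary statistics

Pearson chi-square (no continuity correction), pooled-variance Student t,
and one-way ANOVA F are computed from group summaries by their defining
sums; scipy supplies the reference distributions. The pooled (rather than
Welch) t is used because the group variances enter via the published
summaries and the pooled form reproduces the published worked value
within input rounding. Repeated-measures ANOVA and post-hoc tests are out
of scope: they need per-subject raw data that summaries cannot supply.

## Problem sizes and numerical notes

The test and acceptance runs use 220-s single-subject traces (~96
spectral estimates), cohorts of 44–500 per group, 100 replicates × 1000
samples for the AR(1) recovery, and 10 replicates × 500/500 for the LDA
calibration — sizes at which every stochastic check has comfortably more
precision than its tolerance while the whole suite runs in seconds.
Stochastic calibration quantities (band-power error, LDA rates) are
reported as means over replicate draws; a single draw of the weakest cell
has ~4–5% sampling noise of its own. Degenerate inputs are handled
explicitly: constant windows yield a flagged zero spectrum; zero-variance
group summaries yield t = 0 or an infinite-t/F flag depending on the
means; empty averaging intervals and unusable recordings raise errors
naming the condition or stage.

## Known limitations

- Agreement with any particular commercial maximum-entropy implementation
  cannot be asserted; its AR order and integration scheme are
  unpublished. The package asserts analytic properties (Parseval, band
  recovery, AR-coefficient recovery) instead.
- Independent-feature cohorts understate (or overstate) the joint
  separability of real groups; see above.
- R-peak detection from raw ECG is out of scope; the pipeline starts at
  the R–R series.
- The respiration channel is reduced to the requirement that HF modulation
  frequencies lie in 0.15–0.4 Hz.
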