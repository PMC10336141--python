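# Methods

This note documents the models, parameter choices, and numerical decisions
behind `circare`, and what the synthetic experiments do and do not show.

## Signal model and energy accounting

An actigraphy record is treated as a uniformly sampled non-negative series of
activity counts per minute. Its energy is the sum of squared values
(units (counts)²/min²). Singular spectrum analysis embeds the series as an
L×K Hankel trajectory matrix T (K = N − L + 1), factors it by SVD, and maps
each rank-one term back to a series by averaging along anti-diagonals. The
squared singular values partition ‖T‖²_F exactly, so defining group energies
as Σσᵢ² makes the four reported fractions — base, circadian, behavioural
noise, other — an exact partition of unity regardless of how the groups are
chosen. CARE is the circadian share of that partition.

An alternative `energy_basis="series"` computes group energies from the
diagonal-averaged series instead (denominator: energy of the preprocessed
series). This matches the intuition of "energy of the reconstructed 24-h
signal" but is not an exact partition (diagonal averaging is not orthogonal),
so it is offered for sensitivity analysis only. Both numerator and
denominator always refer to the preprocessed (imputed, valid-day) record, so
they share one basis.

## Window length, rank, grouping

- **Window length L.** Default 2880 epochs (2 days of minutes) when the
  record has at least 4 days, else the largest whole number of days that fits
  in N/2. A window divisible by the 24-h period maximises separability of the
  circadian pair. L is exposed as configuration. The trajectory container
  accepts any 2 ≤ L ≤ N − 1 (L and K are interchangeable in SSA); N/2 is the
  recommended regime, not a hard bound.
- **Rank.** Default 50 eigentriples. High-rank SSA components of count data
  are high-frequency, so the truncation residual ‖T‖²_F − Σσᵢ² is credited to
  the behavioural-noise group; this keeps the partition exact and makes CARE
  conservative (never inflated by truncation). For small problems
  (min(L, K) ≤ 512) a dense SVD is used; otherwise a truncated SVD runs on
  the Hankel matrix as an FFT-based linear operator (a Hankel matrix-vector
  product is a convolution), with a deterministic start vector so repeated
  runs are bit-identical.
- **Dominant period.** Per component: the inverse of the arg-max frequency of
  the mean-removed periodogram, ties broken toward the lower frequency; a
  component with more than half its energy at DC is trend-like (period
  undefined). At 3–7-day record lengths the periodogram grid around 24 h is
  coarse (e.g. 1260/1440/1680 min at 7 days), which motivates the default
  circadian band of [1320, 1560] min (24 h ± 2 h): wide enough to absorb bin
  granularity, narrow enough to exclude the 12-h harmonic.
- **Grouping.** The rank-1 eigentriple is always the base signal, because for
  non-negative count data the largest-energy component is the DC/trend term.
  (For an artificial zero-mean input the rank-1 component would instead be
  one member of the circadian quadrature pair; the separability test
  therefore includes a positive mean, as real count data always do.)
  Dominant period inside the band → circadian; below → noise; above, or
  undefined at index > 1 → "other", which keeps both numerators honest
  without contaminating the denominator. The 12-h and shorter harmonics of a
  non-sinusoidal daily waveform are counted as behavioural noise, consistent
  with defining the noise group as periods < 24 h.
- Per subject, CARE is computed once on the full concatenated valid-day
  record, not averaged over per-day estimates; multi-day windows are what
  stabilise the 24-h pair.

## Preprocessing rules

Zero-count runs are off-wrist candidates: a run of ≥ 15 min lying entirely
inside 08:00–23:00, or ≥ 3 h touching the night window, is nonwear; a run
straddling the window boundary is judged by the more conservative 3-h rule.
Diary off-wrist intervals are always honoured. A calendar day is valid with
≥ 20 h of wear and no missing run longer than 3 consecutive hours (both
bounds inclusive); partial first/last days are dropped before scoring since
wear fractions are undefined on them. Missing epochs (nonwear or device gaps,
treated identically) are imputed in two stages: the mean of observed counts
at the same clock time on the other complete days, then — for gaps recurring
at a fixed clock time — the mean of the ~6 nearest observed epochs (3 per
side, shrinking at record edges). Observed epochs pass through bit-exactly,
and a record needs at least 3 valid days; retained days need not be
consecutive (non-contiguity is recorded in metadata, and re-indexing onto a
contiguous midnight-aligned grid preserves clock phase because only whole
days are concatenated).

## Melatonin model

The sparse-profile fit is a baseline plus skewed cosine pulse: daytime
baseline H (pg/ml), a single nocturnal pulse of height A peaking at acrophase
φ (clock minutes), half-widths w(1 − s) rising and w(1 + s) falling (mean
half-width w in minutes, skew s ∈ (−0.8, 0.8)), clipped at zero outside its
support. The exact parameterisation used in the original SBCF literature is
not public, so the form is isolated in one function (`sbcf_curve`) and can be
swapped without touching the fitting machinery. Fitting is bounded nonlinear
least squares with a 24-start grid (8 acrophases × 3 widths); a baseline-only
model is a guaranteed floor, so the returned RSS never exceeds the flat fit.
Melatonin amplitude is max − min of the fitted 24-h curve on a 1-min grid.

A note on identifiability: the study-style design (09:00, 15:00, 21:00,
03:00, 09:00 next day) contains only four distinct clock times, which cannot
identify five parameters of a 24-h-periodic model. Recovery experiments
therefore use an 18-h design with five distinct clock times (15:00, 21:00,
00:00, 03:00, 09:00), four on the pulse and one at baseline, under which all
parameters are recovered to machine precision from noise-free samples. With
1 pg/ml sample noise the acrophase is recovered within ±1 h in ~90% of fits;
the remaining misses reflect genuinely ambiguous 5-point data, not optimiser
failure.

Cleaning removes samples below 2 pg/ml collected at 03:00 ± 1 h (a low value
at the nocturnal peak indicates a collection problem; low daytime values are
physiological). Validation reports Pearson r and two-sided p of each wearable
feature against melatonin amplitude, with an optional OLS variance
decomposition (R² drop when a predictor is removed from the joint model).

## Synthetic study conditions

The generator emulates healthy adult wrist actigraphy at 60-s epochs as an
additive model: mesor 200 counts/min, a 24-h cosine of amplitude 120
counts/min peaking at 15:00, ~4 Poisson-timed rectangular daytime bursts/day
(300 counts/min × 30 min, placed in 08:00–23:00), optional linear trend,
Gaussian noise with SD 50 counts/min, and planted nonwear gaps; the sum is
clipped at zero. These defaults land the circadian energy fraction near 0.13,
inside the range reported for adult cohorts. Ground-truth fractions are the
component energies of the pre-clipping additive parts (they sum to 1 by
construction); a post-clipping empirical fraction is also reported so tests
can bound the clipping bias, and the generator warns when more than 5% of
epochs clip. Noise and burst placement draw from independent child streams of
the seed, so adding bursts leaves the noise realisation fixed — the basis of
the masking experiments. Cohorts grade the cosine amplitude linearly
(30–300 counts/min by default) to span fractions ≈ 0.01–0.46.

What the generator does *not* emulate: autocorrelated behavioural activity,
day-to-day phase drift and social scheduling (weekday/weekend structure),
device calibration differences, and the heavy-tailed, zero-inflated
distribution of real counts. Passing recovery tests therefore show that the
pipeline measures what it claims under the additive model, not that CARE is
unbiased on any particular device or population.

## The masking experiment

Daytime behavioural bursts are phase-locked to the circadian activity peak,
so their day-coherent component adds constructively to the apparent 24-h
oscillation: the cross term grows linearly with burst load while the
broadband (noise) energy grows quadratically with burst height. Gentle,
prolonged bouts (the generator's defaults) can therefore *raise* CARE
slightly — a real property of energy ratios on additive signals, documented
here as a limitation. The masking robustness experiment uses vigorous short
bouts (1000 counts/min × 15 min, 4/day), for which the quadratic broadband
term dominates and CARE strictly decreases while the noise fraction strictly
increases in every replicate.

## Numerical choices and degenerate inputs

- SVD sign ambiguity is fixed by making the largest-magnitude element of each
  left singular vector positive; with the deterministic start vector this
  makes decompositions reproducible run to run.
- Relative amplitude is computed on the average 24-h profile (mean count at
  each clock minute over the record) with circular 600-/300-min windows at
  epoch resolution; RA = 0 by convention when M10 = L5 = 0. RA of an
  all-positive constant record is 0; a record active in a single 10-h block
  is 1.
- An all-zero record is rejected as degenerate (CARE would be 0/0), as is a
  record with no observed wear epochs; a subject with < 3 valid days raises
  an insufficient-data error carrying the day count. The CLI maps these to
  exit codes 2 (invalid input) and 3 (insufficient data) and lists failed
  subjects with reasons instead of dropping them silently.
- The FFT baseline (`band_energy_fft`) is the share of mean-removed
  periodogram power in the circadian band. Because CARE's denominator
  includes the trend while the FFT baseline's cannot, the cross-method
  agreement check compares the FFT fraction with CARE rescaled to the
  non-base energy, care / (1 − base fraction); on a noiseless
  cosine-plus-constant the two agree to well under 0.05.

## Problem sizes

Tests and the acceptance script use 3–7-day records (N = 4320–10080 epochs at
60 s), cohorts of 20 subjects, 10-replicate masking experiments, and
100-replicate SBCF noise studies; the full suite and the acceptance script
each complete in well under a minute on a single CPU.
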