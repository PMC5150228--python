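# Methods

This note documents the models, estimators and numerical choices behind
`eeglifespan`, and what its synthetic cohorts do and do not establish
about real recordings.

## Cleaning chain

The artifact gate operates on filtered signals: a zero-phase IIR notch
(second order, Q = 30) at the session's mains frequency, then a
zero-phase Butterworth bandpass at 2–36 Hz. The bandpass contract is
stated as an attenuation requirement — 5–30 Hz within ±1 dB, DC and
everything ≥45 Hz down at least 20 dB after the forward–backward
application — and an order-5 design meets it with margin (measured:
−0.75 dB worst passband ripple, −26.8 dB at 45 Hz); an order-4 design
does not (−1.18 dB in the passband), which is why order 5 is the
default. Since the contract, not the filter family, is load-bearing,
any compliant design may be substituted.

Epoch "overall power" is the **mean** of squared samples (µV²). The
threshold (275 µV²) is dimensionally a power, and a mean is invariant
to epoch length, unlike a sum; this is the only reading under which the
threshold is meaningful for arbitrary epoch sizes. Both gates are
strict inequalities: an epoch at exactly 275 µV² is kept, a session at
exactly 10 % rejection is kept.

Rejection is scored per channel but applied jointly: an epoch over
threshold on any channel is dropped from all four, keeping the channels
time-aligned so asymmetry measures compare identical time ranges. The
per-channel rejection fractions are nonetheless tracked separately,
because the session verdict asks whether *any* channel exceeds 10 %.
Exclusion propagates across the CAL/NFB pair of the same recording
order, keyed by (user, order). Sessions with fewer than 10 clean epochs
are flagged `too_short` and excluded; this guards degenerate spectra
and is a package choice where the source procedure is silent.

The five-session cap counts **clean** sessions in recording order: a
user whose clean sessions are the 2nd, 5th and 7th recordings keeps all
three.

## Spectra on an exact 1-Hz grid

A 256-sample epoch at 220 Hz does not have integer-hertz Fourier bins.
The artifact gate therefore keeps its 256-sample windows (they define
the rejection bookkeeping), while spectra are computed on rectangular,
non-overlapping **220-sample** windows tiled across the concatenation
of the kept epochs, whose bins fall exactly on 0, 1, …, 110 Hz. The
periodogram is scaled so the bins sum to the mean squared amplitude of
the analyzed samples; Parseval then holds by construction and is
asserted to 1 % in the tests (the slack covers the discarded
sub-window remainder). Windows are rectangular and non-overlapping — a
plain averaged periodogram — because nothing more elaborate is assumed
by the band definitions. The spectrum is checked against a brute-force
DFT oracle at 1e-10 relative error.

Band powers are inclusive integer-bin sums, so lower-α (8–10) and
upper-α (11–13) partition α (8–13) exactly. Zero band power yields an
absent feature (NaN with a logged reason), never −∞.

The peak alpha frequency is the argmax over the 8–13 Hz bins, reported
only when it strictly exceeds both 1-Hz neighbours *on the full grid*
(so 8 and 13 Hz have defined neighbours at 7 and 14 Hz); ties break to
the lowest frequency. A monotone 1/f spectrum therefore yields no peak,
which operationalizes "no visible alpha peak" — common at frontal
sites — as a local-maximum criterion.

Per-user averaging operates on the log-transformed band powers
(transform-then-average), matching the order in which the transform
enters the feature definitions; alpha peaks are averaged over the
sessions in which a peak exists, with that count recorded and used as
the regression weight adjustment.

## Age-trend regression

Cells are (age × sex), not age alone: the model contains sex terms, and
only sex-separated cells make the cell-level WLS coefficients exactly
equal to user-level OLS (the predictors are then constant within
cells). That identity is asserted at 1e-8 against both statsmodels OLS
and a brute-force normal-equations oracle.

Conventions: age centered at 42 years (the intercept is the prediction
for a 42-year-old male), sex coded male = 0 / female = 1, significance
stars at 0.05/0.01/0.001/0.0001, no multiple-testing correction.
Coefficient p-values use the cell-level residual degrees of freedom;
with one cell per (age, sex) this is on the order of 110 cells for a
full adult age range, where the t reference is essentially exact, and
the choice is recorded in the run metadata. The per-sex refit (age and
age² only) is triggered when either sex interaction has p < 0.05 — a
union of two level-0.05 tests, which consequently fires at roughly
9–10 % under the null even though each component test is calibrated at
5 %; the calibration suite therefore measures the per-interaction
rejection rate. A sex with fewer than 4 cells skips its refit with a
warning.

The omnibus gate (age, age², sex, task, channel and all interactions up
to four-way, treatment coding) is fitted only to justify analysing
channels and tasks separately; its coefficients are not reported.

Quartiles in distribution summaries are medians of the
median-exclusive halves, and adjacent values are the most extreme
observations within 1.5 IQR of the quartiles (Tukey convention).

## Synthetic cohorts: what they emulate

The generator's target spectrum per subject, sex and channel is

    S(f) = gain_ch · 10^(s·κ) · [ c/f^β + plateaus(f) + A·exp(−(f−µ(age))²/2w²) ]

with µ(age) = 9.54145 − 0.01891·(age−42) Hz by default, c = 24 µV²/Hz,
β = 1, A = 18 µV²/Hz, w = 1.2 Hz, temporoparietal gains ≈1 vs frontal
≈0.45, and a female offset κ = 0.05 log₁₀ units. The alpha bump is
Gaussian because the peak is then analytically known; its center is
constrained to stay inside 8–13 Hz over the cohort's age range. Default
demographic structure (≈27 % female; age mass concentrated in the 30s
and 40s, thinning beyond 70) follows a large published consumer-EEG
cohort.

Sessions are phase-randomized surrogates: component amplitudes
√(2·S(f_k)·Δf) with i.i.d. uniform phases, giving stationary
Gaussian-like signals whose expected periodogram is the target and
whose mean square equals its integral. Real EEG is nonstationary;
stationarity suffices to test the estimators, and nothing here should
be read as a physiological model. Artifact bursts are in-band 10-Hz
sinusoids (default 150 µV, i.e. epoch power ≈ 11 250 µV² ≫ 275) added
to a Bernoulli subset of 256-sample windows on all channels, with the
contaminated indices kept as ground truth so the rejection stage can be
scored as a classifier — with burst amplitude far above background,
recall is 1 by test.

Because the 1-s analysis windows leak (Fejér kernel) on the steep
shoulders of the alpha bump, spectral-fidelity checks compare a
finer-resolution Welch estimate (10-s windows, aggregated to 1-Hz bins)
against the target; the pipeline's own 1-Hz estimator carries the same
leakage any 1-s rectangular-window FFT would, which is part of what it
emulates.

The feature-level simulator (`simulate_user_features`) shares the trend
model: log band powers are the generative six-coefficient linear
predictor (defaults taken from a temporoparietal reference channel)
plus channel gain, the female offset, and N(0, 0.35²) noise; peak alpha
is µ(age) + N(0, 0.9²), with detection an independent Bernoulli per
channel (defaults ≈89 % temporoparietal, ≈47–51 % frontal). The noise
scales encode the empirical fact that within-age variability dwarfs
between-age variability, and the decomposition test asserts exactly
that. By default the simulated peaks are continuous — an unbiased
sample of the population trend, which is what parameter-recovery
studies need; `quantize=True` additionally rounds to the 1-Hz grid and
censors to 8–13 Hz, reproducing the measurement chain's (slightly
biasing) discretization. The rendered-signal path keeps each subject's
alpha center deterministic given age; measured peaks from rendered
cohorts are therefore quantized values of a smooth age curve, which
recovers the sign and approximate magnitude of the slope but can
locally overshoot it — visible in the end-to-end example.

## Problem sizes

The statistical suites run at the sizes the questions demand and no
larger: the WLS/OLS identity on cohorts of 50–2000 users, slope
recovery on 100 cohorts of 2000 users (feature-level simulation; the
identity being tested lives in the regression layer, so rendering
hundreds of thousands of seconds of signal would add nothing),
refit-trigger calibration on 1000 cohorts of 300 users, and rendered
end-to-end runs at 120–150 users × 60-s sessions.

## Known limitations

- The generator does not model eye blinks, EMG, electrode pops or any
  physiologically realistic artifact — bursts exist to exercise the
  threshold rule, not to mimic contamination statistics.
- Rendered band powers carry no age trend beyond the alpha bump's
  movement; quadratic-in-age and interaction structure exists only in
  the feature-level simulator. Passing tests show the estimators
  recover known trends, not that real cohorts follow them.
- The regression layer treats users as independent; repeated sessions
  are averaged, never modelled longitudinally.
- Published headline coefficient tables from proprietary cohorts are
  not reproducible here by construction; only their arithmetic
  identities and the methodology are.
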