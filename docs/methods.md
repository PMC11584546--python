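# Methods

This note documents the models, conventions and numerical choices behind
voxfrail, in the order the pipeline runs.

## Vowel synthesis (source-filter model)

The synthetic sustained vowel is a classical source-filter construction.

**Source.** Each glottal cycle is a Rosenberg flow pulse: a rising cosine
ramp over two thirds of the open phase, a falling quarter-cosine over the
remaining third, and zero flow for the closed phase. The open quotient
(OQ, default 0.6, dimensionless in (0,1)) sets the open fraction of the
cycle. Cycles are sampled from the continuous pulse shape at their exact
fractional onsets, so an unperturbed train is a sampled periodic signal
with no cycle-length rounding artifacts — this matters: integer-rounded
cycle lengths alternate (e.g. 367/368 samples at f0 = 120 Hz, fs = 44.1
kHz) and inject a period-2 modulation that shows up as a spurious floor in
the stability features. The radiated source is the first difference of the
flow (the flow derivative).

Jitter and shimmer are i.i.d. Gaussian cycle-to-cycle perturbations of the
period and amplitude respectively, expressed as a percent SD (defaults
0.5% and 2%, typical of normal phonation) and truncated at ±3 SD so a
perturbed period can never collapse. Aspiration noise is white Gaussian
added at a stated SNR in dB (default 30 dB; `inf`/None disables it).

**Spectral tilt.** The chief acoustic correlate of the open quotient is
the tilt of the source spectrum: a longer open phase lowers the maximum
flow declination rate and weakens high-frequency excitation, leaving the
first harmonic dominant. We apply this tilt explicitly as a one-pole
low-pass on the source with cutoff 6000·(1−OQ)² + 250 Hz (Klatt-style TL
control). The explicit filter is needed because the raw Rosenberg-derivative
spectrum carries deep notches whose positions sweep with OQ; sampled at
four narrow formant bands, those notches make the low-frequency energy
ratio respond non-monotonically to OQ even though the overall tilt trend
is monotone. With the explicit tilt the A4-vs-OQ response is monotone
across OQ 0.35–0.85.

**Filter.** A cascade of four second-order all-pole resonators with unity
DC gain at F1–F4 = 800/1200/2500/3500 Hz, bandwidths 80/90/120/130 Hz —
textbook values for an adult /a/; all overridable. F1 and F2 may drift
sinusoidally with a common phase (amplitude `drift_amplitude` Hz, rate
`drift_rate` Hz, defaults 0 and 3); the filter coefficients are updated
every ~5 ms with filter state carried across blocks. F3/F4 stay fixed
because the formant-variation feature only reads F1/F2. The synthesizer
generates 50 ms of warm-up signal and discards it, so the emitted waveform
is steady state; output is DC-free and peak-normalized to |1|.

**What the generator does not emulate.** Intelligible speech, onset/offset
dynamics (attack, vocal fry), microphone and room coloration, nonlinear
source-filter interaction, and the correlation structure of real ageing
voices. Tests passing on this generator demonstrate that the extractors
measure what they claim under known truth — not that the features are
clinically discriminative.

## Acoustic parameters

All extractors subtract the signal mean (DC offset) first and are
deterministic and amplitude-scale invariant.

**A1 — mean zero-crossing rate** (dimensionless, [0,1]). Per 20 ms frame
(10 ms hop), the number of sign changes between consecutive samples
divided by the frame length in samples, averaged over frames. Two details:
a sample equal to zero is counted with the non-negative class, so an exact
zero between a sign change costs nothing; and each frame counts changes
over exactly `frame` intervals (the window extends one sample past the
frame end), which keeps the frame average unbiased even when the hop is
phase-locked to the signal period. On pure tones A1 is within 0.1% of the
analytic 2f/fs for 80–1000 Hz.

**A2 — local peak/valley variation** (% by default). Per frame, the
largest local-maximum amplitude P_i and the smallest local-minimum
amplitude V_i (SciPy `find_peaks` on x and −x); across frames, the mean
absolute deviations D_P and D_V of these series from their means;
A2 = 100·(D_P/|mean P| + D_V/|mean V|)/2. "Average deviation" is read as
mean absolute deviation throughout the package. The normalization by the
mean extremum makes A2 relative (scale-free); a raw-amplitude variant is
available via `A2Config(relative=False)` because the original analysis
chain may not have normalized. Frames without interior extrema are skipped
with a warning.

**A3 — formant-frequency variation** (Hz). The signal is anti-alias
downsampled to ≈11.025 kHz (polyphase), pre-emphasized (coefficient 0.97),
and analyzed in 30 ms Hamming frames at a 10 ms hop with autocorrelation
LPC of order 12 (tiny diagonal ridge for stability). Roots of the LP
polynomial with positive imaginary part become resonance candidates;
candidates need frequency > 90 Hz, < 95% of Nyquist, and bandwidth
< 400 Hz (bandwidth −fs/π·ln|r|). The two lowest surviving frequencies are
F1 < F2. A3 = (MAD(F1) + MAD(F2))/2 across frames. The 30 ms frame (rather
than the more common 25 ms) halves the estimation floor on unperturbed
vowels — with 25 ms frames the harmonic comb biases frame-wise estimates
enough to push the zero-drift floor above 5 Hz at f0 = 120. Order 12 is
kept over the model-matched order 10 because order 10, while better on
noiseless signals, degrades 6× under aspiration noise and biases drift
tracking upward. Under sinusoidal drift of amplitude d the expected A3 is
2d/π (the MAD of a sinusoid); the extractor matches this within ≈6% at
d = 40–80 Hz and agrees with independent spectrogram ridge tracking.

**A4 — low-frequency spectral energy ratio** (dimensionless, [0,1]).
Welch-averaged periodogram of the whole trimmed utterance (4096-sample
Hann segments, 50% overlap); A4 = power at frequencies ≤ 800 Hz over total
power to Nyquist. The bin at exactly 800 Hz counts toward the numerator.
A4 is monotone non-decreasing in the end frequency and equals 1 at
Nyquist.

## Recording QC

**Endpoint detection.** Rabiner-style double threshold on 20 ms/10 ms
short-time energy: the noise floor is the smaller of the first-100 ms mean
and the global minimum frame energy (so fully voiced inputs are their own
floor); the upper threshold sits 10% and the lower 2% of the way from the
floor to the maximum. The voiced span is the frames at or above the upper
threshold, extended outward while frames stay above the lower one, then
optionally extended over adjacent frames that combine a high zero-crossing
rate (≥ 0.25 crossings/sample) with above-floor energy — the energy
condition keeps broadband room noise, which also has a high ZCR, out of
the span. An input with no frame above threshold raises a no-speech error.
Trimming never lengthens a signal and is idempotent to within one hop.

**Duration gate.** Trimmed duration must lie in [0.8 s, 1.2 s]. The bounds
are inclusive: recordings *shorter than* 0.8 s or *longer than* 1.2 s are
withdrawn, so the bounds themselves pass.

**Repeat variability.** Exactly three repeats per subject. Per parameter,
CV% = 100·(population SD)/mean across the repeats; a parameter is accepted
iff CV% < 15 (strict), with the accepted value the 3-repeat mean — the
minimum-variance summary. A zero 3-repeat mean leaves the CV undefined and
the parameter missing, with a warning. The rule is per-parameter: one
unstable parameter does not discard a subject's other parameters. A
subject enters the analysis table only when all three repeats pass the
duration gate.

## Phenotype scoring

Scoring is a pure function of the assessment record. Boundary conventions
(fixed in `ScoringThresholds`, visible in config): weight loss ≥ 4.5 kg is
inclusive ("at least"), > 5% strict; grip cutoffs 28 kg (men) / 18 kg
(women) strict (low grip iff grip < cutoff); gait < 1.0 m/s strict. A
non-ambulatory subject (e.g. wheelchair user) meets the low-mobility
criterion without a gait measurement. Chair-rise inability is a binary
flag (no timed test is modelled). Missing required items make the affected
index *indeterminate*; models using that outcome exclude the subject
(complete-case) with a logged count. Both hybrid flags are reported even
though a subject frail on both indices satisfies both definitions; the
4-category variable (nonfrail / EBF-only / SBF-only / both) disambiguates.

## Association models

One acoustic exposure per model, per the design "each acoustic variable
evaluated separately"; covariate adjustment is supported but off by
default. Binary outcomes use binomial logistic regression; the 4-category
outcome uses multinomial logit with nonfrail as baseline. Estimation is
Newton maximum likelihood (statsmodels) with tolerance 1e-10 and at most
100 iterations; the score is ≈0 at convergence. Wald 95% CIs use
exp(β ± 1.96·SE). Perfect or quasi-perfect separation — detected by the
optimizer, by |β| > 30, or by fitted probabilities pinned at 0/1 — raises
an error instead of reporting an implausible estimate; empty outcome
categories are dropped with a warning. No multiple-testing correction is
applied; every results row carries the number of models fitted in the run
so readers can apply their own. Because the original feature scale behind
published per-unit effects is not recoverable, per-SD standardization of
the exposure is available as a flag (`standardize_exposure`), which
rescales β exactly by the exposure SD.

The odds-to-probability helper implements p = odds/(1+odds), the exact
inverse of p ↦ p/(1−p).

## Synthetic cohorts

Assessment items are drawn independently per subject: sex (55% female),
body weight N(60, 10) kg, exhaustion 50%, any weight loss 50% with
exponential (mean 5 kg) magnitude capped at 30% of body weight, chair-rise
inability 30%, grip N(28.5, 6) / N(19, 5) kg by sex, gait N(1.05, 0.30)
m/s, non-ambulatory 3%, ADL deterioration 30%. These defaults put frailty
prevalence near 15% on each index — inside the 12–24% population range
reported for older adults — and are deliberately *not* calibrated to any
clinical sample. Mode "phenotype" then draws features conditionally on the
scored truth (defaults: A2 +3%-points and A3 +6 Hz under SBF-frail, A1
−0.012 and A4 +0.08 under EBF-frail, matching the published directions of
association); mode "logistic" draws features marginally and the outcome
from Bernoulli(logistic(intercept + Σ coef·feature)) — the
parameter-recovery harness.

The on-disk study generator additionally maps phenotype to synthesis
knobs (SBF-frail → more shimmer and formant drift; EBF-frail → higher open
quotient and less aspiration noise), draws per-repeat durations N(1.0,
0.07) s clipped to [0.75, 1.25], and pads each vowel with 0.2 s of −55 dB
room noise so endpoint detection does real work.

## Verification design and problem sizes

Monotonicity studies treat each replicate as a separate speaker: f0 is
drawn uniformly from 100–200 Hz per replicate. At one fixed f0 the
harmonic comb's alignment with the 800 Hz band edge (F1 sits exactly on
it) adds a sawtooth ripple to mean A4 versus OQ that can mask the tilt
trend; across speakers the alignment averages out. Each monotonicity
contrast uses 50 replicates per level. Parameter recovery uses 200
replicate cohorts of n = 5000 with the A2 coefficient log(1.34) per unit
and ≈20% outcome prevalence; the null rejection rate uses 500 replicates
of n = 500 at ≈25% prevalence. The end-to-end study uses 60 subjects × 3
repeats. These sizes keep every Monte-Carlo standard error small relative
to the property being asserted while the whole suite runs in minutes.

## Known limitations

- The LPC formant tracker assumes a vowel-like spectrum with F1 < F2 below
  ≈5 kHz; it is not a general-purpose formant tracker and will mis-track
  breathy or high-pitched voices where harmonics outnumber resonances.
- A2's per-frame extremum reading is one of several defensible
  interpretations of "largest and smallest values of all peaks and
  valleys"; the raw/relative switch covers the main alternative, a global
  extremum pool does not have a time-series interpretation and is not
  implemented.
- The synthetic cohort draws assessment items independently; real frailty
  items are correlated, so synthetic phenotype co-occurrence rates are
  optimistic.
- Feature units are package conventions (A1 per sample, A2 %, A3 Hz, A4
  ratio); effect sizes per unit are not comparable to published values
  whose units are unrecoverable.
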