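# Methods

## The problem and the estimators

Two physiological conditions activate the brain's lymphatic drainage —
deep sleep and a reversible opening of the blood–brain barrier (OBBB) —
and both reshape the EEG.  The package quantifies those signatures on
two-lead cortical EEG with an EMG channel, sampled at 2 kHz
(0.5-ms step), using five complementary measures, and validates the
whole chain on a synthetic cohort whose ground truth is known exactly.

### Spectra and coherence

Welch estimation with 100-s windows, 50-s overlap and a Bartlett
(triangular) taper per segment; per-segment mean removal only, because
linear detrending would disturb the 0.1-Hz band of interest.  One-sided
density normalization (integral over [0, Nyquist] equals the tapered
variance).  Spectra are additionally smoothed in the frequency domain by
an unweighted (Daniell) moving average — 0.03 Hz for power spectra,
0.13 Hz for the spectra entering coherence.  With the 0.01-Hz grid of
100-s windows these are 3- and 13-bin windows; edge bins use truncated
windows.

Magnitude coherence `C(f) = |Gxy|/sqrt(Gxx·Gyy)` is formed *after*
segment averaging and Daniell smoothing of Gxx, Gyy, Gxy: a coherence
built from a single raw periodogram is identically 1, so smoothing
before the ratio is the only consistent order.  The result is clipped to
[0, 1].  The estimator has a positive bias floor ≈ sqrt(π/4K) for K
effective averages; tests account for this at zero true coherence.

The δ band appears twice on purpose: the broad 0–4 Hz convention used in
staging/methods, and the 0.1–0.5 Hz "slow" band where the OBBB power
contrast lives.  Both are provided as named bands and reported
separately; the package does not guess which a given reader intends.

### Sleep staging

A decision cascade on 10-s epochs: WAKE if EMG RMS is above threshold
and the 8–12 Hz power fraction exceeds 10%; else NREM if the 0–4 Hz
fraction exceeds 30% with low EMG; else REM if the 5–10 Hz fraction
exceeds 20% with low EMG; otherwise the epoch inherits the previous
label (the first epoch defaults to WAKE).  Two interpretation choices
are deliberate and prominent: "% of EEG waveforms per epoch" is
computed as the spectral power fraction of the epoch periodogram
(visual-scoring language has no other computable reading), and
"high/low EMG" means above/below the per-recording median epoch EMG RMS
(an absolute threshold is configurable).  The median convention is
designed for recordings that mix states; on a constant-state recording
roughly half the epochs fall on either side of the median and the
inherit-previous rule then keeps the label stable.  A constant OBBB
recording (awake, high EMG, δ-rich) is the one case the cascade scores
only ~50% as WAKE — its low-EMG half satisfies the NREM rule; this is a
property of the scoring criteria themselves, not of the implementation.
Note the staging θ band (5–10 Hz) intentionally differs from the
analysis θ band (4–8 Hz); both exist as named bands.

### Cross-recurrence analysis

Signals are decimated (anti-aliased polyphase resampling) to an analysis
rate — 50 Hz for θ, 20 Hz for δ in the pipeline defaults — zero-phase
band-passed (4th-order Butterworth, forward–backward), z-scored, and
delay-embedded.  The delay is the first local minimum of the sample
autocorrelation (first zero crossing as fallback, then the lag cap with
a warning); the dimension is the smallest m with a false-nearest-
neighbour fraction below 1% (Kennel criteria, rtol = 10, atol = 2σ),
capped at m_max = 8 — band-limited stochastic signals typically hit the
cap, which is expected and harmless.  The threshold ε is chosen per
window as the distance quantile achieving a 10% recurrence rate, making
indices comparable across states of different amplitude; a fixed ε is
available.  Theiler exclusion is 0 (two different signals need no
autocorrelation guard) and l_min = 2.  Indices are computed on 30-s (θ)
/ 60-s (δ) windows and averaged over at most 4 evenly spaced windows per
recording — window counts chosen to keep distance matrices ≈1500×1500.
MDL is reported in samples at the analysis rate; its absolute value
depends on that rate and the windowing, so only orderings across states
are comparable between analyses.
RR, DET, L and ENTR follow the standard recurrence-quantification
definitions and stand in for indices whose exact definitions are not
publicly available.

### Wavelet patterns

Complex Morlet (ω₀ = 6) CWT on the 50-Hz decimated lead, 40 log-spaced
voices over 2–16 Hz in the pipeline (0.05–30 Hz by default in the
library).  The skeleton links per-column power maxima across time
(±1 frequency bin).  Event detection uses hysteresis: the event *edges*
sit at the main floor — half the median ridge power inside the band,
re-anchored after a first pass to ridge power *inside* detected events
so quiet gaps cannot drag the floor down — while an event only *breaks*
where smoothed ridge power falls below 0.3× the floor.  A half-plateau
threshold crosses the Gaussian-smeared edge of a rectangular burst at
its true boundary, giving duration estimates without systematic edge
bias; the hysteresis keeps within-event interference dips from splitting
one oscillatory event into several.  Ridge power is smoothed over one
band-center cycle before thresholding; events interrupted less than one
cycle are merged; events shorter than two cycles are discarded (the
standard "oscillatory event" criterion).  All floors are relative to the
data, so durations are invariant to amplitude rescaling.  For bursts
whose carrier mixes a coherent tone with in-band noise the detector
shows a known residual bias of roughly −15…+10% depending on duty
cycle; it cancels in group contrasts and vanishes for clean carriers.

### SNR features and the similarity network

SNR = windowed mean / windowed standard deviation (n−1), 60-s windows
stepped by 1 s — 120,000 samples per window at the 0.5-ms step —
computed in O(n) by cumulative sums.  Ninety consecutive SNR values
(1.5 min) form one network input fragment; evaluation fragments are
non-overlapping so per-network Cs values are independent, while training
may use a denser stride (default 30).  The network is an MLP with four
sigmoid hidden layers of 500, 50, 500, 50 units, linear input/output,
output clamped to [0, 1] at inference.  It stands on
scikit-learn's `MLPRegressor` (squared-error loss, Adam, ≤400 epochs,
plateau stopping, seed-deterministic) with input standardization fit on
the training fragments; targets are 1 for the positive (OBBB) class and
0 for the negative (wake baseline) class.  Deep sigmoid stacks
occasionally collapse onto the constant-output solution (vanishing
gradients); training therefore verifies the fit against its own
training classes and restarts from a different deterministic
initialization (up to 3 restarts) when training accuracy stays below
0.9 — a check that uses no evaluation data.  In the leave-one-subject-in
protocol a detector is trained per subject and evaluated on all other
subjects, per state, over both EEG leads; `Cs` is the fraction of
responses above 0.5.  The similar/dissimilar count *ratio* is also
exposed (`cs_literal_ratio`): that alternative form can exceed 1 and so
cannot be "the part of data recognized as similar"; the pipeline reports
the fraction, and the distinction is kept explicit rather than hidden.

### Surrogates and group statistics

AAFT surrogates: rank-remap onto a Gaussian, Fourier phase
randomization (DC phase kept, Nyquist sign-randomized), rank-remap back
onto the original samples — the surrogate is a permutation of the data,
so the amplitude distribution is preserved exactly and the periodogram
approximately.  Optional IAAFT refinement iterations are available
behind a flag; the default is the single-pass original scheme.
One-sided p = (1 + #{surrogate ≥ observed})/(n_surr + 1), so p is never
0, and p ≤ α is decidable with the minimal 19-surrogate design.  The
test assumes stationary inputs.  Group contrasts use the two-sided
Mann–Whitney–Wilcoxon test (exact for groups ≤ 8 without ties,
normal approximation with tie correction otherwise); summaries are
mean ± SEM.  No multiple-testing correction is applied — contrasts are
reported at the per-test level by design; the global-null pipeline test
checks that this level is honest.

## The synthetic cohort

Each recording is a sum of exactly variance-normalized, band-limited
random-phase multisine components (equal in-band Fourier amplitudes,
random phases — Gaussian-like by the CLT, with a *deterministic*
spectral envelope so injected band powers are reproduced with very small
between-subject spread, mirroring the small SEMs of state-averaged band
powers in chronically implanted animals):

| component  | band (Hz)   | cross-lead structure                      |
|------------|-------------|-------------------------------------------|
| infra-slow | 0.01–0.05   | shared                                     |
| slow       | 0.08–0.12   | shared (the 0.1-Hz oscillation)            |
| delta      | 0.5–4       | correlated, coefficient `delta_coherence`  |
| theta      | 4–8         | burst-gated coherent pair, coherence c     |
| alpha      | 8–12        | independent                                |
| background | 2–3.5 & 8.5–500 | independent 1/f                        |

The θ pair is x = √c·s + √(1−c)·n₁, y = √c·s + √(1−c)·n₂ with equal
in-band power, giving magnitude coherence exactly c in-band; the shared
component s is a per-burst tone at a random in-band frequency (stable
wavelet ridges), the incoherent parts are in-band noise, and a common
on/off envelope gates both leads.  Burst durations are
d_min + Exponential(mean − d_min) with d_min = 0.4 s: the mean is the
profile's exactly, while no "oscillatory pattern" is shorter than two θ
cycles — a plain exponential would put a quarter of its mass below any
two-cycle detection criterion and make the injected mean unrecoverable
by construction.  Gaps are likewise shifted-exponential (min 0.5 s).
The background spectrum leaves deliberate holes below 2 Hz and across
3.5–8.5 Hz so that the θ coherence and the 0.1–0.5 Hz power ratios are
recoverable without bias from overlapping independent noise; most
background power sits above 8.5 Hz (desynchronized activity), which is
also what the staging rules key on.

The three state profiles encode the reference state contrasts: θ coherence 0.68 /
0.52 / 0.53 (wake / sleep / OBBB), slow-oscillation power boosts
4.91 : 3.84 : 11.85 (normalized to sleep), burst mean durations 1.47 /
1.18 / 1.16 s.  Parameters the contrasts require but no source states
were fixed once on physiological grounds: wake θ is near-continuous
(duty 0.60) while sleep/OBBB θ is fragmented (duty 0.35) — continuous θ
during active waking versus fragmented θ in NREM is textbook rodent
electrophysiology; NREM sleep carries strongly bilaterally synchronized
δ (`delta_coherence` 0.7, OBBB 0.9, wake 0.2), reflecting the global
character of slow-wave activity; and infra-slow power is elevated in
sleep (0.03) and OBBB (0.04) versus wake (0.005), consistent with
infra-slow oscillations coupling to sleep slow waves and vasomotor/
barrier dynamics.  These choices are what make the MDL and Cs orderings
*emergent* properties of the states rather than directly injected
quantities: MDL(θ) tracks the fragmentation structure of the θ rhythm,
MDL(δ) the share of bilaterally shared slow activity in the δ band, and
Cs the infra-slow/δ content visible to the windowed-mean part of the
SNR.  An EMG channel of white noise at the profile's RMS tone and
per-epoch stage labels complete each recording.

What the generator does **not** emulate: 1/f background inside the
protected bands, movement and electrode artifacts, state transitions
within a recording (profiles are stationary; mixed recordings are built
by concatenation), volume-conduction crosstalk, and any biophysical
neural-mass dynamics.  Passing tests therefore demonstrate that the
estimators recover known structure of this class — not that real rat EEG
contains that structure.

## Numerical and design choices

- Sampling interval fixed at 0.0005 s (2 kHz), configurable.
- FFT length equals the segment length (no zero padding): grid spacing
  0.01 Hz for 100-s windows, making the Daniell bandwidths 3 and 13 bins.
- Per-subject seeds derive from the master seed via numpy's
  `SeedSequence([master, group, subject])` — documented integer mixing,
  stable across platforms.
- Degenerate inputs: constant signals raise a degenerate-input error in
  autocorrelation, surrogate and SNR computations (the zero-variance
  window is named); an all-zero recurrence matrix yields RR = 0 and
  MDL = DET = L = ENTR = 0 by convention.
- The pipeline analyzes both leads where the measure is per-lead
  (spectra use lead 1, as left/right spectra are near-identical by
  construction; SNR fragments pool both leads), and the lead pair for
  coherence and CRA.

## Problem sizes

Default study conditions: 3 states × 7 subjects × 600-s recordings at
2 kHz.  The acceptance suite runs 5 replicate cohorts through the full
pipeline (~1.5 min each on one CPU) and requires every state ordering to
be recovered at p < 0.05 in ≥ 90% of replicates; per-method guarantees
run at reduced sizes (e.g. 500 null runs for surrogate calibration,
100 random 30×30 matrices against the brute-force scanner, 800-s records
for ≥ 200-burst duration recovery).

## Known limitations

- The staging rules cannot represent a constant-state OBBB recording
  (see above); staging accuracy is defined against mixed recordings.
- Pattern-duration estimates carry a duty-cycle-dependent bias of up to
  ~15% for noisy carriers; orderings are unaffected.
- The Cs magnitudes depend on the detector's generalization across
  subjects and are not calibrated to any external scale; only contrasts
  between states are meaningful.
- The surrogate test assumes stationarity; applying it to integrated
  (random-walk-like) signals inflates the false-positive rate.
- EDF I/O quantizes to 16 bits with per-channel auto-scaled physical
  ranges; CSV round trips are exact.
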