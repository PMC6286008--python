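# Methods

## Signal model

The generator emulates single-channel rheoencephalographic (REG)
bioimpedance at 250 Hz. Each beat is an asymmetric pulse: a half-cosine
anacrotic rise over `rise_fraction` of the beat (default 0.21, matching
rise times of ~50–60 samples for ~1 s beats) followed by an
exponential-shaped diastolic decay (rate constant 1.5) that returns to the
beat minimum exactly at the beat boundary. Each beat's template is
normalised to [0, 1] before scaling, so its max−min equals the drawn pulse
range exactly; this is what makes amplitude-recovery tests exact rather
than approximate. On top of the pulse train sit a slow sinusoidal drift
(default 0.005 Ω at 0.05 Hz, below the analysis band) and white sensor
noise.

Two levels of variability are kept separate:

| parameter | unit | default | role |
|---|---|---|---|
| `period_mean` | s | 0.99 | mean pulse period |
| `period_sd` | s | 0.12 | between-segment spread of the period |
| `period_jitter_sd` | s | 0.02 | i.i.d. beat-to-beat period jitter |
| `pulse_range_mean` | Ω | 0.092 apnea / 0.099 baseline | mean per-beat amplitude range |
| `pulse_range_sd` | Ω | 0.03 | between-segment spread of the range |
| `pulse_range_jitter_sd` | Ω | 0.003 | i.i.d. beat-to-beat range jitter |
| `regime_modulation` | – | 0.35 | apnea irregularity strength |
| `noise_sd` | Ω | 0.002 | white noise floor |

`generate_dataset` draws one period and one range per segment from the
between-segment distributions, then synthesises the segment with the
beat-level jitters. The defaults correspond to the emulated study protocol:
29 apnea + 24 baseline segments of 16 s.

### The apnea mechanism

The apnea regime differs from baseline in two coupled ways, both scaled by
`regime_modulation` (m):

1. a stationary AR(1) modulation (coefficient 0.9) of beat amplitudes,
   multiplicative with relative strength m — slow, correlated swings in
   pulse volume such as breath holding produces;
2. a noise-floor amplification, `noise_sd × (1 + 2m)` — extra sample-level
   microvariability.

The second component is the one that carries the low-lag signal. SDratio at
lag τ is ≈ √((1−ρ(τ))/(1+ρ(τ))), a function of the autocorrelation at that
lag, and beat-scale modulation only adds *low*-frequency power, which
raises ρ at small lags rather than lowering it. Only broadband
microvariability lowers ρ(τ≤5) and therefore raises SDratio, R-decay and
CCM where the real study found the groups separated. A period-coupled
modulation was tried and rejected: it creates a second, reversed-direction
group difference at lags near a quarter period, which the study's
significance-versus-lag profile does not show.

The default m = 0.35 is calibrated so that separation is moderate rather
than trivial: the best leave-one-out model clears AUC > 0.8 and 80%
accuracy at a small lag, but no model approaches perfection, and the
significance of SDratio/R dies out at large lags.

### What the generator does not emulate

Electrode physics, the 50 kHz carrier and its demodulation, respiration
and motion artifact morphology (only a crude amplitude-burst injector is
provided for testing the artifact screen), dicrotic notches, and any
subject-level structure (segments are exchangeable; there is no
within-volunteer correlation). Passing tests therefore demonstrate that the
*pipeline* recovers what the generator encodes, not that real REG behaves
this way.

## Preprocessing

Band limiting is a cascade of a 4th-order Chebyshev type II high-pass with
0.1 Hz stopband edge and an 8th-order Chebyshev type II low-pass with
20 Hz stopband edge, both with 40 dB stopband attenuation and applied
forward-backward (zero phase) so pulse landmark timing is unskewed.
Chebyshev II has an equiripple stopband rather than a DC zero, so a
constant input is attenuated to the 80 dB zero-phase floor, not to machine
zero. Records shorter than three settling lengths of the cascade (settling
= impulse-response decay below 1% of peak, ≈ 2.4 s at 250 Hz) are
rejected.

The visual artifact screening of the original protocol is replaced by an
automatic screen computed with median statistics over the whole record (so
a localized artifact cannot inflate its own thresholds): a 16-s window is
rejected if any sample deviates from the record median by more than 8
robust (MAD-based) standard deviations, or if any 1-s stretch spans more
than 3× the record's median per-second range. The 8σ bound is deliberately
loose: an asymmetric pulse wave spends most of each beat near its minimum,
which places clean systolic peaks 5–6 robust SDs from the median.

## Pulse geometry

Minima and maxima are found by local-extremum search with a 0.4 s minimum
spacing (150 bpm ceiling) and a prominence floor of 25% of the robust
amplitude span (2.5th–97.5th percentile), which keeps noise wiggles on the
slow diastolic decay from registering as beats; alternation is enforced by
keeping the most extreme candidate between consecutive opposite landmarks.
Ten per-beat features (amplitudes, spacings, rise slope, area, forward
differences) are summarised per segment by the median. Durations are in
samples, derivatives in Ω/sample and the area in Ω·samples (trapezoidal,
beat minimum subtracted) — conventions chosen so the magnitudes match
classical REG reports (areas of order 10 for 0.09 Ω, ~1 s pulses).

## Poincaré descriptors

All sample statistics use the n−1 denominator. R is the plain Pearson
correlation of (x, y), each window with its own mean and variance; the
difference from sharing one global mean is O(τ/N). CCM uses the standard
geometric triangle area |det|/2 and divides by (number of triplets) ×
(π·SD1·SD2); collinear triplets contribute zero, and the measure is
invariant to affine amplitude transforms. Degenerate plots (zero variance
along a needed axis) yield missing values in sweeps, with a logged warning,
instead of aborting.

## Lag-selection criteria

- Dominant period: lag of the highest autocorrelation peak within
  0.33–2.0 s (30–180 bpm); the peak must be a local maximum with ρ ≥ 0.1,
  otherwise there is no period (white noise fails this, as it should).
- ACF: biased (divide-by-n) normalisation, which keeps |ρ| ≤ 1. The
  second-derivative sign-change and first-local-minimum scans start at lag
  2 because both otherwise involve ρ(0), which carries the white-noise
  variance spike and triggers spurious detections at lag 1 on any noisy
  signal.
- AMIF: plug-in mutual information from a 16×16 equal-width joint
  histogram (nats). The binned AMIF of a near-deterministic signal is
  jagged, so the curve is smoothed with a centred 5-point moving average
  before taking the first strict local minimum. Even so, for a pure
  sinusoid the estimator's first minimum sits between T/8 and T/4 rather
  than exactly at the quarter period — fine structure of the quantised
  joint distribution, not sampling noise — and the tests assert that
  verified band.
- CCM inflection: the CCM-versus-τ curve is smoothed (5-point moving
  average), differentiated centrally, and the knee is the first lag where
  the slope rises above 5% of the initial (first-three-lags) slope,
  corrected by half the smoothing window for the smear the average
  introduces. A curve that never flattens, or never falls, has no knee.

## Group statistics

Two-sample comparisons are normality-gated: Lilliefors-corrected
Kolmogorov–Smirnov on each group at α = 0.05; Welch's t-test if both pass,
two-sided Mann–Whitney U otherwise. Significance is flagged at 0.05 and at
the Bonferroni-corrected fixed threshold 0.025 (two feature families), not
divided by the number of lags. Single-feature discrimination uses the
rank-formulation AUC oriented to ≥ 0.5 with the direction recorded, and
sensitivity/specificity/accuracy at the Youden-optimal threshold, apnea
positive.

## Classification

Relief weights use min-max scaled features and nearest hit/miss by
Euclidean distance. The admissible input combinations at each lag are the
subsets of {SDratio, R, CCM} that do not contain both SDratio and R (the
two are near-duplicates, correlation ≈ −0.997 pooled). Hyperparameters,
none of which are tuned per dataset: logistic regression unpenalised;
Gaussian naive Bayes; linear SVM with C = 1 on per-fold standardized
inputs (C = 1 is only meaningful on a fixed scale); CART with Gini
impurity and minimum leaf size 3.

Validation is leave-one-out. Accuracy thresholds probabilities at 0.5 and
decision values at 0. For AUC, pooled raw LOO scores are pessimistically
biased — the held-out sample's class is underrepresented in its training
fold, shifting every score against the true label (measured null AUC
0.29–0.46 by classifier) — so each held-out score is centred by the
training fold's mean self-predicted score before pooling, which restores
chance level (0.46–0.52) under label permutation.

## Problem sizes and determinism

The test suite and the acceptance script work at the protocol's own scale:
53 segments × 16 s × 250 Hz, lags 1–70, and 50 segments for parameter
recovery; classifier searches in tests cover lags 1–5. Every stochastic
component draws from an explicit seed; identical configuration and seed
give bitwise-identical signals.

## Known limitations

- The generator's effect mechanism is one of many that produce the
  observed descriptor ordering; nothing here validates it physiologically.
- The artifact screen is a stand-in for expert visual inspection and is
  only as good as its two thresholds.
- Feature-level accuracy shares the Youden threshold with
  sensitivity/specificity; other operating-point conventions would shift
  it.
- The AMIF estimator's minima are binning-dependent for strongly periodic,
  nearly noise-free signals.
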