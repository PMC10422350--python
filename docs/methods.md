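# Methods

This note documents the models, defaults, and numerical choices behind
`lungsig`, and what the synthetic validation does and does not establish.

## Signal model and simulator

The simulator (`lungsig.simulate`) emulates a chest-worn two-channel sensor
during metronome-paced breathing: 4 s cycles (2 s inhale, 2 s exhale) at
4000 Hz per channel, in arbitrary ADC-like amplitude units (the analysis uses
only relative quantities, so no absolute calibration is attempted).

**Sound channel.** Inhalation flow noise is modeled as white noise bandpass
filtered to 150–1000 Hz, gated over the inhale half by a Hann window, with
amplitude `sound_burst_gain(tidal_volume)`; the default gain map is linear
with amplitude 1.0 at 1000 mL, the simplest monotone choice. A slow
chest-movement drift (a half-sine per inhale, amplitude 0.5 x TV/1000)
populates the sub-2 Hz band. A cough replaces the breath with a ~0.5 s
broadband (unfiltered white) transient at 3x the deep-breath gain riding on a
deepened drift excursion; cough cycles carry a nominal 1200 mL tidal volume
(the protocol specifies only "over 1000 mL"). Per-cycle noise realizations
are drawn in a fixed order regardless of configuration, so recordings that
differ only in tidal volume share noise and scale exactly.

**ECG channel.** Beats are PQRST-shaped sums of five Gaussian bumps at a
default 75 bpm (≥ one R peak per 2 s half-cycle down to 30 bpm). Respiratory
sinus arrhythmia appears as amplitude modulation: beats whose R peak falls in
an inhale half are scaled by exactly `1 - rsa_modulation_depth`. The depth is
a free parameter with default 0.3; the protocol helper assigns
`0.3 x TV/1000` per condition so that deeper breathing modulates the ECG more
strongly, which is the qualitative behavior the fusion stage relies on for
its second channel. Optional white Gaussian noise (`noise_sd`) is added per
channel.

**What the simulator does not emulate:** real lung-sound spectra (wheezes,
crackles), heart-rate variability and RR-interval-based respiration coupling,
electrode motion artifacts, sensor contact variation, or inter-subject
variability. Passing tests therefore demonstrate that the pipeline recovers
the structure it assumes — monotone sound energy in tidal volume, phase-locked
ECG amplitude modulation — not that it would classify real patients.

## Conditioning

Band splits are 4th-order Butterworth filters applied forward-backward
(`sosfiltfilt`), giving zero phase so envelopes stay aligned with cycle
annotations, with presets `sound_low` (<2 Hz), `sound_high` (>150 Hz),
`ecg_low` (<150 Hz), `ecg_high` (>150 Hz). The upper edge of the sound high
band is the Nyquist frequency. Signals shorter than the filter warm-up are
rejected rather than padded.

The envelope is the population variance (divide by n; the constant factor is
irrelevant downstream but fixed and tested) over a sliding 1000-sample
(250 ms) window, default hop 1 sample. It is computed from centered
cumulative sums accumulated in extended precision, which keeps the
`E[x^2] - E[x]^2` cancellation error orders of magnitude below even
near-constant windows' variances (verified against a naive per-window loop at
1e-10 relative).

## Per-cycle AUC features

Cycle segmentation comes from simulator annotations or a fixed 4 s grid (the
protocol is metronome paced); no peak-detection segmentation is implemented.
Within a cycle, only envelope windows lying entirely inside it are used —
trimming at least half a variance window at each edge — and the order-7 fit
runs on time normalized to [-1, 1] (absolute-time design matrices of order 7
are ill conditioned; the order is never silently reduced).

The per-cycle AUC integrates the fitted polynomial analytically, clipping
negative excursions to zero by splitting the domain at the fit's real roots
(an order-7 fit of a nonnegative envelope can undershoot). The cumulative
series accumulates exact per-interval integrals on an `n_points` grid
(default 40, matching the fusion frame size), so it is nondecreasing by
construction and its differences telescope to the total. A raw-envelope
trapezoid AUC is available as an option (`auc_from="envelope"`); the analytic
fit-based AUC is the default and the quantity used throughout.

## Signature-matrix fusion

Frames of 40 cumulative-AUC points per cycle (100 frames/s of raw 4 kHz
signal) are zoned per channel into lower/middle/upper by two thresholds,
half-open and lower-inclusive (`value == t1` falls in zone 2; the convention
is arbitrary but fixed and tested). The 3x3 matrix counts joint (ECG zone i,
sound zone j) frequencies over the frame; freshly built matrices sum to
exactly 1. The bundled reference matrices sum to ≈ 0.9895 — consistent with
one frame in 95 left uncounted under their (unknown) construction convention
— and are therefore validated under a "sum ≤ 1" contract and stored verbatim.

**Zone thresholds.** No standard preset exists, so the default is data
driven: per channel, each template condition's mean final cumulative AUC
defines a level; levels closer than 1% of the channel's spread merge (deep
breathing and coughing coincide on the ECG channel), and the two thresholds
sit midway between the three lowest distinct levels, with conditions above
the third saturating the upper zone. This anchors the zones to the
lower/middle/upper breathing intensities the map is meant to express.
Pooled-value tertiles were considered and are retained as an option
(`zone_boundaries="tertiles"`) and as the automatic fallback when fewer than
three distinct levels exist; as a default they are fragile, because a tertile
of the pooled distribution tends to land on the densest cluster — an adjacent
condition's plateau — making zone membership flip on tiny envelope
fluctuations. Explicit thresholds can always be supplied, and whichever rule
is used, the thresholds are persisted with the template library so targets
are zoned identically.

Templates are element-wise means of per-cycle training matrices.
Classification minimizes the SSE over the library; ties break
deterministically by insertion order and are flagged in the result, and the
margin to the second-best template is reported.

## Group statistics

The two-group one-way ANOVA uses the explicit mean-square formulas with df
`(1, n_a + n_b - 2)`; group sizes always come from the data. Degenerate
inputs are handled explicitly: identical constant groups are an error;
separated constant groups report F = inf, p = 0 with a `degenerate` flag.
Box-plot summaries use linear-interpolation quartiles (the common default)
with outliers beyond 1.5 x IQR. Critical values are upper-alpha F quantiles;
at alpha = 0.05 they are 5.318 for df (1, 8) (two groups of five cycles) and
4.965 for df (1, 10) (two groups of six).

## Validation problem sizes

The synthetic study used by the tests and the acceptance script runs 10
cycles (5 template + 5 held-out) for each of four conditions — 1000 / 750 /
500 mL and coughing — at zero added noise; within-condition variability comes
from the per-cycle burst noise realizations. Monte-Carlo null calibration of
the F test uses 10^4 replicates of two five-sample standard-normal groups.
These sizes mirror the five-breathing-cycle groups of the underlying protocol
while keeping the full suite fast.

## Known limitations

- The classifier is template matching on 3x3 probability maps; it has no
  rejection option and will assign the nearest template to any input.
- Tidal volume is tracked only as a relative AUC proxy; no calibration to mL
  is provided or claimed.
- Cycle boundaries must be known (paced protocol); free breathing would
  require a segmentation front end.
- The ECG channel separates conditions only insofar as respiratory sinus
  arrhythmia depth varies with breathing depth; subjects with weak RSA would
  leave the sound channel to discriminate alone.
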