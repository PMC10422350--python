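# lungsig

Breathing-pattern analysis for chest-worn multimodal recordings that capture
lung sounds and an ECG on the same 4 kHz time base. The package targets the
monitoring problem faced by wearable respiratory devices: from a single chest
patch, estimate a per-breath tidal-volume proxy, distinguish deep / moderate /
shallow breathing, and flag coughing — without a spirometer.

## Method

For each channel the pipeline computes, per metronome-paced breathing cycle
(4 s: 2 s inhale + 2 s exhale):

1. **Band split.** Zero-phase 4th-order Butterworth filters separate each
   channel into a low and a high band — sound below 2 Hz / above 150 Hz, ECG
   below / above 150 Hz. The sound high band carries inhalation flow noise;
   the ECG low band carries the beat complexes.
2. **Moving-variance envelope.** The filtered signal's energy envelope is the
   population variance over a sliding 250 ms window (1000 samples at 4 kHz).
3. **Polynomial AUC chain.** An order-7 least-squares polynomial is fitted to
   the envelope of each cycle on time normalized to [-1, 1]. The area under
   the fitted curve (negative excursions clipped to 0) is the per-cycle AUC
   `A_k`; its running integral is the cumulative AUC and the successive
   differences of that integral proxy lung volume during inhalation. `A_k`
   scales monotonically with tidal volume on the sound high band, and the
   ECG envelope is modulated through respiratory sinus arrhythmia (beat
   amplitudes drop during inhalation).
4. **Signature-matrix fusion.** Per cycle `k`, the sound (X) and ECG (Y)
   cumulative-AUC series are sampled at 40 points (100 frames/s of raw
   signal); each point falls into one of three zones per channel, and

   `sig_ij = P(X in zone j  and  Y in zone i)`

   yields a 3x3 probability map `SIG_k`. Condition templates are element-wise
   means of training-cycle matrices; a measured matrix is classified by the
   minimal sum of squared element differences
   `E_k = sum_ij (sig_ij^T - sig_ij^k)^2` over the template library.
5. **Group statistics.** Conditions are compared per channel by a two-group
   one-way ANOVA on per-cycle cumulative AUCs: `F = MS_between / MS_within`
   with df `(1, n_a + n_b - 2)`, reported against the upper-alpha critical
   value (5.318 for two groups of five cycles at alpha = 0.05).

A seedable simulator generates recordings with exactly the structure the
pipeline measures (tidal-volume-scaled inhale sound bursts, PQRST ECG with
respiratory amplitude modulation, broadband cough transients), so the whole
chain is testable without any recorded data. Bundled reference signature
matrices (two subjects, three conditions) serve as worked examples and
regression fixtures.

## Worked example

```python
from lungsig import run_template_study

study = run_template_study(seed=42, n_train=5, n_test=5)
print(f"held-out accuracy : {study.accuracy:.2f} ({study.n_test_cycles} cycles)")
for name, auc in study.mean_sound_auc.items():
    print(f"mean sound AUC {name:>7s}: {auc:8.3f}")
cmp = study.comparison_1000_vs_500
print(f"F(1000 vs 500 mL) = {cmp.f_value:.1f}  "
      f"critical = {cmp.f_critical:.3f}  p = {cmp.p_value:.2e}")
```

prints

```
held-out accuracy : 1.00 (20 cycles)
mean sound AUC  1000mL:    0.324
mean sound AUC   750mL:    0.181
mean sound AUC   500mL:    0.082
mean sound AUC   cough:    3.225
F(1000 vs 500 mL) = 834.1  critical = 5.318  p = 2.24e-09
```

The study simulates 10 cycles for each of four conditions (tidal volumes
1000 / 750 / 500 mL and coughing), learns one template per condition from the
first five cycles, and classifies the held-out cycles. Mean sound-channel AUC
(envelope units x s, arbitrary scale) orders cough > 1000 > 750 > 500 mL, and
the deep-vs-shallow F value far exceeds the critical value — the breathing
conditions are statistically separable from the sound channel alone.

The same stages are scriptable from the shell:

```sh
lungsig simulate --out deep.csv --experiment deep --cycles 5 --seed 1
lungsig features deep.csv --out deep.features.csv --condition deep
lungsig templates --series deep=deep.features.csv.series.json ... --out lib.json
lungsig fuse shallow.features.csv.series.json --templates lib.json --out report.json
lungsig stats --group deep=deep.features.csv --group shallow=shallow.features.csv --out stats.json
```

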