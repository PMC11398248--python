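# drivestress

Driver stress assessment from heart-rate variability and thermal facial
imaging.

In-vehicle driver monitoring systems estimate the psycho-physiological
activation ("arousal") of a driver from physiological signals. This package
implements the offline analysis chain of such a system for researchers
working with driving-protocol recordings:

- **Time-domain HRV.** Over each protocol epoch the RMSSD of the R-R
  interval series is computed,

  RMSSD = √( Σₙ₌₂..N (RRₙ − RRₙ₋₁)² / (N−1) )   [ms],

  together with the mean heart rate. Lower RMSSD reflects vagal withdrawal,
  i.e. stress.

- **Arousal index φ ∈ [0, 1].** A baseline epoch fixes RMSSD_B; during
  each later epoch the percent change Δrat = |RMSSD_B − RMSSD_C|·100/RMSSD_B
  is quantized onto 10 levels {0.1, …, 1.0} over the admissible range
  (Δmin, Δmax] = (10, 120], emitted every 5 s, with φ = 0 whenever RMSSD
  rises above baseline (relaxation). The per-epoch mean φ̂ summarises each
  phase.

- **Thermal ROI pipeline.** Consumer thermal cameras export color-mapped
  RGB frames plus per-frame cold/hot anchor temperatures. Per-pixel °C are
  restored by nearest-color indexing against the temperature bar and the
  affine map t = t_cold + (t_hot − t_cold)·index. Face and nose rectangular
  ROIs (pluggable detector) are scored by mean temperature; nose boxes
  starting above 80% or below 25% of the face height are rejected as
  mis-detections; ROI means are normalized by the whole-frame mean and
  averaged per epoch. Nasal-tip skin temperature drops under stress, so the
  normalized nose trace mirrors the HRV indices.

- **Protocols.** Builtin 45-min on-road protocol (Baseline, B1, C1, C2,
  C3, B2, Recovery; stress induced by a co-driver during C2) and 14-min
  simulator protocol (Baseline, BD, CD, VD, E, E+VD, Recovery; distraction
  tasks as stressors), plus YAML/JSON custom protocols.

- **Synthetic sessions.** A generator replaces the wearable sensor and the
  camera: R-R streams with controlled per-epoch RMSSD (one sample per
  40 ms; i.i.d. Gaussian noise with σ = target/√2 so the expected RMSSD
  equals the target) and colormap-encoded thermal frames with ground-truth
  ROI boxes and configurable detection dropouts.

## Worked example

Generate a synthetic 14-min simulator session and run the full pipeline:

```sh
drivestress simulate --protocol simulated --out demo --seed 7
drivestress report --rr demo/rr.csv --frames demo/frames \
    --protocol simulated --out-csv demo/report.csv
```

`demo/report.csv`:

```
epoch,mean_hr_bpm,rmssd_ms,n_samples,phi_hat,face_norm_avg,nose_norm_avg
Baseline,75.10,49.19,3000,0.00,1.3654,1.3268
BD,74.99,42.25,3000,0.10,1.3654,1.3266
CD,75.04,24.62,3000,0.40,1.3637,1.2673
VD,74.99,25.61,3000,0.40,1.3637,1.2676
E,74.99,24.53,3000,0.40,1.3638,1.2677
E+VD,74.99,25.51,3000,0.40,1.3637,1.2675
Recovery,75.03,48.65,3000,0.00,1.3655,1.3272
```

Each 2-min epoch holds 3000 R-R samples (one per 40 ms). The default
scenario imposes a 50% RMSSD drop in the stressor epochs (CD/VD/E/E+VD):
the pipeline recovers RMSSD ≈ 25 ms against the ≈ 49 ms baseline, a
percent change of ≈ 50 that quantizes to φ̂ = 0.4, while the normalized
nose temperature falls from ≈ 1.33 to ≈ 1.27 — the inverse RMSSD/φ̂
behavior and the stress-related nasal cooling the pipeline is built to
expose. Mild driving (BD, 15% drop) scores φ̂ = 0.1; baseline and recovery
score 0.

`drivestress arousal` and `drivestress thermal` run the HRV/arousal and
thermal stages separately; `drivestress simulate --no-thermal` writes an
R-R-only session.

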