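# Methods

## Signals and model

The package analyses one driving session at a time. A session is an
ordered, contiguous sequence of epochs (a *protocol*): a rest baseline,
driving phases with or without explicit stressors, and a recovery. Two
signals are scored against the protocol:

1. an R-R interval stream (ms) at a nominal 40-ms delivery tick, from
   which time-domain HRV is computed, and
2. a stream of color-mapped thermal frames (one per 5 s) with per-frame
   cold/hot anchor temperatures, from which facial skin temperatures are
   restored.

### RMSSD

For an epoch holding intervals RR₁…RR_N,

RMSSD = √( Σₙ₌₂..N (RRₙ − RRₙ₋₁)² / (N−1) ),

the root mean square of the N−1 successive differences. The divisor is the
number of differences, the standard time-domain HRV convention; a constant
series scores 0, and at least two intervals are required (fewer yields an
explicit missing value, never a zero). RMSSD is shift-invariant and
positively homogeneous; both are asserted as properties. The series is used
as delivered: no resampling, gap imputation or ectopic-beat correction
(R-peak detection is assumed to have happened upstream).

At the nominal tick, a phase of duration D ms holds N = ⌊D/40⌋ samples:
3000 for a 2-min phase, 7500 for a 5-min phase.

### Arousal quantizer

With RMSSD_B fixed from the baseline epoch and RMSSD_C from the current
window, Δ = RMSSD_B − RMSSD_C and Δrat = |Δ|·100/RMSSD_B. φ is:

- 0 if Δ ≤ 0 (RMSSD at or above baseline — relaxation direction);
- 0 if Δrat ≤ Δmin;
- 1 if Δrat ≥ Δmax (saturation at maximum activation);
- otherwise s·⌈(Δrat − Δmin)/w⌉ with bin width w = (Δmax − Δmin)·s.

Defaults s = 0.1, Δmin = 10, Δmax = 120 give 10 equal bins of width 11
percentage points over (10, 120] and the image {0.1, …, 1.0} — exactly 10
nonzero levels. The quantizer is non-decreasing in Δrat. Two boundary
choices were genuinely open and are fixed as follows: equality Δrat = Δmin
maps to 0 (the ceiling would force it anyway), and Δrat ≥ Δmax closes the
top bin at 1 rather than leaving it undefined.

The sign convention deserves a note: arousal is awarded only when the
current RMSSD lies *below* baseline. A drop in RMSSD means vagal
withdrawal and rising stress; a rise above baseline is relaxation and maps
to 0 regardless of magnitude.

### The φ trace

φ is emitted every `update_period` = 5 s inside non-baseline epochs.
RMSSD_C is computed over an expanding window from the start of the current
epoch — the window resets at epoch changes so each phase is judged on its
own physiology — with the first emission `warmup` = 30 s into the epoch;
shorter windows make the RMSSD estimate too noisy (relative sampling error
≈ 1/√(2n), about 2.6% at the 750 samples a 30-s warmup provides). A 2-min
epoch therefore yields 18 emissions (offsets 30, 35, …, 115 s). Epochs
shorter than the warmup emit nothing; their φ̂ is reported as 0 and the
epoch is flagged. φ̂ is the arithmetic mean of the emitted values per
epoch; the baseline epoch is reported as φ̂ = 0 by construction.

For the on-road protocol, whose 10-min rest phases begin with settling
artifacts, RMSSD_B (and the baseline/recovery summary rows) use only the
last 5 min of the rest recordings.

## Thermal pipeline

### Temperature restoration

Cameras of the class modelled here export an H×W×3 RGB frame rendered
through a temperature bar (colormap) plus the frame's coldest and hottest
temperatures and their pixel coordinates. Decoding is a two-step inverse:
each pixel is matched to the nearest colormap entry (Euclidean distance in
RGB; ties break toward the lower, colder index), the index is normalized
by L−1 to [0, 1], and

t = t_cold + (t_hot − t_cold) · index.

Normalizing by L−1 is required for the affine map to reach t_hot; the bar
is assumed linear in temperature. With an L-level bar the quantization
error is at most (t_hot − t_cold)/(L−1) per pixel, and the recorded
cold/hot anchor pixels decode to within one step of their anchors — both
asserted as round-trip properties.

### ROI scoring and validity

Face and nose are rectangular pixel boxes (0-based, origin top-left, y
down, half-open). Detection is behind a pluggable interface: the bundled
backend replays ground-truth boxes from a synthetic-session manifest, and
an adapter accepts any external detector object exposing
`detect(rgb) -> (face, nose)`. Detector failures produce missing ROIs,
never exceptions. A nose box whose top edge, relative to the face top,
lies below 25% or above 80% of the face height (strict inequalities) is
anatomically implausible and rejected; its quantities become missing.

Each ROI mean (arithmetic over the W·H pixels) is normalized by the
whole-frame mean temperature — a ratio, which cancels frame-wide
auto-ranging and ambient drift. Frames with a non-positive mean (the °C
convention breaks near zero) are marked missing rather than divided.
Per-epoch values are the means over frames with defined values; an epoch
with none is missing. Missingness always propagates explicitly — gaps in
the temperature curves are data, not zeros.

## Synthetic sessions

The generator defines the conditions every test runs under.

**R-R.** One sample per 40-ms tick. Within an epoch, RR = mean_rr + ε with
ε i.i.d. N(0, σ²) and σ = target_rmssd/√2; since E[(RRₙ−RRₙ₋₁)²] = 2σ²,
the expected RMSSD equals the target analytically. Defaults: mean_rr =
800 ms (75 bpm) and baseline RMSSD 50 ms, a typical healthy resting adult;
the default scenario drops stressor epochs to 50% of baseline RMSSD (a
strong activation of the kind stressful driving elicits) and plain driving
to 85%. i.i.d. noise is deliberate — only RMSSD needs to be controlled —
so the series has none of the autocorrelation, respiratory modulation or
ectopic beats of real HRV; tests passing on it validate the arithmetic of
the chain, not robustness to physiological artifact.

**Thermal.** One 60×80 frame per 5 s: a face rectangle at 34 °C with a
nose rectangle (top edge at 55% of the face height, inside the validity
band) at 33 °C over a 22 °C cabin background, plus N(0, 0.15²) °C pixel
noise. During stressor epochs the nose cools by 1.5 °C, emulating
stress-related nasal vasoconstriction. Anchors t_cold/t_hot are set per
frame to the rendered field's extrema, as an auto-ranging camera does, so
the decoder's frame-specific anchors are genuinely exercised. The default
bar is a 256-entry linear grayscale (unambiguous nearest-neighbor); an
iron-like palette is provided as an alternative. A configurable fraction
of frames carry no ground-truth boxes, standing in for detection failures.
No face geometry, head motion or radiometric calibration is modelled.

All generation is deterministic per seed, and written sessions (CSV, PNG,
JSON) are byte-identical across runs with equal seeds.

## Numerical and design choices

- Epoch intervals are half-open [start, start+duration): every in-range
  sample belongs to exactly one epoch; samples past the protocol end are
  discarded and counted.
- The arousal loop is protocol-driven — it iterates over all non-baseline
  epochs rather than a hard-coded phase count, so the same algorithm
  serves both builtin protocols and any custom one.
- Output formatting is fixed (ms/bpm/°C at 2 decimals, trace φ at 1,
  φ̂ at 2, normalized ratios at 4) so reports are byte-stable; φ̂ gets two
  decimals because it is a mean of quantized levels, and the ratios get
  four because their between-epoch differences sit in the third decimal.
- Problem sizes in the test-suite simulations (full 840-s sessions,
  100-replicate parameter-recovery sweeps) were chosen to keep the
  statistical checks sharp while the whole suite completes in about a
  minute.

## Limitations

- The synthetic RR noise model yields nearly unbiased RMSSD at the window
  sizes used; very short windows (< a few hundred samples) would make the
  expanding-window estimate noticeably noisy.
- The arousal/thermal fusion is co-reporting only: φ is computed from HRV
  alone, with thermal quantities reported alongside.
- Group-level statistics across subjects, live transport from devices, and
  R-peak detection are out of scope.
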