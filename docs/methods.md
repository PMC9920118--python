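# Methods

This note records the scientific and numerical choices behind the package:
what is modelled, which parameters matter, where the design was genuinely
open, and what the synthetic experiments do and do not demonstrate.

## Synthetic cardiorespiratory generator

The generator (`siggen`) renders the three mechanisms by which breathing
reaches a chest-worn recorder:

* **Beat timing (RSA).** Beats are laid down sequentially with interval
  `(60/HR)·(1 + rsa_depth·sin φ(t))`, where `φ` is the breathing phase
  (2π·∫f dt, supporting piecewise-constant frequency profiles). Default
  `rsa_depth = 0.1` — a mid-range adult modulation depth.
* **R-wave rendering.** Each beat is a Gaussian bump (σ = 12 ms) of
  amplitude `1 + rpa_depth·sin φ` (default `rpa_depth = 0.2`). Gaussian
  R-waves are sufficient for peak-based extraction; P/T waves add nothing
  to the surrogates used here and are not modelled.
* **Chest motion.** One accelerometer axis carries
  `adr_gain·sin φ` (default 0.05 g) plus white noise on all three axes
  (default 0.01 g). Optional band-limited (0.3–5 Hz) Hann-windowed
  noise bursts of 1–3 s emulate transient movement artefacts — the band
  overlaps the respiration band, as steps and posture sway do, so bursts
  genuinely contaminate the derived channels; bursts also leak into the
  ECG (electrode motion). Recordings carrying bursts are flagged
  so uncertainty-rejection experiments have labelled corruption.

Sampling rates default to 256 Hz (ECG, accelerometer) and 25.6 Hz
(reference respiration), the rates of a chest-worn exercise recorder.
Dataset draws are uniform in RR ∈ [10, 45] BrPM and HR ∈ [60, 150] bpm —
the range spanned by rest-to-exercise protocols. A single integer seed
makes every recording bit-reproducible.

**What the generator does not emulate:** inter-subject morphology
variability, baseline wander, electrode pop, apnoea/arrhythmia, sensor
drift, or correlated HR–RR dynamics. Passing tests therefore demonstrate
algorithmic correctness and end-to-end learnability of the mapping, not
clinical-grade accuracy on real wearables.

## Derived respiration channels

* Beat-domain series (R–R intervals at the later beat's time; R
  amplitudes at the peak time) are cubic-spline interpolated onto the
  4-Hz output grid (clamped at the ends) and mean-removed — standard
  practice for ECG-derived respiration, smooth at this rate.
* The accelerometer channel uses adaptive noise cancellation: the
  dominant-variance axis is decimated to an 8-Hz working rate, a
  brick-wall DFT band-pass (0.1–1 Hz) forms the reference, and a
  normalised-LMS filter (length 1 s, step 0.01) adapts to predict the
  axis from the reference. The adapted coefficients are then re-applied
  as a fixed FIR over the whole window (a second, non-adaptive pass), so
  the output is a true filtering of the band-limited reference, free of
  warm-up transients and coefficient-jitter sidebands. Decimating first
  keeps the band a comfortable fraction of Nyquist — a 0.1-Hz edge at
  256 Hz produces numerically ill-conditioned IIR sections. The DFT
  brick-wall is exact for the fixed 32-s windows processed here.
* R-peak detection band-passes 5–30 Hz, squares, smooths over 100 ms,
  thresholds at 20% of the 99th percentile with a 200-ms refractory
  period, then refines each candidate to the raw-ECG maximum within
  ±50 ms. Annotated peak locations, when present, bypass detection.
* Every channel and the reference are z-normalised per window; windows
  are non-overlapping, half-open `[start, start+32 s)`, 0-based.

## Breath counting and evaluation

Local maxima of the linearly detrended signal are candidate breaths
(plateau ties resolved to the earliest index). A peak survives if its
smaller peak-to-trough excursion exceeds `0.2 ×` the 75th percentile of
all candidate excursions — this fraction/percentile pair is a
conventional reading of amplitude-thresholded "advanced counting" and is
config-exposed, not asserted as anyone else's exact rule. Instantaneous
rates are `60·fs/Δpeak`; the average rate uses the first-to-last-peak
span. Fewer than two surviving peaks yields a flagged, NaN average rather
than an exception.

The distance transform (per-sample distance to the nearest breath peak)
is computed with the exact Euclidean distance transform; its minima are
the peak set, it is 1-Lipschitz, and the MAE between two transforms
scores breath-location agreement without a pairing rule. For
instantaneous-RR error we pair breaths by index over the overlapping
prefix of the predicted and reference breath lists and log count
mismatches — the simplest defensible pairing.

## Architecture

Teacher (`ned = 5`): encoder levels of strided conv (k=3, s=2) + batch
norm + leaky ReLU (0.2) + dropout + inception-residual block, filters
32→512; a stride-1 bottleneck conv to 1024 filters with its own
inception-residual block; five transposed-conv decoder levels (k=3, s=2)
mirroring the encoder; attention gates on every skip (gating vector =
the feature arriving from the level below; channel-matched skips are
linearly 2× upsampled before concatenation); a rate head of conv
(k=4, s=2) stages with filters 128→64→32→2, each with an
inception-residual block and a self-attention gate, ending in a unit
dense layer.

Inception-residual block on C channels: four parallel convolutions
(k = 15, 17, 19, 21) with C/8 filters each (BN + leaky ReLU), a 1×1
recombination conv back to C (BN), plus a 1×1-projected residual of the
block input; "same" padding throughout. Several placements and widths in
this family are not uniquely determined by the architecture's prose
description; the frozen defaults (branch fraction 1/8, recombination and
projection convs, attention-gate intermediate width equal to the skip's
channel count, head taper ending at 2 filters) were selected once by a
parameter-budget criterion — the variant whose total trainable count
lands closest to the reference sizes of ~24.8 M (teacher) and ~12.5 M
(student) — and are config-exposed (`ArchConfig`). The shipped defaults
give 24.97 M and 12.64 M, a 49.4% reduction.

Student (`ned = 3`): stride-1 convs with 2× average pooling per encoder
level (so the bottleneck still reaches a compact length-16 grid), linear
2× upsampling before each decoder conv, decoder tail 8→4 filters, a
128→32→4 head (strides 4, 2, 2), and the 1024-filter bottleneck
retained. The student is derived from the teacher by removing
inception-residual blocks; the shipped removal set (all encoder/decoder
level blocks and all head blocks, keeping the bottleneck block) is the
deterministic choice under the same parameter-budget criterion.

Transposed convolutions are realised as zero-stuffing followed by a
"same" convolution, so each stride-2 level doubles length exactly —
no off-by-one crops at any `ned`.

## Training

Adam; batch 128; 100 epochs; piecewise-constant learning rates
(1e-2 for epochs ≤ 20, then 1e-4 or 1e-3 depending on the dataset key);
seeded 80:20 window-wise split (subject-wise available behind a config
key). Loss reduction is *sum over elements, mean over batch* for both
heads — fixed here because it changes the learning-rate interpretation.
The rate target is standardised (train-set mean/SD) during optimisation
and the affine inverse is stored on the model and applied at inference;
without this the rate head, whose output starts near zero, spends most
of a short schedule walking to the 10–45 BrPM range through the linear
branch of the smooth-L1 loss.

Distillation runs in three strictly ordered phases: (1) teacher training;
(2) attention-transfer pre-training of the student — 20 epochs by default
(no pre-training length is canonical; config-exposed) at the post-drop
learning rate, matching activation-energy maps of every block shared by
teacher and student (encoder levels 1..3, bottleneck, decoder levels
1..3, head stages), teacher maps linearly interpolated to student
lengths; (3) fine-tuning on `α·L(gt) + (1−α)·L(teacher)` with α = 0.94
applied to both heads, the attention-transfer term dropped. Maps in
phase 2 are computed in inference mode (running statistics, no dropout)
on both sides, so an exact teacher copy is a fixed point of the phase;
a batch whose attention-transfer loss is at numerical zero is skipped
rather than stepped, because Adam rescales arbitrarily small gradients
to full-size steps. The teacher's parameters are never touched by either
student phase.

## Uncertainty

Predictive moments over T = 10 stochastic passes use the population
(1/T) second-moment form `τ⁻¹ + (1/T)Σf² − mean²`; the model-precision
term defaults to τ⁻¹ = 0 (pure between-pass variance) because no
defensible numerical value exists for it — it is config-exposed. The
scalar rejection score combines both heads, since whole windows are
rejected for both outputs, and each component is exposed separately.
The two variances live on different scales (the rate head's variance,
after de-standardisation, is in BrPM²; the signal head's in z-units²),
so a raw sum lets one head decide every rejection. Per-window summaries
therefore report the sum in the network's native output units (rate
variance divided by the stored standardisation scale²), and batched
inference standardises each component across the batch (z-score) before
summation — equal statistical voice per head — shifting the combined
score by its minimum so it remains non-negative; the quantile rule uses
only its ordering. Rejection is a top-fraction
quantile rule (default 3.7%) so the rejection rate is controlled
directly; whether the original procedure used a fixed variance threshold
or a fraction is not documented anywhere we could verify, and the
quantile form makes the rate reproducible.

## Scaled-down study conditions

The end-to-end acceptance study trains on 512 synthetic windows
(RR ∈ [10, 45] BrPM) at `width_scale = 1/8` (every channel count divided
by 8), batch 32, 30 teacher epochs, 20 attention-transfer epochs and 30
distillation epochs — sizes chosen so the whole study runs on a single
CPU in minutes while leaving the architecture's structure (depth,
attention, inception blocks, bottleneck ratio) intact. Under these
conditions the teacher reaches a held-out average-RR MAE below 2 BrPM
and the distilled student stays within 10% of the teacher's error. The uncertainty-rejection check evaluates the trained model on a fresh
set in which 5% of recordings carry heavy motion bursts (amplitude 2.0,
calibrated by a model-free distortion measure: at that amplitude the
accelerometer channel's relative waveform distortion is of order one and
the R-amplitude channel's about 0.4, while annotated beat locations keep
the interval channel clean). The
channel-recovery sweep draws HR ∈ [130, 180] bpm alongside
RR ∈ [6, 60] BrPM: beat-domain sampling must stay above twice the
breathing frequency for the RR-interval surrogate to carry the modulation
unaliased, which is exactly the high-RR/high-HR coupling of incremental
exercise.

## Numerical choices and degenerate inputs

* Attention-map normalisation guards with ε = 1e-8 inside the square
  root (identically on the tensor and constant paths) and warns once on
  near-zero maps.
* Batch norm: momentum 0.1, ε = 1e-5; running statistics are saved in
  checkpoints.
* Dropout uses inverted scaling and a caller-supplied seeded generator;
  with dropout disabled the MC pipeline reduces exactly to the
  deterministic pass.
* Peak-free or constant inputs return flagged empty results, not
  exceptions; too-short recordings yield empty window lists with a
  warning; an all-zero accelerometer yields an all-zero channel.
* Tie-break: plateau maxima resolve to the earliest index.

## Known limitations

* The NumPy implementation is single-threaded per operation and
  practical up to roughly 1/4 of the full architecture width for
  training; full-width models are built for structural checks,
  inference and parameter accounting.
* The synthetic generator's simplifications (above) mean reported errors
  say nothing about PPG-style sensors, severe motion, or pathological
  breathing.
* Instantaneous-RR error depends on the documented index-pairing rule;
  other pairings (e.g. nearest-peak matching) would give slightly
  different numbers.
* Subject-wise splitting is implemented but the synthetic "subjects" are
  independent draws, so it does not probe real between-subject
  generalisation.
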