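# Methods

This note documents the models and procedures `gibbonpam` implements, the
parameters that matter, what the synthetic fixtures do and do not emulate,
and the design decisions taken where the workflow left genuine choices open.

## Problem setting

A grid of autonomous recording units (ARUs) records continuously at 16–48
kHz / 16-bit PCM. The detection targets are female gibbon calls: loud,
tonal, frequency-modulated bouts confined to a species band — 0.5–1.6 kHz
for northern gray gibbons, 0.5–3.0 kHz for southern yellow-cheeked crested
gibbons. The workflow classifies fixed 12-s windows of audio as gibbon or
noise from band-limited spectrogram images.

## Synthetic soundscapes

Every stage is validated on generated data with known ground truth.

- **Call model.** A bout of 3–6 frequency-modulated sine notes, each 0.4–1.2 s
  with a raised-cosine amplitude envelope and sweep endpoints held 15% of the
  bandwidth inside the species band (rising sweeps for the gray profile, arcs
  for the crested). This is deliberately a caricature: it reproduces the
  properties the pipeline depends on — tonal energy confined to the band,
  note/gap temporal structure, known onset and duration — and nothing else.
  ≥ 90% of spectral power falls inside the band by construction.
- **Backgrounds.** Unit-RMS white or pink (1/f power) noise, synthesized in
  the frequency domain, zero-mean, fully seeded.
- **SNR definition.** The ratio (dB) of in-band RMS of the clean call to
  in-band RMS of the background over the call's support, measured through a
  zero-phase 4th-order Butterworth bandpass. 10 dB is the conventional
  boundary below which a call is graded low-quality, so fixtures plant calls
  at 10 dB.
- **Output.** The mixture is peak-normalized to −1 dBFS for safe 16-bit
  export; each placement becomes one row of a Raven-style selection table
  (begin/end s, band Hz, species label, quality grade).

What the fixtures do **not** emulate: reverberation, propagation loss and
spreading, overlapping biophony (insects, birds), diurnal noise cycles, ARU
gain and microphone transfer functions. Tests passing on fixtures therefore
demonstrate the correctness of the machinery (windowing, labeling, training,
thresholding, bookkeeping), not field-condition performance.

## Spectrogram images

STFT with a 512-sample Hann window and no overlap (the defaults of the
spectrogram tool conventionally used for this work); log magnitude expressed
relative to the segment maximum, clipped at −80 dB so digital silence renders
at the color floor; rows cropped to STFT bins whose centers lie inside the
species band; mapped through a fixed perceptually uniform colormap (viridis)
to 3 channels; bilinearly resized to 224 × 224. Per-channel mean/std
normalization uses the natural-image statistics conventional for pretrained
backbones, stored on `RenderSpec` rather than hard-coded. The exact dB range
and palette of the original plotting tool are not documented anywhere, so
pixel-level replication is explicitly out of scope; models are always
retrained against this renderer.

Resampling is polyphase with anti-aliasing by default; `antialias=False`
selects nearest-index decimation for pipelines that downsample without
filtering. Upsampling is rejected.

## Band-limited energy detector

The envelope is the per-frame sum of STFT power over the band, smoothed by a
0.25-s moving average. Events are maximal runs where the envelope strictly
exceeds `threshold_factor × quantile(envelope, threshold_quantile)` — by
default 4 × the median, i.e. 6 dB above a robust estimate of the file's noise
floor. Runs separated by less than `merge_gap_s` (default 1.0 s, roughly the
upper end of inter-note envelope gaps in female call bouts) are merged, and
events outside [1 s, 12 s] are discarded.

Two numerical choices deserve note. First, the threshold is anchored to a
*central* quantile times a factor rather than an upper-tail quantile: an
upper-tail quantile guarantees that a fixed fraction of every file exceeds
it, which manufactures false events on call-free recordings and, on
call-rich recordings, rides up into call energy and misses weaker notes. The
median is insensitive to calls as long as they are sparse, so the same
configuration achieves full recall on 10 dB fixtures and a zero false-event
rate on noise-only fixtures. Second, the strict inequality at the threshold
means a constant envelope (silence) yields no events. The quantile anchor
keeps the detector invariant to inter-ARU gain differences.

## Windowing and labeling

Recordings are cut into 12-s windows every 6 s ("12-s windows with 6-s
overlap" and "6-s hop" describe the same scheme for 12-s windows); trailing
partial windows are dropped because the classifier takes fixed-size images.
Two labeling rules are implemented, both with inclusive boundaries:

- **Containment (training prep):** a window is positive when it contains at
  least 80% of some annotated call (overlap / annotation duration ≥ 0.8);
  ties go to the most-contained annotation's species.
- **Start proximity (test prep):** a window is positive when its start falls
  within ±6 s of some annotated call's start; the nearest start wins.

Annotations graded low-quality (SNR < 10 dB or heavy overlap with other
sounds) are excluded from training by default. Splits are assigned by
recorder location, and `assemble_dataset` hard-fails if any source id
appears in two partitions. Class imbalance is preserved — no rebalancing —
because deployment conditions are imbalanced; the loss weights carry the
imbalance instead. Noise-clip thinning, when needed, is a seeded uniform
subsample.

## Augmentation

Three audio/image plans, all label-preserving and applied to training
partitions only:

- **noise_added:** one white and one pink copy per clip, mixed at an in-band
  SNR of 10 dB by default (the level itself is a free parameter; 10 dB
  matches the quality-grading boundary).
- **cropped:** two random crops per clip — uniformly chosen start and length
  (≥ 50% of the clip to avoid degenerate slivers), then peak-normalized to
  full scale.
- **duplicated:** five copies of each training image, normally combined with
  color jitter.

Color jitter scales brightness, contrast, and saturation by independent
factors drawn uniformly from [1 − s, 1 + s], s = 0.2 by default, clamped to
[0, 1]; hue is untouched. Jitter is applied on the fly from a seeded stream
(one draw per image presentation).

## Classifier and training recipe

Six backbone configurations are named for the CNN families whose motifs they
carry — `alexnet` (large-stride stem plus wide convolutions and a
fully-connected feature stage), `vgg16`/`vgg19` (stacked 3×3 convolutions,
two or three per stage), `resnet18`/`resnet50`/`resnet152` (residual blocks,
one, two, or three per stage). They are compact: a 224×224×3 image is
reduced by a strided stem, processed by two stages with max pooling, and
flattened to a wide feature vector (1568–3136 values, plus a 256-unit
fully-connected stage for the alexnet/vgg families). The wide, flattened
feature interface is deliberate: a classification head over thousands of
features moves far enough in a handful of optimizer steps for the short
schedules below to work, which a narrow pooled bottleneck does not.

`pretrained=True` (the default) starts the backbone from a fixed,
architecture-specific reference initialization, so every training run of a
given architecture begins from identical stock weights; no weights learned
on an external image corpus are shipped. `fine_tune=False` freezes every
backbone parameter (the optimizer skips them; a checksum over backbone
weights is bitwise-stable across training), leaving only the head trainable.

Training: Adam, batch size 32, one-cycle learning-rate schedule stepped per
batch — cosine ramp from max/25 up to the 0.001 maximum over the first 30% of
planned steps, cosine anneal down to max/10⁴. Binary models use
binary cross-entropy on a single logit with per-sample weights
(gibbon 0.9 / noise 0.1, so a misclassified gibbon contributes nine times
the gradient of an equally confident misclassified noise clip); multiclass
models use class-weighted cross-entropy over three logits (noise 0.02,
0.49 per gibbon class), normalized by the summed weights of the batch so the
loss is invariant to rescaling all weights. Early stopping monitors
validation loss with patience 2 and restores the best epoch's weights.
Inference converts the single logit by a sigmoid, or the three logits by a
softmax. Everything is seeded; identical seeds give identical histories.

## Deployment

A trained model slides over full windows of a recording, one window at a
time (peak memory independent of file length), and emits an event for every
(window, target class) whose confidence reaches the threshold (0.90 is the
conventional high-precision operating point). The noise class is never a
target. Adjacent positive windows are *not* merged into bouts — counts are
window-level — and review spectrograms can be exported per event. Recordings
at a different rate than the model expects are rejected rather than silently
resampled.

## Evaluation

Maximum F1 is evaluated at exactly the ten thresholds 0.1, 0.2, …, 1.0, with
F1 ties broken toward the lowest threshold; 0/0 ratios at extreme thresholds
are defined as 0 and flagged rather than raised, so sweeps never crash.
AUC-ROC uses the Mann–Whitney rank formulation with average ranks (ties
count one half), which is exactly testable against an all-pairs oracle and
invariant under strictly monotone score transforms; one-vs-all AUC applies
the binary statistic to each class's probability column, reporting NaN for a
class absent from the labels. Benchmarks run a grid of configuration cells
over replicate seeds and report per-metric mean ± SE (sample SD/√n); failed
cells are recorded, never dropped.

## Density mapping

Verified detections are standardized to calls per hour per ARU (count /
hours analyzed), then interpolated by inverse distance weighting with power
2; all points contribute (no search radius), a grid cell coincident with an
ARU takes its exact rate, and the interpolant is bounded by the data range
by construction. Default grid resolution is 1/50 of the larger array extent.
Coordinates are assumed planar (projected meters). The package emits the
interpolated grid (CSV, optional heat map), not cartography.

## Problem sizes used by the test suite and acceptance script

Fixture checks use 60-s soundscapes with three planted 10 dB calls (20
soundscapes plus 20 noise-only files for detector recall/false-event rates),
200 twelve-second clips (tonal call vs. silence) for the learnability check
of the training recipe, 1000 randomized cases for labeling-rule oracle
equivalence, and 100 random score sets for the metric oracles. These sizes
were chosen so the full pipeline demonstrates its contracts end to end on a
single CPU in minutes.

## Known limitations

- The CNN engine is CPU-oriented and compact; it demonstrates and tests the
  full training recipe faithfully but is not a drop-in for large pretrained
  backbones, and no externally pretrained weights are available to it.
- Synthetic fixtures validate machinery, not field performance; real-data
  metrics require real annotated recordings.
- The energy detector assumes calls are sparse within a file (the median
  envelope estimates the noise floor); files dominated by in-band sound
  would raise the threshold and lower recall.
- Bout-level counting, acoustic localization, and occupancy modeling are out
  of scope.
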