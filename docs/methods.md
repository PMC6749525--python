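# Methods

## The problem and the method

Continuous human-activity recognition (HAR) from a wrist- or pocket-worn
tri-axial accelerometer re-classifies the wearer's activity every few
seconds, yet the activity itself changes on the scale of minutes. Running a
deep classifier on every analysis window therefore wastes almost all of its
compute. `actigate` implements a duty-cycled alternative: a change detector
with negligible cost watches a compact feature of the signal and the
convolutional classifier is invoked only when that feature jumps — otherwise
the previous prediction is carried over. A periodic forcing rule bounds how
long a stale prediction can survive.

The compact feature is the signal magnitude area (SMA) of a window of total
acceleration,

    SMA = (1/n) * Σ_i ( |x_i| + |y_i| + |z_i| ),

a standard proxy for physical-activity intensity. The gate fires when

    |SMA(t) − SMA(t−1)| ≥ T,

with `T = 0.2 m/s²` by default, and additionally forces a classification
every `N = 30` windows. Three conventions deserve note:

* **Absolute difference.** A one-sided rule (`SMA(t) − SMA(t−1) ≥ T`) would
  detect only intensity increases, yet transitions to lower-intensity
  activities (standing → sitting) must fire the gate too; the symmetric rule
  covers both directions.
* **Half-window SMA.** With 50 %-overlap windows the newest ⌈w/2⌉ samples of
  a window are exactly the stride of fresh data; computing SMA over that
  half means every raw sample contributes to exactly one SMA value and the
  detector reacts at stride resolution.
* **Boundary slack.** The `≥` comparison is implemented with a 1e-12
  absolute slack so that differences that are exactly at the threshold in
  decimal arithmetic fire despite binary floating-point representation
  (0.3 − 0.1 < 0.2 in float64).

## Signal path

Raw streams are grouped into contiguous runs (same subject, strictly
increasing timestamps, no gap above five nominal sampling periods — 250 ms
at the default 20 Hz). Each run is high-pass filtered as a whole —
third-order Butterworth, 0.3 Hz cutoff, applied forward-backward so the
body-acceleration channel stays phase-aligned with the total acceleration —
and only then segmented, so windows carry no filter edge transients.
Because the cutoff sits far below the sampling rate, the filter's start-up
transient decays over seconds; reflected-padding initial conditions leave a
visible residual, so the implementation removes the per-run mean (which the
high-pass maps to zero anyway) and uses Gustafsson initial-condition
fitting. This keeps the 5 Hz pass-band gain within 0.01 % and the DC
residual below 1e-3 m/s² over the central 80 % of a 30 s run.

Segmentation is a fixed-size overlapping sliding window: `w = 90` samples
(4.5 s at 20 Hz) with 50 % overlap, stride `round(w·(1−overlap)) = 45`.
Windows never straddle run boundaries; trailing samples that cannot fill a
window are dropped. A window spanning an activity transition is labelled
with the majority label of its samples (ties break alphabetically).

Each window is encoded as eight stacked rows — total x/y/z, body x/y/z, and
the two magnitudes — flattened row-major and refilled row-major into a
30 × 24 single-channel image (8 × 90 = 720 = 30 × 24). The mapping is an
exact bijection; the row order and reshape convention are frozen in the
encoder so models and encoders cannot drift apart. Pixel values are raw
m/s² by default; per-channel z-scoring with training-set statistics is
available behind a flag and the statistics travel with a trained model.

## Models

Five variants share the 30 × 24 × 1 input and six-way output:

| variant | convolutional stack | head | parameters |
|---|---|---|---|
| FCN-I | 16, 16, pool, 32, pool | conv 6 → GAP → softmax | 8,854 |
| FCN-II | 32, 32, pool, 64, pool | conv 6 → GAP → softmax | 31,526 |
| FCN-III | 32, 32, pool, 64, 64, pool | conv 6 → GAP → softmax | 68,454 |
| FCN-IV | 32, 32, 32, pool, 64, 64, pool | conv 6 → GAP → softmax | 77,702 |
| CNN | 32, 32, pool, 64, 64, pool | flatten → 256 → 256 → softmax(6) | 820,710 |

All convolutions are 3 × 3, 'same'-padded, biased, ReLU; pooling is 2 × 2
with floor on odd dimensions (30×24 → 15×12 → 7×6). Under exactly these
conventions the baseline CNN's closed-form count reproduces 820,710, which
is what pins the otherwise under-determined padding/pooling choices; the
FCN-III count follows as 68,454 from the same closed form (320 + 9,248 +
18,496 + 36,928 + 3,462). A global-average-pooling head replaces all dense
layers in the FCNs, which is why they need roughly a tenth of the CNN's
parameters: in the CNN, 688,384 of the 820,710 parameters sit in the first
dense layer alone.

Training uses Adam at a constant 1e-4, batch size 32, at most 400 epochs,
dropout 0.25 immediately before the final convolution (FCNs) or 0.5 after
each dense layer (CNN), a seeded 10 % validation split, and early stopping
on validation loss (patience 20 by default, best weights restored).
Cross-validation partitions at window level (shuffled, seeded, folds within
one sample of equal); windows of one subject can land in both train and
test folds, a known leakage caveat of window-level partitioning that is
documented rather than corrected. Class indices are alphabetical; argmax
ties break toward the lowest index.

The networks are built on the package's own NumPy engine (im2col
convolutions, BLAS matmuls, float32 activations): at these model sizes a
single CPU core trains FCN-III on 3,000 images in a few minutes, and the
engine's trainable-parameter totals are asserted against the closed-form
counter for every variant.

## The gated pipeline

Per window, in stream order: compute half-window SMA, gate, and either
classify (encode + forward pass) or carry the last classifier output. Gate
state is O(1) — previous SMA, last label, windows since last call — and
resets at recording-session boundaries (a fresh session has no history; its
first window always classifies). Evaluation scores each window against its
majority true label and reports the usage rate: the fraction of windows on
which the classifier actually ran. The threshold sweep classifies every
window once and replays the gate per threshold, which is exact because the
classifier is deterministic per window.

## The synthetic generator

Streams are sums of a constant gravity vector (orientation per activity), a
sinusoidal body component for dynamic activities (amplitude/frequency per
activity, phase drawn once per schedule entry), and white sensor noise,
sampled at 20 Hz with instantaneous activity switches. Two further terms
make the within-activity SMA structure realistic rather than sterile:

* **Effort modulation** (`amplitude_cv`): the body amplitude is multiplied
  by a slow random modulation (Gaussian knots every 1.5 s, linearly
  interpolated). The cv values are set so the consecutive-window SMA
  fluctuation of every dynamic activity sits at a common ~0.1 m/s² scale —
  half the gate threshold — so change-triggered calls occur within
  activities at a few percent of windows, while inter-activity jumps (≥ 1.6
  m/s² between adjacent levels) still dominate.
* **Postural fidgeting** (`fidget_rate`, `fidget_amplitude`): static
  postures receive brief Hann-windowed wiggles at Poisson times. Static SMA
  traces are then quiet but not dead flat, which matters for the gate:
  perfectly flat static segments would never fire a change call, so a stale
  prediction entering a static stretch could only be corrected by the
  periodic forcing rule.

Default SMA levels on the mean-window scale: sitting/standing ≈ 9.9 (the two
postures are deliberately indistinguishable by SMA — the periodic forcing
rule exists precisely because similar intensities can hide a change),
walking ≈ 11.5, upstairs ≈ 12.5, downstairs ≈ 13.5, jogging ≈ 15.1 m/s².
At T = 0.2, N = 30 the overall classifier usage on mixed streams lands at
roughly 12–18 %.

What the generator does **not** model: physiological gait shape (harmonics,
stride asymmetry), orientation drift, sensor bias or temperature effects,
gradual transitions, and between-subject variability beyond the seeded
randomness. Passing tests therefore demonstrate the pipeline's mechanics
and its qualitative energy/accuracy trade-off, not field performance on
real wearables.

## Reference evaluation protocol

The protocol module reproduces the study design end to end on synthetic
data: train FCN-III on 3,000 majority-labelled windows, then compare gated
and ungated recognition on a held-out ~30-minute continuous stream
(stride-unaligned dwell times of 90–170 s). Training streams mix three
families — half long-dwell (45–75 s entries, clean windows), a quarter
transition-dense with random activity order (10–22 s entries), and a
quarter transition-dense alternating dynamic/static. The transition-rich
families matter: the window the gate selects at a transition contains up to
50 % of the previous activity, and a classifier trained only on clean
windows labels such windows by their *average* intensity (a half-jogging,
half-standing window looks like walking) instead of by their majority
activity. With global average pooling the network can learn the majority
vote — per-region class evidence averaged over the image — but only if
training data contains such windows. Reference-model training caps at 40
epochs (patience 10), which the easy synthetic classes saturate well
before; the cap keeps the protocol inside a few CPU-minutes.

## Numerical and degenerate-input conventions

* Stride rounding `round(w(1−overlap))`, minimum 1; runs shorter than `w`
  yield no windows; runs shorter than 3(order+1)+1 samples refuse to filter.
* Malformed records in input files are skipped and counted, never fatal;
  files with zero well-formed records are an error.
* Gate: first window of every session classifies; the forcing counter
  counts windows since the last invocation of either kind; `T = 0` makes
  every window classify; `T = ∞` leaves only forced calls (usage → 1/N).
* Training refuses empty or single-class datasets; when fewer than six
  classes are present the class-score layer shrinks to match.
* Determinism: every stochastic step (stream synthesis, splits, shuffling,
  dropout, initialisation) derives from explicit integer seeds; equal seeds
  give equal streams bitwise and equal fold assignments.

## Known limitations

* The dataset-scale figures (65,067 windows; 14.44 % usage; the Table-level
  accuracies) require the WISDM v2.0 raw download and depend on how
  recording discontinuities are split into runs; the run convention here
  (split on subject change, activity change, or >250 ms gap) is one
  defensible choice among several.
* Energy and latency on embedded hardware are out of scope entirely.
* The FCN-III layer structure yields 68,454 parameters under any padding
  convention. Counts near 71,184 sometimes quoted for networks of this
  shape arise only from a deviating head (a 4×4 final convolution plus a
  dense softmax gives 64,992 + 6,150 + 42); this package follows the layer
  table above.
* Window-level cross-validation leaks subject identity across folds;
  subject-wise evaluation would read lower.
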