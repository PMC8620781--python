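# Methods

This note documents the models, parameters and design choices behind
`gaitmode`: the two-stage classification pipeline, the synthetic-sensor
signal model that stands in for human recordings, and the numerical
conventions the implementation commits to.

## Pipeline model

### Stage 1 — per-sample gait-event classification

The event detector is a feed-forward network (one hidden layer, 64 ReLU
units, softmax output, batch size 16) that maps the instantaneous
42-element vector of normalized IMU channels at one 2000 Hz sample to
one of {Other, FC, TO}. No temporal context enters the feature vector;
the classifier has to key on the local extrema and inflections that
coincide with foot contact and toe off.

Labeling an *instant* would yield one positive sample per event among
thousands of negatives, which is unlearnable; instead every sample
within ±10 ms of a true event instant carries that event's label
(overlaps resolved to the nearer event; an exact FC/TO distance tie is
rejected as degenerate). Two further measures address the residual
imbalance between Other and event samples:

- inverse-frequency class weights in the cross-entropy loss, and
- random subsampling of Other samples to 3× the event-sample count when
  assembling the training set (seeded; all event-band samples are kept).

The first and last 50 ms of each trial are excluded from training
labels and from inference (filter edge effects).

Per-sample predictions are discretized: each maximal run of consecutive
FC (or TO) predictions becomes one event at the run's *median* sample
time (robust to asymmetric runs), and a same-kind event within a 200 ms
refractory window of the previous one is discarded — well below the
shortest physiological stride, well above the label band width.
Predicted and true events are matched greedily nearest-in-time,
one-to-one, same-kind, within ±100 ms. Signed prediction times are
`(true − predicted)` in ms, positive = predicted early; quantiles use
linear interpolation and the std is the population form.

### Stage 2 — transition prediction by window voting

A transition label is the ordered pair *(mode of the current stance →
mode entered at the same leg's next foot contact)*. The closed
vocabulary has 19 classes in three families:

- walking: W→W, W→SA, W→RA, W→SD, W→RD, W→O, W→ST (ramp destinations
  collapse the incline: W→RA2 is labeled W→RA);
- ramp ascent: RA*k*→RA*k* and RA*k*→W for inclines k = 1, 2, 3
  (4°, 8°, 12°);
- ramp descent: the RD analogues.

Pairs outside the vocabulary (e.g. SA→W) are flagged and excluded from
training and scoring.

Within each stance, sliding windows of 100 ms advance by 12 ms while
the window end stays at or before TO, giving
`floor((duration − 100)/12) + 1` windows. Each window's feature is the
per-channel mean over the window of all 20 conditioned-EMG channels
followed by all 42 normalized IMU channels — 62 elements. The mean is
the minimal per-channel summary compatible with a 62-element vector;
other window statistics were deliberately not added.

One MLP per family (one hidden layer, 128 ReLU units, batch size 64)
classifies windows; the current mode — and hence the family — is known
controller state at inference time. A single pooled 19-class model is
available behind `PipelineConfig(single_model=True)`. The stance-level
decision is a plurality vote over window predictions; ties break by the
larger summed softmax probability of the tied labels, then by the lower
class index. Early prediction at offset *o* ms restricts the vote to
windows ending at least *o* ms before TO — a *cumulative* vote over all
evidence available by the cutoff, not just the window at the cutoff —
and returns the sentinel `"undecidable"` if no window qualifies.

At training time windows are anchored at foot-switch ground truth; at
inference they are anchored at the detected FC/TO, so stage-2 results
include stage-1 timing errors end to end.

### Training recipe

Both stages share one trainer: Adam (learning rate 1e-3, β₁ = 0.9,
β₂ = 0.999) on categorical cross-entropy, ReLU hidden activations,
softmax output, Glorot-uniform initialization, mini-batches reshuffled
each epoch. 10% of the training samples (stratified, seeded) are held
out as a validation split; training runs at most 100 epochs and stops
10 epochs after the best validation accuracy if no improvement follows,
restoring the best-epoch weights. The monitored metric is validation
accuracy by default (`monitor="loss"` is available). Everything is
driven by one integer seed; retraining with the same seed is bit-exact.
`grid_search` enumerates candidate configurations, compares best
validation accuracy, and breaks ties toward fewer parameters.

### Signal conditioning

- EMG: rectification, then zero-phase 4th-order Butterworth high-pass
  at 20 Hz, then low-pass at 200 Hz. Note the high-pass removes the
  low-frequency content of the rectified signal, so the conditioned
  "envelope" is not sign-definite.
- IMU: zero-phase 4th-order Butterworth low-pass at 20 Hz (order chosen
  to match the EMG filters), applied at the native 286 Hz, then linear
  interpolation onto a uniform grid at 2000 Hz spanning the same
  duration (`round(duration·rate) + 1` points, endpoints preserved
  exactly), then per-channel Z-scoring.
- Zero-phase realization: forward–backward filtering (`filtfilt`) with
  reflective (even) padding of 3× the filter order. The effective
  magnitude response is the squared single-pass Butterworth magnitude;
  the analytic oracle used in tests applies bilinear prewarping so it
  describes the digital filter exactly up to Nyquist.
- Normalization statistics (per-channel mean and population std of the
  filtered, resampled IMU channels) are fitted on the training folds
  only and applied unchanged to the held-out trial — the leakage-free
  reading; EMG is not Z-scored. Zero-variance channels are rejected by
  name.

### Evaluation

Intra-subject leave-one-out cross-validation: per subject, each trial
is the test set once while the remaining trials fit the normalizer and
both classifiers. Results pool across folds and subjects. "Aggregate
accuracy" is pooled (micro) accuracy over all scored stances of a
family; per-subject mean accuracy is reported alongside. Confusion
matrices (rows = actual, columns = predicted; the row-normalized
diagonal equals recall) and per-class precision/recall/F1 are reported
at each family's headline offset (walking 50 ms, ramp ascent 150 ms,
ramp descent 250 ms before TO). Zero-denominator precision/recall cells
are reported as 0 and flagged; F1 is 0 when precision + recall = 0.
Stances whose FC or TO was not detected within ±100 ms are counted as
missed and excluded from accuracy, as are (separately counted)
undecidable votes.

## Synthetic data model

The simulator generates the exact channel layout the pipeline assumes:
20 EMG channels at 2000 Hz (11 right-limb and 9 left-limb muscles),
7 IMUs (pelvis, both thighs, shanks and feet) × 6 DOF at 286 Hz, and
4 binary foot-switch channels at 2000 Hz.

A trial is a sequence of strides, each assigned a locomotion mode. Per
(mode, channel), the waveform over one stride is a baseline plus 1–3
Gaussian bumps in stride phase (wrap-around distance), with parameters
drawn once per mode from fixed seeds — the mode *signature*. On top of
the mode-specific shape:

- **Event markers.** Sharp bumps (width 0.012 stride) at phase 0 on
  foot/shank/thigh acceleration channels (FC) and at the stance
  fraction on shank/foot/thigh angular-velocity channels (TO), the same
  in every mode. These model the impact transients and swing-onset
  rotations that make gait events detectable from inertial data.
- **Anticipation.** A per-channel component whose amplitude depends on
  the *next* stride's mode, ramping linearly from 15% of the stride to
  TO. This models anticipatory gait adjustment — the physiological
  reason a transition is predictable from the stance *before* the step
  into the new mode — and produces the characteristic rise of
  prediction accuracy toward TO. For ramp-ascent destinations the
  plantarflexor EMG anticipation scales with incline.
- **EMG form.** EMG channels are generated directly as non-negative
  activation envelopes (a post-rectification analog of interference
  EMG) with burst amplitudes that increase with ramp-ascent incline for
  the plantarflexors (gastrocnemii, soleus) — steeper ascent, stronger
  push-off. The full conditioning chain is still applied to them.
- **Variability.** Stride durations get multiplicative log-normal
  jitter (sd 5% of 1.1 s default); each subject gets one multiplicative
  amplitude factor (log-normal, sd 10%); i.i.d. Gaussian noise
  (sd 0.25 in signal units, against template amplitudes of order 1–3)
  is added per channel. All randomness derives from
  `(seed, subject_id, trial_id)`, so identical configurations are
  byte-identical.

Left-side channels are evaluated half a stride out of phase; left-side
events are generated likewise but only the right (lead) side is scored
downstream. Foot-switch channels are 1 exactly on each [FC, TO) stance
of their side. The default per-trial route walks a lab circuit —
W W RA RA W RD RD W SA W SD W O W ST — with the ramp incline rotating
by trial (`trial_id mod 3 + 1`), so every subject's trial set covers
all three inclines and every training fold of the leave-one-out split
still contains the held-out trial's classes.

**What the simulator does not model:** biomechanically validated
kinematics or kinetics, raw interference EMG, stair/obstacle waveform
fidelity beyond label-level distinctness, gait pathology, sensor
artifacts (drift, soft-tissue motion, electrode lift). Passing
end-to-end tests therefore demonstrates that the pipeline's machinery —
conditioning, labeling, training, detection, windowing, voting,
cross-validation — is correct and recovers structure that is present in
the data; it does not certify accuracy levels on human recordings.

## Problem sizes and defaults

The default study configuration is 4 subjects × 6 trials (24 LOOCV
folds, ~15 strides per trial), which exercises every transition class
while keeping a full experiment to a few minutes on one CPU; the
smaller runs in the test suite (1–2 subjects) use a single-incline
route so each training fold contains every test class. Key defaults:
stride 1.1 s, stance fraction 0.6, label tolerance ±10 ms, refractory
200 ms, match tolerance ±100 ms (on the scale of the largest observed
timing errors), window 100 ms / step 12 ms, offsets 350/250/150/50 ms.

## Known limitations

- The event detector is sample-wise; no recurrent or convolutional
  context is used, matching the design it implements.
- Event discretization (run median + refractory) is one reasonable
  convention; scoring is robust to it because matching allows ±100 ms.
- The stage-2 family router uses the current locomotion mode as known
  state; a deployed system would take it from the ongoing mode
  estimate, whose errors are not modeled here.
- With very small datasets the stratified validation split can leave
  rare transition classes with only a handful of validation windows,
  making early stopping noisier; the defaults keep every class
  represented in each fold.
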