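# Methods

This note documents the models, the parameter choices and the numerical
conventions used throughout the package, and what the synthetic test bed
does and does not establish about real EEG.

## Problem setup

Seizure prediction is treated as per-epoch binary classification.  A 10 s
multichannel EEG segment is labeled 1 (preictal) if it lies inside the
preictal window — the 10, 20 or 30 minutes ending at a seizure onset — and
0 (baseline) if it lies far from every seizure.  Ictal segments belong to
neither class.  Epoch-level classification is the whole scope: event-based
alarm metrics (false detections per hour, warning horizons) are not
computed.

## Preprocessing

* **Notch filters.** Second-order IIR notches at 50 and 60 Hz (quality
  factor 30) remove mains interference.  They are applied forward and
  backward (`filtfilt`), so the effective magnitude response is squared and
  the group delay is identically zero.  Measured attenuation at the notch
  frequencies exceeds 40 dB by a large margin; the 10 Hz passband loss is
  under 5 %.
* **Low-pass.** A 50th-order windowed-sinc FIR at 35 Hz, also zero-phase.
  "Non-causal" filtering is interpreted as zero-phase forward–backward
  application; no adaptation signal exists, so no adaptive variant is
  implemented.  Because the gamma band (30–80 Hz) is part of the default
  feature set and a 35 Hz low-pass would null it, **features are computed
  from the notch-filtered signal and the low-pass is applied only when the
  gamma band is disabled** (`FilterConfig.lowpass_cutoff_hz=None` is the
  default in `ExperimentConfig`).
* **Epoching.** Preictal epochs tile the preictal window backwards from
  the onset, so the last epoch always abuts the seizure; a window that
  would extend before the recording start is truncated and logged.  No
  epoch of either label ever overlaps a seizure interval.  Baseline epochs
  must lie at least `baseline_min_gap_s` (default 3600 s; configurable)
  from every seizure *and* outside every preictal window — the guard
  distance prevents peri-ictal activity from contaminating the negative
  class.  Eligible baseline epochs are down-sampled uniformly (seeded, seed
  recorded in the manifest) to equal the preictal count, giving each
  subject a balanced dataset.  With 9 seizures and a 10 min window this
  yields 540 + 540 epochs per subject and 22,680 over 21 subjects.

## Features

* **Band profile.** STFT with a 1 s (256-sample) Hann window and 50 %
  overlap, no boundary padding: 19 frames per 10 s epoch.  The 1 s window
  is the common field default and resolves the 0.5 Hz delta edge
  acceptably.  Entry (b, t) is the *mean magnitude* (not power) over the
  frequency bins in band b at frame t, averaged over channels — magnitude
  keeps the profile linear in signal amplitude.  Bins are assigned to
  half-open bands [low, high); with a 1 Hz grid the nominal 12–13 Hz
  alpha/beta gap leaves bin 12 unassigned, exactly as the band table
  states.  Averaging over channels is what reduces the feature to the
  stated 5 × T shape; per-channel profiles remain available by computing
  profiles on single-channel epochs.
* **Correlation map.** Plain Pearson correlation over the epoch's samples
  for every channel pair.  A zero-variance channel has undefined
  correlation; its off-diagonal entries are set to 0 and the event counted
  (`n_zero_variance`), never silently dropped.
* **Baseline normalization.** Per subject, the element-wise mean of the
  band profiles and correlation maps over baseline epochs is the divisor
  for every epoch's features.  The number of profiles is configurable and
  defaults to *all available* (the nominal 1000 exceeds the 540 baseline
  epochs a balanced subject has; the count actually used is always
  recorded).  In experiments the mean is computed **from training-split
  baseline epochs only**, so no statistic of the evaluation epochs leaks
  into normalization.  Division is guarded: cells where the baseline mean
  has magnitude below ε = 10⁻⁸ are set to 1 — the "no change" value — and
  counted.  Normalized correlation values may leave [−1, 1] (division by a
  small or negative baseline entry); they are passed through unchanged, as
  plain division prescribes, and the QC counters make the frequency of
  such cells visible.

## Image composition and backbones

The two normalized matrices are resampled bilinearly into a fixed
two-block layout (band profile top half, correlation map bottom half),
min–max scaled per image to [0, 1] (a constant image maps to all zeros) and
replicated across 3 channels.  The layout is a package design choice — the
composition of the two feature types into a single backbone input is
otherwise unspecified — and is deterministic, so permutation of channels
permutes the correlation block predictably.

Backbones are registered by string id and used **frozen**; no fine-tuning
is performed.

* `efficientnet-b0` (optional, requires torch + timm): pooled penultimate
  layer, 1280-d.  The named dense head layer of the original graph is a
  framework-specific node; the pooled penultimate layer is the standard,
  framework-portable transfer-learning read-out.  Standard pretrained
  input normalization is applied.
* `mini-cnn` (default): a seeded random-weight CNN in NumPy — four 3×3
  stride-2 convolutions (8/16/32/64 channels), ReLU, **4×4 regional
  average pooling**, random linear read-out to 128-d.  Regional (rather
  than global) pooling is deliberate: the class signal lives in *which
  rows of the image are bright*, and global pooling erases that layout.
  Untrained random convolutional features are a well-understood baseline
  embedding and make the whole pipeline reproducible offline.
* `tiny-cnn`: two layers, global pooling, 32-d — intentionally weaker,
  used as the backbone-swap ablation arm.

## Ensemble

Six SVMs (RBF kernel, C = 1.0, gamma = "scale", tol = 10⁻³, one-vs-rest)
vote by arithmetic mean of their binary outputs, rounded half-up: a 3–3
tie predicts preictal, favoring sensitivity.  The discussion of gamma
elsewhere mentions a tuned value of 0.1; "scale" is the default here and a
numeric override is available.  Member diversity is bagged stratified
leave-one-fold-out (6 folds, seeded) by default, with random 80 % feature
subspaces as an alternative (`diversity="subspace"`); which mechanism the
original system used is not determinable, so both are offered and the
choice is recorded in the manifest.  Each member standardizes features on
its own training subset (a `StandardScaler` in front of the SVC): deep
feature dimensions differ in scale by more than an order of magnitude, and
an RBF kernel on unstandardized features measurably degrades separation.
Hard votes enter the rounding rule; the mean of the members' continuous
decision scores is kept solely for ROC curves, because the vote itself
offers only seven operating points.

## Evaluation

Stratified 60/20/20 split within subject.  The default assignment is
contiguous-in-time blocks per (subject, label) group, so adjacent epochs
never straddle a split boundary — a temporal-leakage guard; a seeded
epoch-level random split (`split_mode="random"`) mirrors the simpler
protocol.  Metrics are computed from exact confusion-count formulas;
ratios with zero denominators are reported absent-with-reason.  Aggregation
is per subject, then mean ± sd across subjects, with pooled-epoch metrics
and pooled AUC alongside.  AUC is the trapezoid area under the ROC from a
threshold sweep of the mean decision scores and equals the scaled
Mann–Whitney U statistic.

## Synthetic generator

Each frequency band is band-limited Gaussian noise (white noise filtered
by a 4th-order Butterworth band-pass at the band edges), normalized to
unit variance and scaled by the band's amplitude; pure tones are avoided
because they make correlation maps rank-deficient and STFT estimates
degenerate.  Channel correlation is imposed by multiplying the independent
band sources with the Cholesky factor of the target matrix — exact in
expectation — and white sensor noise (default sd 3 µV) is added, which
dilutes realized correlations toward identity just as sensor noise does in
practice.  Default band amplitudes follow a 1/f-like resting-EEG profile
(delta 30, theta 15, alpha 12, beta 6, gamma 3 µV).  The default
correlation model is `(1 − floor)·ρ^|i−j| + floor` with floor 0.2: scalp
recordings keep distant electrode pairs weakly correlated through volume
conduction and the shared reference, and the floor also keeps the
division-based normalization of correlation maps away from near-zero
denominators.  Each recording is laid out as baseline activity with
annotated seizures; the preictal window before each onset (and the ictal
span itself) carries the preictal parameters.  Everything is driven by one
integer seed; identical specs produce bit-identical output.

The generator emulates controllable spectral and spatial contrast, *not*
physiology: no seizure morphology, no artifacts (EMG/EOG/electrode pops),
no nonstationary drift, no inter-subject anatomy.  Passing the synthetic
recovery tests therefore shows that the pipeline is correct and sensitive
to the kinds of structure it claims to use — it does not certify
performance on clinical data, which is why headline accuracies from real
archives are out of scope here.

## Experiment scale

The default synthetic cohort uses 8 subjects × 21 channels × 1 seizure
with a 10 min preictal window and a 600 s baseline guard, i.e. ~22 min of
signal and 120 balanced epochs per subject; this gives 192 pooled held-out
test epochs, large enough that the strong-signal (≈100 %) and no-signal
(≈50 %) outcomes are clearly separated, while a full cohort run stays
around a minute of CPU.  Ablation arms share the generated recordings and,
where unchanged, the epoching and embeddings.

## Known limitations

* The numpy backbones are untrained; absolute accuracies on real data
  would require the pretrained EfficientNet-B0 weights (optional extra).
* The CHB-MIT summary parser covers the standard dialect (file blocks,
  seizure counts, start/end second lines); exotic variants in a few
  archive files may need the channel-selection override.
* EDF writing quantizes to 16 bits per sample with a per-channel physical
  range; round trips are exact only to that quantization.
* Baseline down-sampling is uniform; no attempt is made to match the
  circadian distribution of baseline epochs to the preictal ones.
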