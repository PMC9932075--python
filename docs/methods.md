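# Methods

## Data model

A project is a set of videos (optionally several synchronized camera
streams with identical frame counts and rates), each tiled into contiguous
clips of a user-chosen length (default 60 s; the trailing remainder is kept
as a short clip so clips always tile the video exactly). Frame coordinates
are 0-based and half-open everywhere, including the annotation files; bout
intervals exist only at the I/O boundary. Clips — not frames or videos —
are the atomic unit of annotation, training, confidence scoring and review,
because a human reviewer needs the context of a whole clip to correct any
frame in it.

A fraction `prop_labeled` of clips is selected uniformly at random for
annotation; `|D_labeled| = max(1, round_half_away_from_zero(prop · N))`
(floor of 1 so no split is empty; the count formula is kept literal even
when `prop` is close to 1). The labeled set is further split
`prop_validate = 0.20` into validation vs. training clips, with the
validation count floored at 1 and capped so training is never empty. All
selections are reproducible from integer seeds; k-fold splitting over clips
(shuffled, near-equal folds) is delegated to scikit-learn's `KFold`. The
learning-curve sweep of labeled fractions is 0.02–0.20 in steps of 0.02
(where accuracy changes fastest per unit of annotation) and 0.25–0.90 in
steps of 0.05 — 24 values.

## Temporal frames (optical flow)

Motion between consecutive grayscale frames is estimated with TV-L1
(total-variation regularization, L1 data term) via
`skimage.registration.optical_flow_tvl1`, using that reference
implementation's solver defaults (attachment 15, tightness 0.3, 5 warps,
10 iterations), exposed in the pipeline config. The wrapper returns the
a→b motion field as per-pixel (dx, dy); the sign convention was verified
against synthetic translations. Flow fields are rendered to 8-bit RGB via
HSV: hue = orientation on a cyclic wheel, value = |flow| / max_magnitude
clipped at 1, saturation fixed at maximum, so zero motion is black. The
normalization constant is fixed **per video** (default: the 99th percentile
of flow magnitudes), not per frame, so brightness is comparable across
frames of one video. Any fixed cyclic wheel would do, since downstream
features are learned; this one is frozen for reproducibility.

## Feature extraction

Frames are resized to 224×224 RGB, scaled to [0, 1] and
channel-standardized. The backbone is a ResNet18-class stack of bias-free
strided 3×3 convolutions (channels 32-64-128-256-512, ReLU, stride 2)
ending in global average pooling, so every frame maps to a 512-vector.
Weights are drawn from a seeded He-normal initialization: feature
extraction is deterministic, needs no downloads, and the backbone slot is
pluggable, so a pretrained network can be substituted where available
(pretrained weights change benchmark accuracy, not any of the structural or
algorithmic properties tested here). Temporal frames are stacked with their
five predecessors and five successors along channels (stack size 11 → 33
channels), edge-replicating the first/last flow image at clip boundaries;
the temporal feature of frame j is centered on the flow between j and j+1,
with the final frame reusing the last flow image so both streams have equal
length. The flow backbone is the spatial backbone with its first
convolution kernel tiled 11× along input channels; all other weights are
shared, and because convolution is linear a stack of 11 identical images
reproduces 11× the original first-layer response (tested).

Per frame and camera, spatial and temporal 512-vectors are concatenated
camera-major, spatial before temporal: 1024·C dimensions for C cameras.

## RICA reduction

The concatenated features are reduced to 512 dimensions by reconstruction
independent component analysis: standardize inputs per column, then
minimize

    J(W) = (λ/N) Σᵢ ‖W Wᵀ xᵢ − xᵢ‖² + (1/N) Σᵢ Σₖ log cosh(wₖᵀ xᵢ)

over the d_in × d_out matrix W by L-BFGS from a seeded random start
(λ = 1, iteration cap 200 by default, all config-exposed). Both terms carry
the per-sample 1/N normalization, following the convention of the MATLAB
`rica` implementation this mirrors. The fitted transform is purely linear
and is applied with the training-time standardization. To avoid leaking
information from unlabeled/test clips into the representation, the
transform is fitted on the labeled clips' features only (config-
overridable); the pipeline therefore orders the `reduce` stage after
`split`. Against a derivative-free optimizer run to convergence on a tiny
instance, the L-BFGS fit reaches the same objective within 1 % (tested).

## Classifier

Architecture: sequence input (512) → BiLSTM → dropout(0.5) → BiLSTM →
dropout(0.5) → fully-connected(K) → softmax, cross-entropy loss over K
mutually exclusive behaviors. Hidden units per direction default to 128
(config-exposed; the source work does not state a value). Clips are cut
into ~15-s sequences (`round(15·fps)` frames, remainder kept) before
training; sequences are mixed across clips into shuffled minibatches of 8,
padded to the longest sequence in the batch with padded frames masked out
of the loss. For the backward direction of each BiLSTM layer, sequences are
reversed within their true lengths so padding never precedes real frames.

Training uses Adam (β₁ = 0.9, β₂ = 0.999) — the optimizer is unstated in
the source work, but the stated schedule maps directly onto it — with
initial learning rate 10⁻³ multiplied by 0.1 every 4 epochs, at most 16
epochs, validation loss evaluated every epoch. Training stops once the
number of epochs whose validation loss is ≥ the smallest earlier loss
exceeds 2; the count is cumulative, not consecutive (the trace
[1.0, 0.9, 0.95, 0.92, 0.91] stops after epoch 5). Parameters from the
best-validation epoch are restored. Single-class training labels produce a
warning, not an error. The LSTM forward/backward passes, dropout
(inverted), the optimizer and the whole loop are implemented in numpy;
gradients are verified against finite differences in the test suite, and
training is bit-reproducible from the seed in single-threaded mode.

The fixed schedule assumes a realistic volume of training sequences: with
only a handful of minibatches per epoch, the 10×-per-4-epochs decay freezes
optimization before convergence. Test fixtures and the synthetic study
below are therefore sized so an epoch contains several minibatches.

## Confidence and calibration

Frame confidence is the max softmax score; temperature scaling divides
logits by a scalar T > 0 fitted on the validation set (best-epoch model,
computed once after training) by deterministic bounded scalar minimization
of the NLL over log T ∈ [log 0.05, log 20]. Scaling never changes the
predicted label. Clip confidence is the unweighted mean of frame
confidences; dataset confidence (and accuracy) is the frame-count-weighted
mean over clips. Calibration is reported per clip as PE = conf − acc and
AE = |PE|, aggregated as unweighted means MSD and MAE — note the deliberate
asymmetry, kept exactly as defined: MAE/MSD weight clips equally while
dataset confidence weights by frames.

## Review efficiency

Reviewing a clip corrects its labels, so its accuracy becomes 1. For an
ordering of the n unlabeled clips, `acc(D_k)` is the frame-weighted dataset
accuracy after reviewing the first k. The random baseline is the exact
average over all orderings when n < 7, else a seeded Monte-Carlo mean
(default 100 permutations; the candidate analysis in the acceptance script
uses 500). `IOR_k` is the pointwise difference from the baseline, and
`mean IOR = (1/n)·Σ_{k=0..n} IOR_k` — an (n+1)-term sum divided by n, kept
literally as defined. Review efficiency is the ratio of a candidate
ordering's mean IOR to that of the optimal ordering (ascending true
accuracy, ties broken by clip index): 1 for an accuracy-matching order,
0 in expectation for a random one, negative for worse-than-random;
undefined (flagged) when all clips are equally accurate.

One caveat discovered by exhaustive testing: with **unequal** clip sizes the
ascending-accuracy ordering does not dominate every other ordering at every
budget k — the one-step gain of reviewing clip i is (1 − accᵢ)·|clipᵢ|, so
the truly dominant order sorts by that product descending. With
equal-length clips (the framework's operating assumption) the two coincide
and ascending accuracy is dominant at every k; the dominance property is
asserted for equal sizes.

## Synthetic data

The generators emulate the structure of laboratory behavior datasets
without shipping any video: mutually exclusive behaviors whose labels
follow a first-order Markov chain (per-behavior self-transition probability
`p_stay`, switching to other behaviors in proportion to their stationary
weights — so bout lengths are geometric with mean 1/(1−p_stay), and class
imbalance is controlled by the weights); behavior-dependent motion (a
textured blob moving at each behavior's velocity plus jitter, bouncing off
frame edges with its heading reversed, over a static textured background,
with a sinusoidal carrier moving rigidly with the blob so dense flow is
well-constrained); class-conditional Gaussian features
(means on scaled coordinate axes at exact pairwise distance Δ·σ, isotropic
noise σ); and a classifier of known accuracy and calibration (true
posteriors with mass q ≈ base accuracy on a random class, true labels
sampled *from* those posteriors, logits = s·log p — s = 1 calibrated,
s > 1 overconfident with fitted temperature ≈ s). All randomness flows from
one seed through named substreams.

What the fixtures do not emulate: photorealistic animals, JPG artifacts,
annotation noise, long-range temporal structure beyond first-order bouts,
or the covariance structure of real CNN features. Passing tests therefore
demonstrate that the algorithms are implemented correctly and behave as
designed under their stated assumptions, not that any particular accuracy
will be reached on real video.

## Study conditions used in the automated checks

The classifier-recovery check uses K = 3 behaviors, 512-d features with
Δ = 6σ separation, Markov labels with p_stay = 0.9, 60 one-minute clips at
5 fps (18 000 frames), 30 % of clips labeled (20 % of those for
validation), default hyperparameters, and reports the median held-out
frame accuracy over 3 seeds; this sizing gives several minibatches per
epoch so the fixed schedule can converge, and runs in a few CPU-minutes.
The calibration checks use 20 000 frames at base accuracy 0.8 with
overconfidence scales 1 and 2. The review checks use 10 equal-length clips
with accuracies spread over [0.30, 0.95] and a 500-permutation random
baseline.

## Known limitations

- The default backbone is randomly initialized; absolute accuracies on real
  video will be far below what a pretrained backbone yields. The backbone
  interface accepts any object with `features()` / `first_layer_response()`.
- Numpy training is single-threaded and CPU-bound; it is sized for clips'
  worth of data, not hours of video.
- Reading arbitrary video containers requires an external decode step; the
  frame store consumes per-video archives of still images (PNG-in-zip), and
  the `simulate` stage writes them directly.
- Co-occurring (non-exclusive) behaviors, Bayesian/density-based confidence
  alternatives, and GUI review tools are out of scope.
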