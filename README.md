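# deepaction

Automated per-frame annotation of animal behavior in video, for
behavioral-neuroscience labs that record long sessions (home-cage rodents,
multi-camera arenas, cephalopods) and need frame-level ethograms without
annotating everything by hand.

The pipeline:

1. **Two-stream features.** Each video frame is represented by its
   appearance (the raw frame) and its motion (dense TV-L1 optical flow
   between consecutive frames, rendered as an HSV "temporal frame" whose hue
   encodes direction and brightness magnitude). Both streams pass through a
   CNN backbone whose global-average-pooling layer yields a 512-vector per
   frame; temporal frames are stacked with their 5 predecessors and 5
   successors (33 input channels) for short-term motion context. Per-camera
   spatial and temporal features are concatenated (1024·C dims for C
   cameras) and reduced back to 512 dims by reconstruction ICA, which
   minimizes `J(W) = (λ/N)·Σ‖WWᵀx − x‖² + (1/N)·Σ log cosh(Wᵀx)`.
2. **Sequence classification.** A two-layer BiLSTM (dropout 0.5 after each
   layer, softmax head) maps the per-frame feature sequence of each ~15-s
   chunk to one of K mutually exclusive behaviors per frame, trained with
   cross-entropy: Adam, lr 10⁻³ dropped 10× every 4 epochs, minibatch 8,
   ≤16 epochs, early stopping once validation loss has been ≥ its running
   minimum more than twice.
3. **Confidence and review.** The frame confidence is the max softmax score
   `p̂ⱼ = max_k σ(z_j/T)⁽ᵏ⁾`, with the temperature T fitted on validation
   data by minimizing NLL; clip confidence is the mean over frames.
   Calibration is summarized by per-clip prediction error
   `PE = conf − acc`, with aggregates MAE and MSD. Reviewing a clip raises
   its accuracy to 1, so for any review ordering the dataset accuracy after
   k clips is `acc(D_k) = |D_k^rev|/|D| + acc(D_k^unrev)·|D_k^unrev|/|D|`;
   the mean improvement over a random ordering, normalized by that of the
   optimal (ascending-accuracy) ordering, is the **review efficiency**
   (1 = optimal, 0 = no better than random).

Everything runs on plain CPU numpy/scipy: the TV-L1 solver comes from
scikit-image, while the CNN backbone (seeded random weights, pluggable for a
pretrained network) and the BiLSTM with full backpropagation through time
are implemented in the package.

## Worked example

`examples/` contains one short script per capability. Training the
classifier on synthetic spatiotemporal features
(`python examples/04_train_classifier.py`) prints:

```
trained 16 epochs (stop: max_epochs, best epoch 16)
  epoch 1: lr 1e-03  train loss 0.904  val loss 0.650
  ...
  epoch 5: lr 1e-04  train loss 0.213  val loss 0.217
held-out frame accuracy: 0.935; macro F1 over all 3 classes: 0.931
```

i.e. with three behaviors whose 32-d features are well separated and whose
labels follow a Markov bout process, the BiLSTM labels ~94 % of held-out
frames correctly under the standard schedule (note the lr drop at epoch 5).
Calibration (`examples/05_confidence_calibration.py`):

```
fitted temperature T = 1.974 (NLL 0.9207 -> 0.7220)
        max softmax: MAE 0.1913  MSD +0.1913
 temperature-scaled: MAE 0.0276  MSD +0.0047
```

a classifier made overconfident by doubling calibrated logits is corrected
by the fitted T ≈ 2: the signed confidence−accuracy gap per clip drops from
+0.19 to +0.005. And review (`examples/06_review_efficiency.py`) shows a
noisy-but-informative confidence ordering reaching efficiency 0.964 of the
optimal review order.

The full pipeline — synthetic videos → flow → CNN features → RICA →
training → confidence → review → export — runs end-to-end via
`python examples/07_full_pipeline.py`, or from a shell with the thin CLI:

```bash
deepaction all --config project.yaml
deepaction predict --config project.yaml   # single stage, idempotent
```

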