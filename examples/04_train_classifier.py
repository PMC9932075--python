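"""Train the BiLSTM classifier on synthetic spatiotemporal features.

Class-conditional Gaussian features with Markov bout structure stand in
for the reduced two-stream features; the classifier is trained with the
standard schedule (Adam, lr 1e-3 dropping 10x every 4 epochs, minibatch 8,
early stopping with patience 2) and evaluated per frame on held-out clips.
"""

import numpy as np

from deepaction import (
    BehaviorKernel,
    BehaviorSet,
    Hyperparameters,
    SyntheticBehaviorSpec,
    SyntheticFeatureSpec,
    accuracy,
    build_network,
    generate_features,
    generate_label_sequence,
    per_class_prf,
    predict,
    train,
)

bs = BehaviorSet(["rest", "walk", "run"])
fps, frames_per_clip, d = 2.0, 120, 32
bspec = SyntheticBehaviorSpec(
    bs, {l: BehaviorKernel() for l in bs.labels}, p_stay=0.9, fps=fps
)
fspec = SyntheticFeatureSpec(bs, d=d, sigma=1.0, separation=8.0)

clips = {}
for i in range(26):
    labels = generate_label_sequence(bspec, frames_per_clip, seed=100 + i)
    clips[f"clip{i:02d}"] = (generate_features(fspec, labels, seed=100 + i), labels)
ids = sorted(clips)
train_set = {c: clips[c] for c in ids[:18]}
val_set = {c: clips[c] for c in ids[18:22]}
test_set = {c: clips[c] for c in ids[22:]}

hp = Hyperparameters(hidden_units=64)
net = build_network(K=bs.K, d_in=d, hidden_units=64, seed=0)
model = train(net, train_set, val_set, bs, fps=fps, hp=hp, seed=0)

print(f"trained {len(model.log)} epochs (stop: {model.stopping_reason}, "
      f"best epoch {model.best_epoch})")
for e in model.log[:5]:
    print(f"  epoch {e['epoch']}: lr {e['learning_rate']:.0e}  "
          f"train loss {e['train_loss']:.3f}  val loss {e['val_loss']:.3f}")

pred_all, true_all = [], []
for feats, labels in test_set.values():
    pred_all.append(predict(model, feats).labels)
    true_all.append(labels)
pred, true = np.concatenate(pred_all), np.concatenate(true_all)
per_class, f1_all = per_class_prf(pred, true, bs)
print(f"held-out frame accuracy: {accuracy(pred, true):.3f}; "
      f"macro F1 over all {bs.K} classes: {f1_all:.3f}")
# Accuracy ~0.95 here: the 8-sigma class separation makes frames nearly
# perfectly separable, and the BiLSTM exploits bout structure across time.
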