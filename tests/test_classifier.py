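"""BiLSTM classifier: architecture, schedule, stopping, prediction."""

import numpy as np
import pytest

from deepaction.classifier import (
    BiLSTMNetwork,
    Hyperparameters,
    _masked_ce_loss,
    _pad_batch,
    build_network,
    early_stop_epoch,
    learning_rate_schedule,
    predict,
    split_into_sequences,
    train,
)
from deepaction.metrics import accuracy
from deepaction.project import BehaviorSet
from deepaction.synthetic import (
    SyntheticBehaviorSpec,
    SyntheticFeatureSpec,
    BehaviorKernel,
    generate_features,
    generate_label_sequence,
)

D = 16  # reduced feature dim for fast tests
HP_FAST = Hyperparameters(hidden_units=24)


def make_clips(behavior_set, n_clips, frames_per_clip, fps, seed, d=D, separation=8.0):
    """Markov-labeled Gaussian-feature clips keyed by clip id."""
    bspec = SyntheticBehaviorSpec(
        behavior_set, {l: BehaviorKernel() for l in behavior_set.labels},
        p_stay=0.9, fps=fps,
    )
    fspec = SyntheticFeatureSpec(behavior_set, d=d, sigma=1.0, separation=separation)
    clips = {}
    for i in range(n_clips):
        labels = generate_label_sequence(bspec, frames_per_clip, seed * 1000 + i)
        feats = generate_features(fspec, labels, seed * 1000 + i)
        clips[f"c{i:02d}"] = (feats, labels)
    return clips


class TestSequences:
    def test_60s_clip_at_10fps_gives_4_sequences_of_150(self):
        feats = np.zeros((600, 8))
        seqs = split_into_sequences(feats, None, fps=10.0)
        assert [x.shape[0] for x, _ in seqs] == [150, 150, 150, 150]

    def test_short_clip_is_one_sequence(self):
        feats = np.zeros((30, 8))
        seqs = split_into_sequences(feats, None, fps=10.0)
        assert len(seqs) == 1 and seqs[0][0].shape[0] == 30

    def test_concatenation_reconstructs_clip(self):
        rng = np.random.default_rng(0)
        feats = rng.standard_normal((412, 8))
        labels = rng.integers(0, 3, 412)
        seqs = split_into_sequences(feats, labels, fps=10.0)
        np.testing.assert_array_equal(np.concatenate([x for x, _ in seqs]), feats)
        np.testing.assert_array_equal(np.concatenate([y for _, y in seqs]), labels)

    def test_empty_clip_rejected(self):
        with pytest.raises(ValueError):
            split_into_sequences(np.zeros((0, 8)), None, fps=10.0)


class TestNetwork:
    def test_output_shape_and_softmax_rows(self):
        net = build_network(K=4, d_in=D, hidden_units=8, seed=0)
        x = np.random.default_rng(1).standard_normal((2, 9, D))
        logits, _ = net.forward(x, lengths=[9, 9])
        assert logits.shape == (2, 9, 4)
        probs = np.exp(logits) / np.exp(logits).sum(axis=2, keepdims=True)
        np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-6)

    def test_eval_mode_is_deterministic(self):
        net = build_network(K=3, d_in=D, hidden_units=8, dropout=0.5, seed=0)
        x = np.random.default_rng(2).standard_normal((1, 7, D))
        a, _ = net.forward(x, lengths=[7])
        b, _ = net.forward(x, lengths=[7])
        np.testing.assert_array_equal(a, b)

    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(ValueError):
            build_network(K=1, d_in=D)

    def test_backprop_matches_numerical_gradient(self):
        """BPTT gradients agree with central finite differences."""
        rng = np.random.default_rng(3)
        net = BiLSTMNetwork(K=3, d_in=4, hidden_units=5, dropout=0.0, seed=1)
        seqs = [
            (rng.standard_normal((7, 4)), rng.integers(0, 3, 7)),
            (rng.standard_normal((5, 4)), rng.integers(0, 3, 5)),
        ]
        x, y, mask, lengths = _pad_batch(seqs)

        def loss():
            logits, cache = net.forward(x, lengths)
            l, dl = _masked_ce_loss(logits, y, mask)
            return l, cache, dl

        _, cache, dl = loss()
        grads = net.backward(cache, dl)
        eps = 1e-6
        for name, p in net.params.items():
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp, _, _ = loss()
            p[idx] = orig - eps
            lm, _, _ = loss()
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(num, rel=1e-3, abs=1e-7), name


class TestSchedule:
    def test_learning_rate_drops_tenfold_every_four_epochs(self):
        hp = Hyperparameters()
        lrs = [learning_rate_schedule(e, hp) for e in range(1, 9)]
        assert lrs[:4] == pytest.approx([1e-3] * 4)
        assert lrs[4:] == pytest.approx([1e-4] * 4)

    def test_patience_rule_on_scripted_trace(self):
        # three epochs >= the 0.9 minimum -> terminate after epoch 5
        assert early_stop_epoch([1.0, 0.9, 0.95, 0.92, 0.91], patience=2) == 5

    def test_monotone_decreasing_losses_never_stop(self):
        losses = np.linspace(1.0, 0.1, 16)
        assert early_stop_epoch(losses, patience=2) is None

    def test_patience_counts_cumulatively_not_consecutively(self):
        # non-min epochs at 2, 4, 6 -> stop at the third offence
        assert early_stop_epoch([1.0, 1.1, 0.8, 0.9, 0.7, 0.75], patience=2) == 6


class TestTraining:
    def test_training_log_schedule_and_reproducibility(self, behavior_set):
        clips = make_clips(behavior_set, 6, 60, fps=2.0, seed=1)
        ids = sorted(clips)
        tr = {c: clips[c] for c in ids[:4]}
        va = {c: clips[c] for c in ids[4:]}

        def run():
            net = build_network(behavior_set.K, d_in=D, hidden_units=24, seed=5)
            return train(net, tr, va, behavior_set, fps=2.0, hp=HP_FAST, seed=5)

        m1, m2 = run(), run()
        assert m1.log == m2.log  # bit-identical training trace
        assert [e["epoch"] for e in m1.log] == list(range(1, len(m1.log) + 1))
        for e in m1.log:
            assert e["learning_rate"] == pytest.approx(
                learning_rate_schedule(e["epoch"], HP_FAST)
            )
        assert m1.stopping_reason in ("patience", "max_epochs")
        assert len(m1.log) <= HP_FAST.max_epochs

    def test_single_class_training_warns_but_proceeds(self, behavior_set):
        rng = np.random.default_rng(0)
        tr = {"a": (rng.standard_normal((40, D)), np.array(["rest"] * 40))}
        va = {"b": (rng.standard_normal((20, D)), np.array(["rest"] * 10 + ["walk"] * 10))}
        net = build_network(behavior_set.K, d_in=D, hidden_units=8, seed=0)
        with pytest.warns(UserWarning, match="single class"):
            model = train(net, tr, va, behavior_set, fps=2.0, hp=HP_FAST, seed=0)
        assert model.log

    def test_empty_split_rejected(self, behavior_set):
        net = build_network(behavior_set.K, d_in=D)
        with pytest.raises(ValueError):
            train(net, {}, {}, behavior_set, fps=2.0)


@pytest.fixture(scope="module")
def trained():
    bs = BehaviorSet(["rest", "walk", "run"])
    clips = make_clips(bs, 26, 120, fps=2.0, seed=3)
    ids = sorted(clips)
    hp = Hyperparameters(hidden_units=64)
    net = build_network(bs.K, d_in=D, hidden_units=64, seed=3)
    model = train(
        net, {c: clips[c] for c in ids[:18]}, {c: clips[c] for c in ids[18:22]},
        bs, fps=2.0, hp=hp, seed=3,
    )
    held_out = {c: clips[c] for c in ids[22:]}
    return model, held_out


class TestPrediction:
    def test_n_frames_in_n_labels_out(self, trained):
        model, held_out = trained
        feats, _ = next(iter(held_out.values()))
        result = predict(model, feats)
        assert result.labels.shape == (feats.shape[0],)
        assert result.probabilities.shape == (feats.shape[0], 3)

    def test_labels_are_argmax_of_probabilities(self, trained):
        model, held_out = trained
        feats, _ = next(iter(held_out.values()))
        result = predict(model, feats)
        np.testing.assert_array_equal(
            result.label_indices, result.probabilities.argmax(axis=1)
        )
        np.testing.assert_allclose(result.probabilities.sum(axis=1), 1.0, atol=1e-6)

    def test_high_accuracy_on_separable_features(self, trained):
        model, held_out = trained
        accs = [
            accuracy(predict(model, feats).labels, labels)
            for feats, labels in held_out.values()
        ]
        assert np.mean(accs) >= 0.9

    def test_feature_dim_mismatch_rejected(self, trained):
        model, _ = trained
        with pytest.raises(ValueError):
            predict(model, np.zeros((10, D + 1)))


class TestBidirectionality:
    def test_bilstm_beats_forward_only_on_future_dependent_task(self):
        """Label of frame j is set by features of frame j+3: a forward-only
        LSTM cannot see them, a BiLSTM can."""
        bs = BehaviorSet(["a", "b"])
        hp = Hyperparameters(hidden_units=16, max_epochs=8)

        def dataset(n_clips, seed0):
            out = {}
            for i in range(n_clips):
                r = np.random.default_rng(seed0 + i)
                z = r.standard_normal((83, D))
                y = (z[3:, 0] > 0).astype(int)
                out[f"c{i}"] = (z[:-3], bs.to_labels(y))
            return out

        tr, va, te = dataset(6, 0), dataset(2, 100), dataset(3, 200)
        scores = {}
        for bidir in (True, False):
            net = build_network(2, d_in=D, hidden_units=16,
                                bidirectional=bidir, seed=1)
            model = train(net, tr, va, bs, fps=2.0, hp=hp, seed=1)
            accs = [
                accuracy(predict(model, f).labels, y) for f, y in te.values()
            ]
            scores[bidir] = np.mean(accs)
        assert scores[True] > scores[False]
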