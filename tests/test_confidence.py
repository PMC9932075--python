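"""Confidence scores, temperature scaling, calibration errors."""

import numpy as np
import pytest

from deepaction.confidence import (
    calibration_errors,
    clip_accuracy,
    clip_confidence,
    dataset_confidence,
    fit_temperature,
    negative_log_likelihood,
    scaled_confidence,
    softmax_confidence,
)
from deepaction.metrics import accuracy
from deepaction.project import BehaviorSet
from deepaction.synthetic import generate_calibrated_logits


@pytest.fixture(scope="module")
def calibrated():
    bs = BehaviorSet(["a", "b", "c"])
    logits, labels = generate_calibrated_logits(
        ["a"] * 8000, bs, base_accuracy=0.8, overconfidence_scale=1.0, seed=0
    )
    return bs, logits, bs.to_indices(labels)


class TestSoftmaxConfidence:
    def test_direct_evaluation(self):
        p = softmax_confidence(np.array([[2.0, 0.0, 0.0]]))
        assert p[0] == pytest.approx(np.e**2 / (np.e**2 + 2), abs=1e-6)

    def test_uniform_logits_give_one_over_k(self):
        p = softmax_confidence(np.zeros((3, 4)))
        np.testing.assert_allclose(p, 0.25)

    def test_shift_invariance(self):
        z = np.array([[1.0, -2.0, 0.5]])
        np.testing.assert_allclose(
            softmax_confidence(z), softmax_confidence(z + 100.0)
        )

    def test_nonfinite_logits_rejected(self):
        with pytest.raises(ValueError):
            softmax_confidence(np.array([[np.inf, 0.0]]))


class TestTemperature:
    def test_calibrated_logits_give_T_near_one(self, calibrated):
        _, logits, y = calibrated
        tm = fit_temperature(logits, y)
        assert tm.T == pytest.approx(1.0, abs=0.05)

    def test_doubled_logits_give_T_near_two(self, calibrated):
        _, logits, y = calibrated
        tm = fit_temperature(2.0 * logits, y)
        assert tm.T == pytest.approx(2.0, abs=0.1)

    def test_matches_grid_search_oracle(self, calibrated):
        _, logits, y = calibrated
        tm = fit_temperature(1.5 * logits, y)
        grid = np.linspace(0.5, 4.0, 701)
        nlls = [negative_log_likelihood(1.5 * logits, y, t) for t in grid]
        assert tm.T == pytest.approx(grid[int(np.argmin(nlls))], abs=0.01)

    def test_nll_at_fit_not_worse_than_unit_temperature(self, calibrated):
        _, logits, y = calibrated
        tm = fit_temperature(3.0 * logits, y)
        assert tm.nll_fitted <= tm.nll_initial

    def test_single_class_validation_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_temperature(np.zeros((5, 3)), np.zeros(5, dtype=int))


class TestScaledConfidence:
    def test_unit_temperature_equals_softmax(self):
        z = np.random.default_rng(0).standard_normal((20, 4))
        np.testing.assert_allclose(scaled_confidence(z, 1.0), softmax_confidence(z))

    def test_large_temperature_approaches_uniform(self):
        z = np.random.default_rng(1).standard_normal((10, 5))
        np.testing.assert_allclose(scaled_confidence(z, 1e6), 0.2, atol=1e-4)

    def test_warming_lowers_confidence_keeps_labels(self):
        z = np.random.default_rng(2).standard_normal((50, 3)) * 3
        assert np.all(scaled_confidence(z, 2.0) < softmax_confidence(z))
        np.testing.assert_array_equal(
            (z / 2.0).argmax(axis=1), z.argmax(axis=1)
        )

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            scaled_confidence(np.zeros((2, 3)), 0.0)


class TestClipAndDataset:
    def test_clip_confidence_is_mean(self):
        assert clip_confidence([1.0, 0.5, 0.75, 0.75]) == 0.75

    def test_clip_accuracy_matches_metrics_accuracy(self):
        pred = ["a", "b", "a", "a"]
        true = ["a", "b", "b", "a"]
        assert clip_accuracy(pred, true) == accuracy(pred, true) == 0.75

    def test_dataset_confidence_frame_weighted(self):
        assert dataset_confidence([0.8, 0.6], [100, 300]) == pytest.approx(0.65)

    def test_equal_sizes_reduce_to_plain_mean(self):
        assert dataset_confidence([0.2, 0.8], [50, 50]) == pytest.approx(0.5)

    def test_single_clip_is_identity(self):
        assert dataset_confidence([0.7], [123]) == pytest.approx(0.7)


class TestCalibrationErrors:
    def test_direct_evaluation(self):
        rep = calibration_errors([0.9, 0.7], [0.8, 0.8])
        np.testing.assert_allclose(rep.pe, [0.1, -0.1])
        assert rep.mae == pytest.approx(0.1)
        assert rep.msd == pytest.approx(0.0)

    def test_perfectly_calibrated(self):
        rep = calibration_errors([0.5, 0.9], [0.5, 0.9])
        assert rep.mae == 0.0 and rep.msd == 0.0

    def test_mae_bounds_msd(self):
        rng = np.random.default_rng(3)
        conf = rng.random(30)
        acc = rng.random(30)
        rep = calibration_errors(conf, acc)
        assert rep.mae >= abs(rep.msd)
        np.testing.assert_allclose(rep.ae, np.abs(rep.pe))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            calibration_errors([0.5], [0.5, 0.6])


class TestCalibrationImprovement:
    def test_temperature_scaling_shrinks_msd_of_overconfident_model(self):
        """On an overconfident synthetic classifier (calibrated logits x 2),
        temperature-scaled clip confidences have smaller |MSD| than raw
        softmax ones."""
        bs = BehaviorSet(["a", "b", "c"])
        logits, labels = generate_calibrated_logits(
            ["a"] * 6000, bs, base_accuracy=0.75, overconfidence_scale=2.0, seed=1
        )
        y = bs.to_indices(labels)
        pred = logits.argmax(axis=1)
        tm = fit_temperature(logits, y)
        clip_size = 200
        msd = {}
        for method, conf in (
            ("softmax", softmax_confidence(logits)),
            ("temperature", scaled_confidence(logits, tm.T)),
        ):
            confs, accs = [], []
            for lo in range(0, len(y), clip_size):
                confs.append(clip_confidence(conf[lo:lo + clip_size]))
                accs.append(np.mean(pred[lo:lo + clip_size] == y[lo:lo + clip_size]))
            msd[method] = calibration_errors(confs, accs).msd
        assert abs(msd["temperature"]) < abs(msd["softmax"])
        assert msd["softmax"] > 0  # raw softmax is overconfident here
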