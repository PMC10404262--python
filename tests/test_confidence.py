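"""Confidence model: agreement targets, class-balanced loss, K-fold protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arborseg.confidence import (
    ConfLossParams,
    agreement_map,
    build_confidence_model,
    confidence_loss,
    kfold_self_test,
    probability_histograms,
    train_confidence_model,
)
from arborseg.types import LabelVolume, ProbabilityMaps


def lab(arr):
    return LabelVolume(np.asarray(arr, dtype=np.int16))


class TestAgreementMap:
    def test_identical_volumes_give_all_ones(self):
        a = lab(np.random.default_rng(0).integers(0, 4, (6, 6, 6)))
        assert agreement_map(a, a).all()

    def test_single_difference_gives_single_zero(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 4, (6, 6, 6)).astype(np.int16)
        b = a.copy()
        b[2, 3, 4] = (b[2, 3, 4] + 1) % 4
        target = agreement_map(lab(a), lab(b))
        assert target.sum() == a.size - 1
        assert target[2, 3, 4] == 0

    def test_mean_equals_voxel_accuracy(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 4, (8, 8, 8)).astype(np.int16)
        b = rng.integers(0, 4, (8, 8, 8)).astype(np.int16)
        # counting oracle
        acc = sum(
            int(a[i, j, k] == b[i, j, k])
            for i in range(8) for j in range(8) for k in range(8)
        ) / 512
        assert agreement_map(lab(a), lab(b)).mean() == pytest.approx(acc)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            agreement_map(lab(np.zeros((4, 4, 4))), lab(np.zeros((5, 4, 4))))


class TestConfidenceLoss:
    def test_perfect_confidence_on_correct_voxel_is_zero(self):
        assert confidence_loss(np.array([[[1.0]]]), np.array([[[1.0]]])) == pytest.approx(
            0.0, abs=1e-5
        )

    def test_half_confidence_values(self):
        # Y=1, X=0.5 -> -ln 0.5; Y=0, X=0.5 -> -0.1 ln 0.5
        p = ConfLossParams(a=0.1)
        v1 = confidence_loss(np.array([0.5]), np.array([1.0]), p)
        v0 = confidence_loss(np.array([0.5]), np.array([0.0]), p)
        assert v1 == pytest.approx(-np.log(0.5), abs=1e-6)
        assert v0 == pytest.approx(-0.1 * np.log(0.5), abs=1e-6)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_per_voxel_brute_force(self, trial):
        rng = np.random.default_rng(200 + trial)
        x = rng.random((5, 5, 5))
        y = (rng.random((5, 5, 5)) > 0.5).astype(float)
        a = 0.1
        expected = 0.0
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    xc = min(max(x[i, j, k], 1e-7), 1 - 1e-7)
                    expected -= y[i, j, k] * np.log(xc) + a * (1 - y[i, j, k]) * np.log(1 - xc)
        expected /= 125
        assert confidence_loss(x, y, ConfLossParams(a)) == pytest.approx(expected, abs=1e-6)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(x=st.floats(min_value=0.01, max_value=0.99))
    def test_asymmetry_identity(self, x):
        """loss(Y=0, X=x) = a * loss(Y=1, X=1-x) for the class-balanced loss."""
        p = ConfLossParams(a=0.1)
        left = confidence_loss(np.array([x]), np.array([0.0]), p)
        right = confidence_loss(np.array([1 - x]), np.array([1.0]), p)
        assert left == pytest.approx(0.1 * right, rel=1e-6)

    def test_invalid_a_rejected(self):
        with pytest.raises(ValueError):
            ConfLossParams(a=0.0)


class TestKFoldProtocol:
    def _stub_subjects(self, n):
        rng = np.random.default_rng(0)
        out = []
        for _ in range(n):
            labv = LabelVolume(rng.integers(0, 4, (8, 8, 8)).astype(np.int16))
            from arborseg.types import IntensityVolume

            vol = IntensityVolume(rng.random((2, 8, 8, 8)).astype(np.float32))
            out.append((vol, labv))
        return out

    def _stub_train(self, record):
        def train(subjects, cfg, mcfg):
            ids = frozenset(id(s[0]) for s in subjects)
            record.append(ids)
            return ids  # the "model" remembers its training subjects

        return train

    @staticmethod
    def _stub_predict(model, volume):
        seg = LabelVolume(np.zeros((8, 8, 8), dtype=np.int16))
        probs = ProbabilityMaps(np.full((4, 8, 8, 8), 0.25, dtype=np.float32))
        # tag the prediction with the model so the test can audit fold purity
        return seg, (probs, model)

    def test_two_folds_four_subjects(self):
        subjects = self._stub_subjects(4)
        trained = []
        results = kfold_self_test(
            subjects, K=2, train_fn=self._stub_train(trained),
            predict_fn=self._stub_predict,
        )
        assert len(trained) == 2  # exactly K models trained
        assert len(results) == 4  # every subject predicted exactly once
        for i, (seg, (probs, model)) in enumerate(results):
            # the model that predicted subject i never trained on it
            assert id(subjects[i][0]) not in model

    def test_leave_one_out_limit(self):
        subjects = self._stub_subjects(3)
        trained = []
        results = kfold_self_test(
            subjects, K=3, train_fn=self._stub_train(trained),
            predict_fn=self._stub_predict,
        )
        assert len(trained) == 3
        assert all(len(ids) == 2 for ids in trained)
        assert len(results) == 3

    def test_fewer_subjects_than_folds_rejected(self):
        with pytest.raises(ValueError):
            kfold_self_test(self._stub_subjects(1), K=2)


class TestConfidenceTraining:
    def test_descent_and_output_range(self):
        """Training on a synthetic (auto, probs, manual) pair reduces the loss."""
        rng = np.random.default_rng(0)
        manual = LabelVolume(rng.integers(0, 4, (32, 32, 32)).astype(np.int16))
        auto = manual.voxels.copy()
        flip = rng.random(auto.shape) < 0.1
        auto[flip] = (auto[flip] + 1) % 4
        auto = LabelVolume(auto.astype(np.int16))
        maps = np.full((4, 32, 32, 32), 0.05, dtype=np.float32)
        for c in range(4):
            maps[c][auto.voxels == c] = 0.85
        probs = ProbabilityMaps(maps / maps.sum(axis=0, keepdims=True))
        from arborseg.seg_model import TrainConfig

        cfg = TrainConfig(patches_per_subject=24, patch_size=16, n_epochs=2, batch_size=4, seed=0)
        model = train_confidence_model([(auto, probs, manual)], cfg)
        assert model.loss_trace[-1] < model.loss_trace[0]
        pred = model.predict_patch(
            np.concatenate(
                [np.eye(4, dtype=np.float32)[auto.voxels[:16, :16, :16]].transpose(3, 0, 1, 2),
                 probs.maps[:, :16, :16, :16]]
            )[None]
        )
        assert pred.min() >= 0.0 and pred.max() <= 1.0

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            train_confidence_model([])

    def test_build_deterministic(self):
        a = build_confidence_model(seed=2)
        b = build_confidence_model(seed=2)
        for k, v in a.net.state_dict().items():
            assert np.array_equal(v, b.net.state_dict()[k])


class TestProbabilityHistograms:
    def _setup(self, flip_fraction):
        rng = np.random.default_rng(3)
        truth = LabelVolume(rng.integers(0, 4, (10, 10, 10)).astype(np.int16))
        auto = truth.voxels.copy()
        flip = rng.random(auto.shape) < flip_fraction
        auto[flip] = (auto[flip] + 1) % 4
        maps = rng.dirichlet(np.ones(4), size=(10, 10, 10)).transpose(3, 0, 1, 2)
        return ProbabilityMaps(maps.astype(np.float32)), LabelVolume(auto.astype(np.int16)), truth

    def test_all_correct_gives_empty_misclassified_histogram(self):
        probs, _, truth = self._setup(0.0)
        h = probability_histograms(probs, truth, truth, class_code=2)
        assert h.empty_mis
        assert not h.empty_correct

    def test_histograms_are_normalized(self):
        probs, auto, truth = self._setup(0.3)
        h = probability_histograms(probs, auto, truth, class_code=2)
        assert h.freq_correct.sum() == pytest.approx(1.0)
        assert h.freq_mis.sum() == pytest.approx(1.0)

    def test_csv_export(self, tmp_path):
        probs, auto, truth = self._setup(0.3)
        h = probability_histograms(probs, auto, truth, class_code=3)
        path = h.to_csv(tmp_path / "hist.csv")
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["bin_edge", "freq_correct", "freq_mis"]
        assert len(df) == len(h.bin_edges) - 1
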