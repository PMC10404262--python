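"""Segmentation backbone: architecture contract, loss, training, inference."""

import numpy as np
import pytest

from arborseg.seg_model import (
    SegModel,
    SegModelConfig,
    TrainConfig,
    build_seg_model,
    predict_segmentation,
    segmentation_loss,
    train_source_model,
)
from arborseg.metrics import dice
from arborseg.types import WM, one_hot

TINY = SegModelConfig(size_scale=0.125)


class TestArchitectureContract:
    def test_forward_shape_and_simplex(self):
        model = build_seg_model(TINY, seed=0)
        x = np.random.default_rng(0).standard_normal((2, 2, 16, 16, 16)).astype(np.float32)
        out = model.predict_patch_probs(x)
        assert out.shape == (2, 4, 16, 16, 16)
        assert out.min() >= 0
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-5)

    def test_same_seed_identical_parameters(self):
        a = build_seg_model(TINY, seed=3)
        b = build_seg_model(TINY, seed=3)
        for k, v in a.net.state_dict().items():
            assert np.array_equal(v, b.net.state_dict()[k]), k

    def test_reference_scale_has_16_kernels_per_conv(self):
        model = build_seg_model(SegModelConfig(), seed=0)
        assert model.config.growth == 16
        assert model.net.db1.convs[0].weight.data.shape[-1] == 16

    def test_seven_dense_blocks_required(self):
        with pytest.raises(ValueError):
            build_seg_model(SegModelConfig(n_dense_blocks=5), seed=0)

    def test_checkpoint_round_trip(self, tmp_path):
        model = build_seg_model(TINY, seed=4)
        path = model.save(tmp_path / "m.npz")
        back = SegModel.load(path)
        x = np.random.default_rng(1).standard_normal((1, 2, 16, 16, 16)).astype(np.float32)
        assert np.allclose(model.predict_patch_probs(x), back.predict_patch_probs(x))


class TestSegmentationLoss:
    def test_perfect_prediction_is_zero(self):
        y = one_hot(np.random.default_rng(0).integers(0, 4, (5, 5, 5)).astype(np.int16))
        assert segmentation_loss(y, y) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_prediction_is_ln4(self):
        y = one_hot(np.random.default_rng(1).integers(0, 4, (5, 5, 5)).astype(np.int16))
        probs = np.full_like(y, 0.25)
        assert segmentation_loss(probs, y) == pytest.approx(np.log(4), abs=1e-6)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_per_voxel_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        probs = rng.dirichlet(np.ones(4), size=(5, 5, 5)).transpose(3, 0, 1, 2)
        y = one_hot(rng.integers(0, 4, (5, 5, 5)).astype(np.int16))
        # independent oracle: explicit per-voxel summation
        expected = 0.0
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    for c in range(4):
                        expected -= y[c, i, j, k] * np.log(max(probs[c, i, j, k], 1e-7))
        expected /= 125
        assert segmentation_loss(probs, y) == pytest.approx(expected, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segmentation_loss(np.zeros((4, 3, 3, 3)), np.zeros((4, 2, 3, 3)))


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_subjects(self):
        from arborseg.phantom import default_base_spec, make_label_phantom, render_intensities

        subs = []
        for seed in (31, 32):
            lab = make_label_phantom((32, 32, 32), branch_depth=2, gm_thickness=2, seed=seed)
            subs.append((render_intensities(lab, default_base_spec(), seed=seed + 10), lab))
        return subs

    def test_loss_descends_over_epochs(self, tiny_subjects):
        cfg = TrainConfig(patches_per_subject=24, patch_size=16, n_epochs=2, batch_size=4, seed=0)
        model = train_source_model(tiny_subjects, cfg, TINY)
        assert len(model.loss_trace) == 2
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_empty_subject_list_rejected(self):
        with pytest.raises(ValueError):
            train_source_model([], TrainConfig(), TINY)

    def test_training_is_deterministic(self, tiny_subjects):
        cfg = TrainConfig(patches_per_subject=8, patch_size=16, n_epochs=1, batch_size=4, seed=5)
        a = train_source_model(tiny_subjects, cfg, TINY)
        b = train_source_model(tiny_subjects, cfg, TINY)
        assert a.loss_trace == b.loss_trace
        for k, v in a.net.state_dict().items():
            assert np.array_equal(v, b.net.state_dict()[k]), k


class TestPrediction:
    def test_labels_equal_argmax_of_probabilities(self):
        from arborseg.phantom import default_base_spec, make_label_phantom, render_intensities

        lab = make_label_phantom((32, 32, 32), branch_depth=2, gm_thickness=2, seed=41)
        vol = render_intensities(lab, default_base_spec(), seed=42)
        model = build_seg_model(TINY, seed=0)
        model.patch_size = 16
        seg, probs = predict_segmentation(model, vol)
        assert seg.shape == vol.shape
        assert np.array_equal(seg.voxels, np.argmax(probs.maps, axis=0))

    def test_prediction_is_deterministic(self):
        from arborseg.phantom import default_base_spec, make_label_phantom, render_intensities

        lab = make_label_phantom((32, 32, 32), branch_depth=2, gm_thickness=2, seed=43)
        vol = render_intensities(lab, default_base_spec(), seed=44)
        model = build_seg_model(TINY, seed=1)
        model.patch_size = 16
        seg_a, probs_a = predict_segmentation(model, vol)
        seg_b, probs_b = predict_segmentation(model, vol)
        assert np.array_equal(seg_a.voxels, seg_b.voxels)
        assert np.array_equal(probs_a.maps, probs_b.maps)

    def test_argmax_tie_breaks_toward_lowest_code(self):
        from arborseg.types import ProbabilityMaps

        maps = np.full((4, 2, 2, 2), 0.25, dtype=np.float32)
        assert (ProbabilityMaps(maps).argmax_labels().voxels == 0).all()
        maps[1] = 0.4
        maps[3] = 0.4
        maps[0] = maps[2] = 0.1
        assert (ProbabilityMaps(maps).argmax_labels().voxels == 1).all()


def test_source_domain_sanity_dice(confidence_runs):
    """A tiny model trained on source phantoms segments a held-out phantom well."""
    bundle = confidence_runs[1]
    seg, _ = bundle["heldout_pred"]
    _, ho_lab = bundle["heldout"]
    assert dice(seg, ho_lab, WM) > 0.8
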