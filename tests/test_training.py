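"""Loss, augmentation, training loop and cross-validation."""

import numpy as np
import pytest

from spinealign.models import build_model, scaled_arch
from spinealign.pipeline import PAIR_SLOTS, build_training_sets, desk_profile
from spinealign.training import (TrainingConfig, TrainingSample, augment_sample,
                                 cross_validate, mse_loss, train_model)


def _sample(rng, shape=(20, 24), n_points=2):
    img = rng.normal(size=shape).astype(np.float32)
    label = rng.uniform(0.2, 0.8, size=2 * n_points).astype(np.float32)
    return TrainingSample(image=img, label=label)


class TestConfig:
    def test_defaults_follow_protocol(self):
        cfg = TrainingConfig()
        assert (cfg.epochs, cfg.batch_size, cfg.dropout, cfg.optimizer,
                cfg.folds) == (50, 32, 0.5, "adadelta", 5)

    @pytest.mark.parametrize("kwargs", [dict(dropout=1.0), dict(folds=1)])
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            TrainingConfig(**kwargs)


class TestAugmentation:
    def test_hflip_involution(self, rng):
        s = _sample(rng)
        pairs = ((0, 1),)
        once = augment_sample(s, "hflip", pair_slots=pairs)
        twice = augment_sample(once, "hflip", pair_slots=pairs)
        np.testing.assert_array_equal(twice.image, s.image)
        np.testing.assert_allclose(twice.label, s.label, atol=1e-6)

    def test_hflip_swaps_pairs(self, rng):
        s = _sample(rng, n_points=2)
        out = augment_sample(s, "hflip", pair_slots=((0, 1),))
        w = s.image.shape[1]
        # point 0 of the flipped sample is the mirrored point 1
        assert out.label[0] == pytest.approx((w - 1) / w - s.label[2], abs=1e-6)
        assert out.label[1] == pytest.approx(s.label[3], abs=1e-6)

    def test_identity_ops(self, rng):
        s = _sample(rng)
        rot0 = augment_sample(s, "rotate", angle_deg=0.0)
        np.testing.assert_allclose(rot0.label, s.label, atol=1e-6)
        sc1 = augment_sample(s, "scale", scale_factor=1.0)
        np.testing.assert_allclose(sc1.label, s.label, atol=1e-6)
        np.testing.assert_allclose(sc1.image, s.image, atol=1e-5)

    def test_rotation_fixes_crop_center(self, rng):
        img = rng.normal(size=(21, 21)).astype(np.float32)
        center = np.array([10.0 / 21, 10.0 / 21], dtype=np.float32)
        s = TrainingSample(image=img, label=np.tile(center, 1))
        out = augment_sample(s, "rotate", angle_deg=90.0)
        np.testing.assert_allclose(out.label, center, atol=1e-6)

    def test_rotation_moves_labels_with_image_content(self, rng):
        # a bright dot away from centre must stay under its label
        img = np.zeros((41, 41), dtype=np.float32)
        img[12, 28] = 100.0
        s = TrainingSample(image=img,
                           label=np.array([28 / 41, 12 / 41], dtype=np.float32))
        out = augment_sample(s, "rotate", angle_deg=25.0)
        x_px, y_px = out.label[0] * 41, out.label[1] * 41
        yy, xx = np.unravel_index(np.argmax(out.image), out.image.shape)
        assert abs(x_px - xx) < 1.5 and abs(y_px - yy) < 1.5

    def test_scaling_moves_labels_with_image_content(self, rng):
        img = np.zeros((41, 41), dtype=np.float32)
        img[26, 14] = 100.0
        s = TrainingSample(image=img,
                           label=np.array([14 / 41, 26 / 41], dtype=np.float32))
        out = augment_sample(s, "scale", scale_factor=1.1)
        x_px, y_px = out.label[0] * 41, out.label[1] * 41
        yy, xx = np.unravel_index(np.argmax(out.image), out.image.shape)
        assert abs(x_px - xx) < 1.5 and abs(y_px - yy) < 1.5

    def test_out_of_range_label_rejected(self, rng, caplog):
        img = rng.normal(size=(30, 30)).astype(np.float32)
        s = TrainingSample(image=img,
                           label=np.array([0.98, 0.02], dtype=np.float32))
        with caplog.at_level("WARNING"):
            out = augment_sample(s, "rotate", angle_deg=45.0)
        assert out is None
        assert "rejected" in caplog.text

    def test_unknown_op_rejected(self, rng):
        with pytest.raises(ValueError):
            augment_sample(_sample(rng), "elastic")


class TestTrainModel:
    def _overfit_setup(self, rng, n=20):
        arch = scaled_arch("third_order", (38, 38), output_units=4,
                          relu_convs=True)
        model = build_model(arch, seed=1)
        samples = [_sample(rng, shape=(38, 38), n_points=2) for _ in range(n)]
        return model, samples

    def test_memorizes_small_sample_set(self, rng):
        # a correct implementation must fit 20 samples far below its
        # first-epoch loss within the 50-epoch protocol
        model, samples = self._overfit_setup(rng)
        _, hist = train_model(model, samples, TrainingConfig(epochs=50, seed=0))
        assert hist["train_loss"][-1] < 0.5 * hist["train_loss"][0]

    def test_zero_variance_labels_converge_to_zero(self, rng):
        model, samples = self._overfit_setup(rng)
        fixed = [TrainingSample(s.image, np.full(4, 0.5, dtype=np.float32))
                 for s in samples]
        _, hist = train_model(model, fixed,
                              TrainingConfig(epochs=60, seed=0, dropout=0.0))
        # Adadelta ramps slowly from cold accumulators; require an order of
        # magnitude of decay toward zero within 60 single-batch epochs
        assert hist["train_loss"][-1] < 0.1 * hist["train_loss"][0]

    def test_same_seed_identical_history(self, rng):
        cfg = TrainingConfig(epochs=2, seed=9)
        m1, samples = self._overfit_setup(rng)
        rng2 = np.random.default_rng(1234)  # same stream as fixture start
        _, h1 = train_model(m1, samples, cfg)
        arch = scaled_arch("third_order", (38, 38), output_units=4,
                          relu_convs=True)
        m2 = build_model(arch, seed=1)
        _, h2 = train_model(m2, samples, cfg)
        assert h1["train_loss"] == h2["train_loss"]

    def test_label_shape_mismatch_rejected(self, rng):
        model, samples = self._overfit_setup(rng)
        bad = [TrainingSample(s.image, s.label[:2]) for s in samples]
        with pytest.raises(ValueError, match="output_units"):
            train_model(model, bad, TrainingConfig(epochs=1))

    def test_empty_dataset_rejected(self, rng):
        model, _ = self._overfit_setup(rng)
        with pytest.raises(ValueError, match="empty"):
            train_model(model, [], TrainingConfig(epochs=1))


class TestCrossValidate:
    def test_folds_partition_dataset(self, rng):
        samples = [_sample(rng, shape=(12, 12), n_points=1) for _ in range(100)]
        cfg = TrainingConfig(epochs=1, folds=5, seed=3)

        def factory(seed):
            arch = scaled_arch("third_order", (12, 12), output_units=2,
                              kernel_scale=0.4)
            return build_model(arch, seed=seed)

        records = cross_validate(samples, cfg, factory)
        assert len(records) == 5
        assert all(r["test_size"] == 20 for r in records)       # 8:2 split
        assert all(r["train_size"] == 80 for r in records)

    def test_same_seed_same_assignment(self, rng):
        n = 30
        cfg = TrainingConfig(epochs=1, folds=5, seed=3)
        perm_a = np.random.default_rng(cfg.seed).permutation(n)
        perm_b = np.random.default_rng(cfg.seed).permutation(n)
        folds_a = [f.tolist() for f in np.array_split(perm_a, cfg.folds)]
        folds_b = [f.tolist() for f in np.array_split(perm_b, cfg.folds)]
        assert folds_a == folds_b
        flat = sorted(i for f in folds_a for i in f)
        assert flat == list(range(n))  # disjoint cover

    def test_dataset_smaller_than_folds_rejected(self, rng):
        samples = [_sample(rng) for _ in range(3)]
        with pytest.raises(ValueError):
            cross_validate(samples, TrainingConfig(epochs=1, folds=5),
                           lambda s: None)


class TestMirrorLabelConsistency:
    def test_hflip_consistent_with_geometry_mirror(self, phantom_pool):
        # re-deriving the unsigned parameters from hflip-augmented landmarks
        # of a full phantom must reproduce the original values
        from spinealign.geometry import (KeyPointSet, PARAMETER_NAMES,
                                         Point2D, compute_all_parameters)

        ann = phantom_pool[0]
        h, w = ann.pixels.shape
        label, names = [], []
        for name, pt in ann.landmarks.as_dict().items():
            names.append(name)
            label.extend([pt.x / w, pt.y / h])
        sample = TrainingSample(image=ann.pixels.astype(np.float32),
                                label=np.array(label, dtype=np.float32))
        pairs = tuple((i, i + 1) for i in range(0, 10, 2))
        flipped = augment_sample(sample, "hflip", pair_slots=pairs)
        pts = flipped.label.reshape(-1, 2) * [w, h]
        kps = KeyPointSet.from_dict(
            {n: Point2D(float(x), float(y)) for n, (x, y) in zip(names, pts)})
        a = compute_all_parameters(ann.landmarks).as_dict()
        b = compute_all_parameters(kps).as_dict()
        for name in PARAMETER_NAMES:
            assert b[name] == pytest.approx(a[name], abs=0.1)
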