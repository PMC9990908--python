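"""Splits, normalization, crop sampling, augmentation, training loop."""

import numpy as np
import pytest

from embryoseg import (
    AugmentConfig,
    LabelVolume,
    ModelConfig,
    PhantomConfig,
    SegModel,
    SplitSpec,
    TrainConfig,
    VolumeImage,
    augment,
    generate_phantom,
    normalize_intensity,
    sample_crop,
    split_dataset,
    train,
)
from embryoseg.training import affine_transform_pair


class TestSplit:
    def test_paperlike_counts(self):
        """96 specimens split 73/18/5 into disjoint exhaustive sets."""
        ids = [f"s{i}" for i in range(96)]
        tr, va, te = split_dataset(ids, SplitSpec(73, 18, 5), seed=0)
        assert (len(tr), len(va), len(te)) == (73, 18, 5)
        assert set(tr) | set(va) | set(te) == set(ids)
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))

    def test_three_singletons(self):
        tr, va, te = split_dataset(["a", "b", "c"], SplitSpec(1, 1, 1), seed=1)
        assert len(tr) == len(va) == len(te) == 1
        assert {tr[0], va[0], te[0]} == {"a", "b", "c"}

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            split_dataset(list(range(90)), SplitSpec(73, 18, 5), seed=0)

    def test_deterministic(self):
        ids = list(range(20))
        a = split_dataset(ids, SplitSpec(10, 5, 5), seed=42)
        b = split_dataset(ids, SplitSpec(10, 5, 5), seed=42)
        assert a == b


class TestNormalize:
    def test_zero_mean_unit_sd(self, rng):
        v = VolumeImage(rng.normal(3.0, 10.0, size=(12, 12, 12)).astype(np.float32))
        n = normalize_intensity(v)
        assert abs(n.data.mean()) < 1e-5
        assert abs(n.data.std() - 1.0) < 1e-5

    def test_constant_maps_to_zero(self):
        v = VolumeImage(np.full((6, 6, 6), 7.0, dtype=np.float32))
        assert np.all(normalize_intensity(v).data == 0.0)

    def test_affine_invariance(self, rng):
        data = rng.normal(size=(10, 10, 10)).astype(np.float32)
        a = normalize_intensity(VolumeImage(data))
        b = normalize_intensity(VolumeImage(2.5 * data + 17.0))
        np.testing.assert_allclose(a.data, b.data, atol=1e-4)

    def test_idempotent(self, rng):
        v = VolumeImage(rng.normal(size=(10, 10, 10)).astype(np.float32))
        once = normalize_intensity(v)
        twice = normalize_intensity(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-6)


class TestSampleCrop:
    def test_bounds(self, rng):
        img = VolumeImage(rng.normal(size=(40, 40, 40)).astype(np.float32))
        lab = LabelVolume(np.zeros((40, 40, 40), dtype=np.int32))
        ic, lc = sample_crop(img, lab, 16, 0)
        assert ic.shape == lc.shape == (16, 16, 16)

    def test_padding_contract(self, rng):
        """A 10^3 volume yields an exact 16^3 crop padded with zeros."""
        img = VolumeImage(np.ones((10, 10, 10), dtype=np.float32))
        lab = LabelVolume(np.ones((10, 10, 10), dtype=np.int32))
        ic, lc = sample_crop(img, lab, 16, 3)
        assert ic.shape == (16, 16, 16)
        assert (ic == 0).sum() == 16**3 - 10**3
        assert (lc == 0).sum() == 16**3 - 10**3

    def test_deterministic_and_foreground_bias(self, rng):
        data = np.zeros((40, 40, 40), dtype=np.float32)
        labs = np.zeros((40, 40, 40), dtype=np.int32)
        labs[16:, 16:, 16:] = 2
        img, lab = VolumeImage(data), LabelVolume(labs)
        a = sample_crop(img, lab, 8, 5)
        b = sample_crop(img, lab, 8, 5)
        np.testing.assert_array_equal(a[0], b[0])
        hits = 0
        for seed in range(10):
            _, lc = sample_crop(img, lab, 8, seed, foreground_biased=True)
            hits += lc.any()
        assert hits >= 9  # biased sampling almost always lands on the blob


class TestAugment:
    def test_zero_magnitudes_identity(self, rng):
        ic = rng.normal(size=(12, 12, 12)).astype(np.float32)
        lc = rng.integers(0, 3, size=(12, 12, 12)).astype(np.int32)
        oi, ol = augment(ic, lc, AugmentConfig.none(), 0)
        np.testing.assert_array_equal(oi, ic)
        np.testing.assert_array_equal(ol, lc)

    def test_label_alphabet_never_grows(self, rng):
        ic = rng.normal(size=(16, 16, 16)).astype(np.float32)
        lc = np.zeros((16, 16, 16), dtype=np.int32)
        lc[4:9, 4:9, 4:9] = 2
        lc[10:13, 10:13, 10:13] = 5
        aug = AugmentConfig(rotate_deg=25, scale=0.2, shear=0.1,
                            intensity_shift=0.3, noise_sd=0.1)
        for seed in range(5):
            _, ol = augment(ic, lc, aug, seed)
            assert set(np.unique(ol)) <= set(np.unique(lc))

    def test_right_angle_rotation_roundtrip(self, rng):
        """90-degree rotation then its inverse reproduces the crop exactly."""
        ic = rng.normal(size=(10, 10, 10)).astype(np.float64)
        lc = rng.integers(0, 4, size=(10, 10, 10)).astype(np.int32)
        rot = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        fi, fl = affine_transform_pair(ic, lc, rot)
        bi, bl = affine_transform_pair(fi, fl, rot.T)
        np.testing.assert_allclose(bi, ic, atol=1e-10)
        np.testing.assert_array_equal(bl, lc)

    def test_intensity_transforms_leave_labels(self, rng):
        ic = rng.normal(size=(8, 8, 8)).astype(np.float32)
        lc = rng.integers(0, 3, size=(8, 8, 8)).astype(np.int32)
        aug = AugmentConfig(rotate_deg=0, scale=0, shear=0,
                            intensity_shift=0.5, noise_sd=0.2)
        oi, ol = augment(ic, lc, aug, 1)
        np.testing.assert_array_equal(ol, lc)
        assert not np.array_equal(oi, ic)


@pytest.fixture(scope="module")
def tiny_pair():
    cfg = PhantomConfig(shape=(32, 32, 32), n_organs=3, seed=17)
    return generate_phantom(cfg)


class TestTrainLoop:
    def test_loss_decreases_and_history(self, tiny_pair):
        """A few steps of overfitting reduce the training loss."""
        model = SegModel(ModelConfig.tiny(n_classes=4, input_size=32), seed=0)
        cfg = TrainConfig.tiny(iterations=30, crop_size=32, seed=0, val_interval=30)
        model, hist = train(model, [tiny_pair], [], cfg)
        assert len(hist) == 30
        first = np.mean([h["train_loss"] for h in hist[:5]])
        last = np.mean([h["train_loss"] for h in hist[-5:]])
        assert last < first

    def test_validation_rows_and_determinism(self, tiny_pair):
        """iterations=val_interval gives exactly one validation row; reruns match."""
        def run():
            model = SegModel(ModelConfig.tiny(n_classes=4, input_size=32), seed=1)
            cfg = TrainConfig.tiny(iterations=10, crop_size=32, seed=1, val_interval=10)
            return train(model, [tiny_pair], [tiny_pair], cfg)[1]

        h1, h2 = run(), run()
        assert [r for r in h1 if "val_dice" in r] == [r for r in h1 if r["step"] == 10]
        assert h1 == h2

    def test_empty_train_set_rejected(self):
        model = SegModel(ModelConfig.tiny(n_classes=4, input_size=16), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(model, [], [], TrainConfig.tiny(iterations=1, crop_size=16))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(iterations=0)
        with pytest.raises(ValueError):
            TrainConfig(iterations=10, val_interval=20)
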