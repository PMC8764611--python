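"""Windowing, resizing, DICOM IO, augmentation, balancing and splits."""

import numpy as np
import pytest

from ascites_resunet import (
    AugmentSpec,
    HUSlice,
    PhantomSpec,
    WindowSpec,
    apply_window,
    augment_pair,
    balance_and_augment,
    generate_dataset,
    read_dicom_slice,
    resize_image,
    resize_mask,
    split_train_test,
    to_model_input,
)
from ascites_resunet.phantom import DatasetEntry, PhantomDataset
from ascites_resunet.preprocess import (
    apply_augment,
    draw_augment,
    materialize,
    write_dicom_slice,
)


class TestWindowing:
    @pytest.mark.parametrize(
        "hu,expected",
        [(-140.0, 0.0), (260.0, 1.0), (60.0, 0.5), (100.0, 0.6), (-1000.0, 0.0), (1000.0, 1.0)],
    )
    def test_abdomen_window_values(self, hu, expected):
        out = apply_window(np.array([[hu]]))
        assert out[0, 0] == pytest.approx(expected)

    def test_monotone_in_hu(self):
        hu = np.linspace(-1200, 1200, 4801)
        out = apply_window(hu[None, :])[0]
        assert np.all(np.diff(out) >= 0)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_custom_window(self):
        w = WindowSpec(width=100, level=0)
        assert apply_window(np.array([[-50.0]]), w)[0, 0] == 0.0
        assert apply_window(np.array([[50.0]]), w)[0, 0] == 1.0
        with pytest.raises(ValueError):
            WindowSpec(width=0)


class TestDicomIO:
    def test_rescale_arithmetic(self, tmp_path):
        """stored * slope + intercept: 700 * 2 - 1000 = 400 HU."""
        import pydicom

        hu = HUSlice(np.full((8, 8), 0.0, dtype=np.float32))
        path = tmp_path / "s.dcm"
        write_dicom_slice(hu, path)
        ds = pydicom.dcmread(str(path))
        ds.RescaleSlope = "2"
        ds.RescaleIntercept = "-1000"
        arr = np.full((8, 8), 700, dtype=np.uint16)
        ds.PixelData = arr.tobytes()
        ds.save_as(str(path))
        back = read_dicom_slice(path)
        assert back.pixels[0, 0] == pytest.approx(400.0)

    def test_round_trip_exact(self, tmp_path, small_spec):
        from ascites_resunet.phantom import generate_slice

        hu, _ = generate_slice(small_spec)
        write_dicom_slice(hu, tmp_path / "p.dcm")
        back = read_dicom_slice(tmp_path / "p.dcm")
        np.testing.assert_array_equal(hu.pixels, back.pixels)
        assert back.pixel_spacing_mm[0] == pytest.approx(hu.pixel_spacing_mm[0])
        assert back.slice_thickness_mm == pytest.approx(hu.slice_thickness_mm)

    def test_missing_rescale_tag_named(self, tmp_path):
        import pydicom

        hu = HUSlice(np.zeros((8, 8), dtype=np.float32))
        path = tmp_path / "bad.dcm"
        write_dicom_slice(hu, path)
        ds = pydicom.dcmread(str(path))
        del ds.RescaleSlope
        ds.save_as(str(path))
        with pytest.raises(ValueError, match="RescaleSlope"):
            read_dicom_slice(path)


class TestResizing:
    def test_constant_image_stays_constant(self):
        out = resize_image(np.full((16, 16), 0.3), 8)
        np.testing.assert_allclose(out, 0.3)
        assert out.shape == (8, 8)

    def test_checkerboard_halved_averages_to_half(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        out = resize_image(board.astype(float), 2)
        np.testing.assert_allclose(out, 0.5)

    def test_extrema_within_input_range(self, small_spec):
        from ascites_resunet.phantom import generate_slice

        hu, _ = generate_slice(small_spec)
        out = resize_image(hu.pixels, 32)
        assert out.min() >= hu.pixels.min() and out.max() <= hu.pixels.max()

    def test_upsizing_rejected(self):
        with pytest.raises(ValueError):
            resize_image(np.zeros((8, 8)), 16)
        with pytest.raises(ValueError):
            resize_mask(np.zeros((8, 8), dtype=np.uint8), 16)

    def test_mask_resize_stays_binary(self):
        ones = np.ones((16, 16), dtype=np.uint8)
        np.testing.assert_array_equal(resize_mask(ones, 8), np.ones((8, 8)))
        empty = np.zeros((16, 16), dtype=np.uint8)
        assert resize_mask(empty, 8).sum() == 0

    def test_small_block_survives_nearest_neighbour(self):
        """A 2x2 positive block at even coordinates keeps exactly one
        pixel after 2x nearest-neighbour down-sampling."""
        mask = np.zeros((512, 512), dtype=np.uint8)
        mask[100:102, 240:242] = 1
        out = resize_mask(mask, 256)
        assert int(out.sum()) == 1

    def test_nonbinary_mask_rejected(self):
        with pytest.raises(ValueError):
            resize_mask(np.full((8, 8), 0.5), 4)


class TestModelInput:
    def test_channel_replication(self):
        g = np.random.default_rng(0).uniform(0, 1, (8, 8))
        x = to_model_input(g)
        assert x.shape == (8, 8, 3)
        np.testing.assert_array_equal(x[:, :, 0], x[:, :, 1])
        np.testing.assert_array_equal(x[:, :, 0], x[:, :, 2])
        assert x.max() == g.max()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            to_model_input(np.full((4, 4), 1.5))


class TestAugmentation:
    def test_identity_spec(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (16, 16, 3))
        mask = (rng.random((16, 16)) > 0.7).astype(np.uint8)
        spec = AugmentSpec(rotation_range_deg=(0, 0), allow_horizontal_flip=False,
                           allow_vertical_flip=False)
        out_img, out_mask = augment_pair(img, mask, spec)
        np.testing.assert_allclose(out_img, img)
        np.testing.assert_array_equal(out_mask, mask)

    def test_flip_involution_and_cardinality(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (16, 16, 3))
        mask = (rng.random((16, 16)) > 0.7).astype(np.uint8)
        once_i, once_m = apply_augment(img, mask, 0.0, True, False)
        twice_i, twice_m = apply_augment(once_i, once_m, 0.0, True, False)
        np.testing.assert_allclose(twice_i, img)
        np.testing.assert_array_equal(twice_m, mask)
        assert once_m.sum() == mask.sum()  # pure flips preserve cardinality

    def test_same_transform_applied_to_image_and_mask(self):
        img = np.zeros((32, 32, 3))
        mask = np.zeros((32, 32), dtype=np.uint8)
        img[4:8, 4:8] = 1.0
        mask[4:8, 4:8] = 1
        out_img, out_mask = augment_pair(img, mask, AugmentSpec(seed=4))
        np.testing.assert_array_equal((out_img[:, :, 0] > 0.5).astype(np.uint8), out_mask)

    def test_angles_bounded_over_many_draws(self):
        spec = AugmentSpec(seed=0)
        rng = np.random.default_rng(0)
        angles = [draw_augment(spec, rng)[0] for _ in range(1000)]
        assert min(angles) >= -10.0 and max(angles) <= 10.0
        assert max(angles) > 5.0 and min(angles) < -5.0  # draws fill the range

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            apply_augment(np.zeros((8, 8, 3)), np.zeros((16, 16), dtype=np.uint8), 0, False, False)

    def test_asymmetric_rotation_range_rejected(self):
        with pytest.raises(ValueError):
            AugmentSpec(rotation_range_deg=(-5, 10))


def _manifest_only_dataset(n_pos, n_neg):
    entries = [
        DatasetEntry(subject_id=f"p{i}", slice_index=0, has_ascites=True)
        for i in range(n_pos)
    ] + [
        DatasetEntry(subject_id=f"n{i}", slice_index=0, has_ascites=False)
        for i in range(n_neg)
    ]
    return PhantomDataset(entries)


class TestBalanceAndAugment:
    def test_balances_to_target(self):
        ds = _manifest_only_dataset(30, 70)
        out = balance_and_augment(ds, 70, AugmentSpec(seed=0))
        assert out.class_counts == {True: 70, False: 70}

    def test_target_equal_leaves_unchanged(self):
        ds = _manifest_only_dataset(5, 5)
        out = balance_and_augment(ds, 5, AugmentSpec(seed=0))
        assert len(out) == 10
        assert all(e.augment_of is None for e in out.entries)

    def test_never_discards_originals(self):
        ds = _manifest_only_dataset(30, 70)
        with pytest.raises(ValueError, match="discard"):
            balance_and_augment(ds, 50, AugmentSpec(seed=0))

    def test_cohort_scale_augmentation_total(self):
        """1969 + 4368 originals balanced to 24,437 per class yield the
        48,874-image augmented manifest."""
        ds = _manifest_only_dataset(1969, 4368)
        out = balance_and_augment(ds, 24437, AugmentSpec(seed=0))
        assert len(out) == 48874
        assert out.class_counts == {True: 24437, False: 24437}
        originals = [e for e in out.entries if e.augment_of is None]
        assert len(originals) == 1969 + 4368


class TestSplit:
    def test_subject_level_split_is_stratified(self, small_dataset):
        train, test = split_train_test(small_dataset, 0.5, seed=0)
        tl = train.subject_labels()
        el = test.subject_labels()
        assert sum(tl.values()) == 2 and sum(el.values()) == 2

    def test_no_subject_straddles_partitions(self, small_dataset):
        for seed in range(50):
            train, test = split_train_test(small_dataset, 0.6, seed=seed)
            assert not (set(train.subject_ids) & set(test.subject_ids))
            assert len(train.subject_ids) + len(test.subject_ids) == 8

    def test_cohort_scale_ratio(self):
        entries = []
        for i in range(100):
            entries.append(DatasetEntry(f"a{i}", 0, True))
            entries.append(DatasetEntry(f"c{i}", 0, False))
        ds = PhantomDataset(entries)
        train, test = split_train_test(ds, 0.8, seed=1)
        tl = train.subject_labels()
        assert sum(tl.values()) == 80 and len(tl) == 160
        el = test.subject_labels()
        assert sum(el.values()) == 20 and len(el) == 40

    def test_too_few_subjects_rejected(self):
        ds = _manifest_only_dataset(1, 4)
        with pytest.raises(ValueError, match="at least 2 subjects"):
            split_train_test(ds, 0.8, seed=0)


class TestMaterialize:
    def test_pipeline_output_contracts(self, small_dataset):
        aug = balance_and_augment(small_dataset, 20, AugmentSpec(seed=2))
        X, y, labels = materialize(aug, target_size=32, augment=AugmentSpec(seed=2))
        assert X.shape == (40, 32, 32, 3) and y.shape == (40, 32, 32)
        assert X.min() >= 0.0 and X.max() <= 1.0
        assert set(np.unique(y)) <= {0, 1}
        assert labels.sum() == 20
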