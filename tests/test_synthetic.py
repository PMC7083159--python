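"""Synthetic image/dataset generator and the tiny-CNN model factory."""

import numpy as np
import pytest

from crmloc.exceptions import InputError
from crmloc.preprocess import mask_to_bbox
from crmloc.saliency import FeatureStack, crm_bruteforce, crm_closed_form
from crmloc.synthetic import (
    TinyCnnSpec,
    build_tiny_cnn,
    generate_dataset,
    generate_sample,
    load_adapter,
    save_adapter,
    split_dataset,
    train_head,
)


class TestGenerateSample:
    def test_normal_sample_has_no_boxes(self):
        s = generate_sample(seed=3, n_lesions=0)
        assert s.label == "normal" and s.lesion_boxes == ()

    def test_same_seed_bit_identical(self):
        a = generate_sample(seed=9, n_lesions=2)
        b = generate_sample(seed=9, n_lesions=2)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask.values, b.mask.values)
        assert a.lesion_boxes == b.lesion_boxes

    def test_two_lesions_disjoint_and_inside_mask_bbox(self):
        s = generate_sample(seed=4, n_lesions=2)
        assert len(s.lesion_boxes) == 2
        mb = mask_to_bbox(s.mask)
        for box in s.lesion_boxes:
            assert box.x_min >= mb.x_min and box.x_max <= mb.x_max
            assert box.y_min >= mb.y_min and box.y_max <= mb.y_max
        a, b = s.lesion_boxes
        from crmloc.localization import iou

        assert iou(a, b) == 0.0

    def test_image_in_unit_range(self):
        s = generate_sample(seed=1, n_lesions=2)
        assert s.image.min() >= 0.0 and s.image.max() <= 1.0

    def test_parameter_validation(self):
        with pytest.raises(InputError):
            generate_sample(seed=0, size=16)
        with pytest.raises(InputError):
            generate_sample(seed=0, contrast=0.0)


class TestGenerateDataset:
    def test_class_counts_match_fraction(self):
        samples, _ = generate_dataset(100, 0.5, seed=0)
        assert sum(s.y for s in samples) == 50

    def test_label_box_consistency_for_every_sample(self):
        samples, _ = generate_dataset(40, 0.4, seed=2)
        for s in samples:
            assert (s.label == "normal") == (len(s.lesion_boxes) == 0)

    def test_manifest_row_count_is_normals_plus_boxes(self):
        samples, manifest = generate_dataset(60, 0.5, seed=5)
        n_normal = sum(1 for s in samples if s.y == 0)
        n_boxes = sum(len(s.lesion_boxes) for s in samples)
        assert len(manifest) == n_normal + n_boxes

    def test_different_master_seeds_give_disjoint_streams(self):
        a, _ = generate_dataset(10, 0.5, seed=1)
        b, _ = generate_dataset(10, 0.5, seed=2)
        for sa, sb in zip(a, b):
            assert not np.array_equal(sa.image, sb.image)

    def test_reproducible_manifest(self):
        _, m1 = generate_dataset(20, 0.5, seed=11)
        _, m2 = generate_dataset(20, 0.5, seed=11)
        assert m1.equals(m2)

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(InputError):
            generate_dataset(10, 0.0, seed=0)
        with pytest.raises(InputError):
            generate_dataset(1, 0.5, seed=0)


class TestSplit:
    def test_parts_are_disjoint_and_cover(self):
        samples, _ = generate_dataset(50, 0.5, seed=1)
        splits = split_dataset(samples, seed=0)
        ids = [s.image_id for part in splits.values() for s in part]
        assert sorted(ids) == sorted(s.image_id for s in samples)
        assert len(set(ids)) == len(ids)

    def test_invalid_fractions(self):
        samples, _ = generate_dataset(10, 0.5, seed=1)
        with pytest.raises(InputError):
            split_dataset(samples, fractions=(0.5, 0.5, 0.5))


class TestTinyCnnSpec:
    def test_depth_one_has_three_blocks(self):
        assert TinyCnnSpec(image_size=64, depth=1).n_blocks == 3

    def test_kernel_formula_and_doubling(self):
        spec = TinyCnnSpec(image_size=64, depth=4)
        assert spec.kernels_initial == 32  # ceil(64 / 2)
        assert spec.n_blocks == 12
        assert spec.section_kernels == (32, 64, 128)

    def test_invalid_depth(self):
        with pytest.raises(InputError):
            TinyCnnSpec(image_size=64, depth=0)


class TestTinyCnnAdapter:
    def test_feature_shape_and_determinism(self):
        adapter = build_tiny_cnn(TinyCnnSpec(image_size=64, depth=1), seed=7)
        image = generate_sample(seed=1, n_lesions=1).image
        a = adapter.features(image)
        b = build_tiny_cnn(TinyCnnSpec(image_size=64, depth=1), seed=7).features(image)
        assert a.values.shape == adapter.feature_shape == (8, 8, 256)
        np.testing.assert_array_equal(a.values, b.values)

    def test_deep_spec_keeps_spatial_resolution(self):
        adapter = build_tiny_cnn(TinyCnnSpec(image_size=64, depth=4), seed=0)
        assert adapter.feature_shape[0] >= 4

    def test_linear_head_descriptor_agrees_with_head_forward(self, rng):
        """The adapter's (W, b) descriptor must reproduce its own logits."""
        adapter = build_tiny_cnn(TinyCnnSpec(image_size=64, depth=1), seed=3)
        stack = adapter.features(generate_sample(seed=2, n_lesions=1).image)
        logits = adapter.head_forward(stack).scores
        u, v, _ = stack.values.shape
        manual = (
            stack.values.reshape(u * v, -1).sum(axis=0) / (u * v)
        ) @ adapter.head.W + adapter.head.b
        np.testing.assert_allclose(logits, manual, rtol=1e-5)

    def test_closed_form_crm_matches_bruteforce_on_real_adapter(self):
        adapter = build_tiny_cnn(TinyCnnSpec(image_size=32, depth=1), seed=5)
        stack = adapter.features(generate_sample(seed=6, size=32).image)
        closed = crm_closed_form(stack, adapter.linear_head).values
        brute = crm_bruteforce(adapter, stack).values
        np.testing.assert_allclose(closed, brute, rtol=1e-9, atol=1e-15)

    def test_untrained_probabilities_near_half(self):
        adapter = build_tiny_cnn(TinyCnnSpec(image_size=64, depth=1), seed=1)
        p = adapter.predict_proba(generate_sample(seed=1).image)
        assert abs(p[0] - 0.5) < 0.2 and p.sum() == pytest.approx(1.0)

    def test_checkpoint_roundtrip(self, tmp_path):
        adapter = build_tiny_cnn(TinyCnnSpec(image_size=32, depth=1), seed=9,
                                 source_id="ckpt-test")
        image = generate_sample(seed=4, size=32).image
        path = tmp_path / "model.npz"
        save_adapter(adapter, path)
        loaded = load_adapter(path)
        assert loaded.source_id == "ckpt-test"
        np.testing.assert_array_equal(
            adapter.predict_proba(image), loaded.predict_proba(image)
        )


class TestTrainHead:
    @staticmethod
    def _tiny_problem(rng, n=60, k=12):
        """Two well-separated Gaussian clusters along a random direction."""
        X = rng.normal(size=(n, k))
        y = rng.integers(0, 2, n)
        direction = rng.normal(size=k)
        direction /= np.linalg.norm(direction)
        X += np.outer(2.0 * y - 1.0, direction) * 2.0
        return X, y

    def test_zero_epochs_keeps_near_uniform_head(self, rng):
        adapter = build_tiny_cnn(TinyCnnSpec(image_size=32, depth=1), seed=2)
        k = adapter.feature_shape[2]
        X, y = self._tiny_problem(rng, k=k)
        train_head(adapter, X[:40], y[:40], X[40:], y[40:], epochs=0, seed=0)
        stack = adapter.features(generate_sample(seed=3, size=32).image)
        p = adapter.head_forward(stack, "probability").scores
        assert abs(p[0] - 0.5) < 0.25

    def test_learns_linearly_separable_features(self, rng):
        adapter = build_tiny_cnn(TinyCnnSpec(image_size=32, depth=1), seed=2)
        k = adapter.feature_shape[2]
        X, y = self._tiny_problem(rng, n=200, k=k)
        train_head(adapter, X[:150], y[:150], X[150:], y[150:], epochs=10, seed=0)
        logits = X[150:] @ adapter.head.W + adapter.head.b
        acc = ((logits[:, 0] > logits[:, 1]).astype(int) == y[150:]).mean()
        assert acc >= 0.9

    def test_deterministic_for_fixed_seed(self, rng):
        X, y = self._tiny_problem(rng, n=80, k=256)
        heads = []
        for _ in range(2):
            adapter = build_tiny_cnn(TinyCnnSpec(image_size=64, depth=1), seed=4)
            train_head(adapter, X[:60], y[:60], X[60:], y[60:], epochs=5, seed=1)
            heads.append((adapter.head.W.copy(), adapter.head.b.copy()))
        np.testing.assert_array_equal(heads[0][0], heads[1][0])
        np.testing.assert_array_equal(heads[0][1], heads[1][1])
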