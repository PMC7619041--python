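"""Mixing laws: blend, masked paste, region mix, and the post-mix opening."""

import numpy as np
import pytest

from prmix.data_model import extract_primary_mask
from prmix.mixers import (
    MixConfig,
    carve_mask,
    masked_mix,
    mixup,
    morphological_opening,
    prmix_multi,
    prmix_pair,
    rectangle_mask,
)
from prmix.oaa import RegionAbsentError, SearchConfig, oaa

from conftest import make_sample

IDENTITY_SEARCH = SearchConfig(
    rotation_range=(0.0, 0.0), scale_range=(1.0, 1.0), translation_range=(0.0, 0.0)
)


class TestMixup:
    def test_endpoints_return_inputs_bit_exactly(self, toy_taxonomy):
        rng = np.random.default_rng(0)
        s = make_sample(rng.integers(0, 4, (5, 5)), sample_id="s", rng=rng)
        t = make_sample(rng.integers(0, 4, (5, 5)), sample_id="t", rng=rng)
        at_one = mixup(s, t, 1.0)
        np.testing.assert_array_equal(at_one.image, s.image)
        np.testing.assert_array_equal(at_one.argmax_labels(), s.labels)
        at_zero = mixup(s, t, 0.0)
        np.testing.assert_array_equal(at_zero.image, t.image)
        np.testing.assert_array_equal(at_zero.argmax_labels(), t.labels)

    def test_halfway_blend_arithmetic(self):
        s = make_sample(np.zeros((2, 2), dtype=int), sample_id="s")
        t = make_sample(np.zeros((2, 2), dtype=int), sample_id="t")
        s.image[:] = 0.2
        t.image[:] = 0.6
        out = mixup(s, t, 0.5)
        np.testing.assert_allclose(out.image, 0.4)

    def test_weights_sum_to_one_and_convexity(self):
        rng = np.random.default_rng(3)
        s = make_sample(rng.integers(0, 4, (6, 6)), sample_id="s", rng=rng)
        t = make_sample(rng.integers(0, 4, (6, 6)), sample_id="t", rng=rng)
        lam = 0.37
        out = mixup(s, t, lam)
        np.testing.assert_allclose(out.weights.sum(axis=-1), 1.0)
        lo = np.minimum(s.image, t.image)
        hi = np.maximum(s.image, t.image)
        assert np.all(out.image >= lo - 1e-12) and np.all(out.image <= hi + 1e-12)

    def test_lambda_outside_unit_interval_rejected(self):
        s = make_sample(np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError):
            mixup(s, s, 1.5)


class TestMaskedMix:
    def test_all_false_mask_returns_target(self):
        s = make_sample(np.ones((4, 4), dtype=int), sample_id="s")
        t = make_sample(np.full((4, 4), 2), sample_id="t")
        out = masked_mix(s, t, np.zeros((4, 4), dtype=bool))
        np.testing.assert_array_equal(out.image, t.image)
        np.testing.assert_array_equal(out.labels, t.labels)

    def test_all_true_mask_returns_source(self):
        s = make_sample(np.ones((4, 4), dtype=int), sample_id="s")
        t = make_sample(np.full((4, 4), 2), sample_id="t")
        out = masked_mix(s, t, np.ones((4, 4), dtype=bool))
        np.testing.assert_array_equal(out.image, s.image)
        np.testing.assert_array_equal(out.labels, s.labels)

    def test_rectangle_mix_matches_per_pixel_composition(self):
        rng = np.random.default_rng(4)
        s = make_sample(rng.integers(0, 4, (4, 4)), sample_id="s", rng=rng)
        t = make_sample(rng.integers(0, 4, (4, 4)), sample_id="t", rng=rng)
        mask = rectangle_mask((4, 4), 1, 1, 2, 2)
        out = masked_mix(s, t, mask)
        for i in range(4):
            for j in range(4):
                if mask[i, j]:
                    assert out.labels[i, j] == s.labels[i, j]
                    np.testing.assert_array_equal(out.image[i, j], s.image[i, j])
                else:
                    assert out.labels[i, j] == t.labels[i, j]
                    np.testing.assert_array_equal(out.image[i, j], t.image[i, j])

    def test_carve_mask_is_semantic(self):
        labels = np.array([[1, 2], [3, 0]])
        np.testing.assert_array_equal(
            carve_mask(labels, [1, 3]), np.array([[True, False], [True, False]])
        )


class TestPRMixPair:
    def test_empty_region_list_returns_target_bit_exactly(self, toy_taxonomy):
        rng = np.random.default_rng(0)
        s = make_sample(rng.integers(0, 4, (8, 8)), sample_id="s", rng=rng)
        t = make_sample(rng.integers(0, 4, (8, 8)), sample_id="t", rng=rng)
        out = prmix_pair(s, t, [], toy_taxonomy, rng=rng)
        np.testing.assert_array_equal(out.sample.image, t.image)
        np.testing.assert_array_equal(out.sample.labels, t.labels)
        assert out.replaced == {}

    def test_perfect_slot_substitutes_source_content(self, toy_taxonomy):
        # source and target share region geometry; identity transform
        labels_t = np.zeros((12, 12), dtype=np.int64)
        labels_t[3:9, 2:8] = 1
        labels_t[3:6, 9:11] = 3
        labels_s = labels_t.copy()
        labels_s[3:9, 2:8] = 2  # different subregion, same primary
        rng = np.random.default_rng(1)
        s = make_sample(labels_s, sample_id="s", rng=rng)
        t = make_sample(labels_t, sample_id="t", rng=rng)
        cfg = MixConfig(search=IDENTITY_SEARCH, regions_per_mix=(1, 1))
        out = prmix_pair(s, t, [1], toy_taxonomy, cfg, np.random.default_rng(2))
        region = labels_t == 1
        np.testing.assert_array_equal(out.sample.labels[region], labels_s[region])
        np.testing.assert_array_equal(out.sample.image[region], s.image[region])
        np.testing.assert_array_equal(out.sample.labels[~region], labels_t[~region])
        np.testing.assert_array_equal(out.sample.image[~region], t.image[~region])

    def test_output_matches_per_pixel_composition_given_placement(self, toy_taxonomy):
        rng = np.random.default_rng(7)
        labels_s = np.zeros((16, 16), dtype=np.int64)
        labels_s[2:9, 2:9] = 1
        labels_t = np.zeros((16, 16), dtype=np.int64)
        labels_t[6:13, 5:12] = 2
        s = make_sample(labels_s, sample_id="s", rng=rng)
        t = make_sample(labels_t, sample_id="t", rng=rng)
        cfg = MixConfig(search=SearchConfig(translation_range=(-2, 2), shift_range=(-3, 3), stepsize=1))
        # replicate the single oaa call with an identically seeded generator
        res = oaa(s, t, 1, toy_taxonomy, cfg.search, np.random.default_rng(42))
        out = prmix_pair(s, t, [1], toy_taxonomy, cfg, np.random.default_rng(42))
        Mtp = labels_t == 0  # placeholder, recomputed below
        Mtp = extract_primary_mask(labels_t, toy_taxonomy, 1).mask
        expect_lab = t.labels.copy()
        expect_img = t.image.copy()
        expect_lab[Mtp] = 0
        expect_img[Mtp] = 0.0
        expect_lab[res.mask] = res.labels_patch[res.mask]
        expect_img[res.mask] = res.image_patch[res.mask]
        np.testing.assert_array_equal(out.sample.labels, expect_lab)
        np.testing.assert_array_equal(out.sample.image, expect_img)

    def test_absent_region_raises_when_strict(self, toy_taxonomy):
        s = make_sample(np.zeros((6, 6), dtype=np.int64), sample_id="s")
        t = make_sample(np.full((6, 6), 1), sample_id="t")
        with pytest.raises(RegionAbsentError):
            prmix_pair(s, t, [1], toy_taxonomy, rng=np.random.default_rng(0))

    def test_retain_mode_keeps_vacated_target_content(self, toy_taxonomy):
        labels_t = np.zeros((12, 12), dtype=np.int64)
        labels_t[2:10, 2:10] = 1  # big target region
        labels_s = np.zeros((12, 12), dtype=np.int64)
        labels_s[4:7, 4:7] = 1  # small source region
        rng = np.random.default_rng(3)
        s = make_sample(labels_s, sample_id="s", rng=rng)
        t = make_sample(labels_t, sample_id="t", rng=rng)
        cfg = MixConfig(search=IDENTITY_SEARCH, vacated_mode="retain")
        out = prmix_pair(s, t, [1], toy_taxonomy, cfg, np.random.default_rng(0))
        vacated = (labels_t == 1) & (out.sample.labels != 1)
        # uncovered target-region pixels keep their original content
        uncovered = (labels_t == 1) & (labels_s != 1)
        np.testing.assert_array_equal(out.sample.labels[uncovered], labels_t[uncovered])
        assert not vacated.any()


class TestPRMixMulti:
    def test_single_source_single_region_reduces_to_pair(self, toy_taxonomy):
        rng = np.random.default_rng(5)
        labels = np.zeros((12, 12), dtype=np.int64)
        labels[2:8, 2:8] = 1
        labels[9:11, 2:6] = 3
        s = make_sample(labels, sample_id="s", rng=rng)
        t = make_sample(np.roll(labels, 1, axis=0), sample_id="t", rng=rng)
        cfg = MixConfig(regions_per_mix=(1, 1), search=IDENTITY_SEARCH)
        multi = prmix_multi([s], t, toy_taxonomy, cfg, np.random.default_rng(9))
        assert len(multi.replaced) == 1
        (p,) = multi.replaced
        pair = prmix_pair(s, t, [p], toy_taxonomy, cfg, np.random.default_rng(123))
        # identity search: placement is deterministic, so outputs agree
        np.testing.assert_array_equal(multi.sample.labels, pair.sample.labels)
        np.testing.assert_array_equal(multi.sample.image, pair.sample.image)

    def test_replaced_count_within_configured_range(self, phantom_dataset):
        samples, tax = phantom_dataset
        cfg = MixConfig(regions_per_mix=(2, 4))
        for seed in range(5):
            res = prmix_multi(
                samples[1:3], samples[0], tax, cfg, np.random.default_rng(seed)
            )
            assert 1 <= res.n_replaced <= 4

    def test_label_conservation(self, phantom_dataset):
        samples, tax = phantom_dataset
        cfg = MixConfig(regions_per_mix=(2, 4))
        res = prmix_multi(samples[1:3], samples[0], tax, cfg, np.random.default_rng(0))
        inputs = set(np.unique(samples[0].labels))
        for s in samples[1:3]:
            inputs |= set(np.unique(s.labels))
        assert set(np.unique(res.sample.labels)) <= inputs

    def test_same_seed_bit_identical(self, phantom_dataset):
        samples, tax = phantom_dataset
        cfg = MixConfig(regions_per_mix=(2, 4))
        a = prmix_multi(samples[1:3], samples[0], tax, cfg, np.random.default_rng(77))
        b = prmix_multi(samples[1:3], samples[0], tax, cfg, np.random.default_rng(77))
        np.testing.assert_array_equal(a.sample.labels, b.sample.labels)
        np.testing.assert_array_equal(a.sample.image, b.sample.image)
        assert a.replaced == b.replaced and a.diagnostics == b.diagnostics

    def test_no_eligible_region_returns_target_unchanged(self, toy_taxonomy, caplog):
        s = make_sample(np.zeros((6, 6), dtype=np.int64), sample_id="s")
        t = make_sample(np.full((6, 6), 1), sample_id="t")
        with caplog.at_level("WARNING"):
            res = prmix_multi([s], t, toy_taxonomy, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(res.sample.labels, t.labels)
        assert res.replaced == {}

    def test_untouched_regions_bit_identical_to_target(self, phantom_dataset):
        samples, tax = phantom_dataset
        cfg = MixConfig(regions_per_mix=(2, 3))
        rng = np.random.default_rng(4)
        res = prmix_multi(samples[1:3], samples[0], tax, cfg, rng)
        touched = np.zeros(samples[0].shape, dtype=bool)
        for p in res.replaced:
            touched |= extract_primary_mask(samples[0].labels, tax, p).mask
            touched |= extract_primary_mask(res.sample.labels, tax, p).mask
        np.testing.assert_array_equal(
            res.sample.labels[~touched], samples[0].labels[~touched]
        )
        np.testing.assert_array_equal(
            res.sample.image[~touched], samples[0].image[~touched]
        )


class TestMorphologicalOpening:
    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 5, (10, 10))
        np.testing.assert_array_equal(morphological_opening(labels, 0), labels)

    def test_protrusion_removed_body_intact(self):
        labels = np.zeros((9, 9), dtype=np.int64)
        labels[2:7, 2:7] = 1  # 5x5 square
        labels[1, 4] = 1  # single-pixel protrusion
        out = morphological_opening(labels, 1)
        assert out[1, 4] == 0
        np.testing.assert_array_equal(out[2:7, 2:7], 1)

    def test_idempotent_per_label(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 4, (24, 24))
        once = morphological_opening(labels, 1)
        twice = morphological_opening(once, 1)
        np.testing.assert_array_equal(once, twice)

    def test_opened_masks_stay_disjoint_and_shrink(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 4, (16, 16))
        out = morphological_opening(labels, 1)
        for lab in np.unique(labels):
            if lab == 0:
                continue
            assert not np.any((out == lab) & (labels != lab))
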