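import warnings
from dataclasses import replace as dc_replace

import numpy as np
import pytest
from scipy.stats import chisquare, ks_2samp

from goldx import (
    BackgroundPatch,
    ConfigurationError,
    GoldXParams,
    ParameterError,
    detect_image,
    detection_fixture,
    multi_tilt_fixture,
    process_stack,
    random_patch,
    replace_fiducial,
    scale_patch,
    select_background,
    select_background_manual,
    surround_stats,
)
from goldx.replace import dihedral_transform
from goldx.synth import SynthParams, blank_noise_image, generate_tilt_series


class TestSelectBackground:
    def test_returns_minimum_rmsd_of_drawn_candidates(self):
        rng = np.random.default_rng(0)
        img = np.random.default_rng(1).normal(size=(128, 128))
        img[40:80, 40:80] = 5.0  # an exactly flat square among texture
        best, candidates = select_background(
            img, None, 16, n_candidates=50, rng=rng, return_candidates=True
        )
        assert len(candidates) == 50
        # independent exhaustive re-evaluation of every drawn candidate
        rmsds = [float(img[y:y + 16, x:x + 16].std())
                 for (y, x) in (c.origin for c in candidates)]
        assert best.rmsd == min(rmsds)

    def test_single_candidate_returned_regardless_of_rmsd(self):
        rng = np.random.default_rng(3)
        img = np.random.default_rng(4).normal(size=(64, 64))
        best, candidates = select_background(
            img, None, 16, n_candidates=1, rng=rng, return_candidates=True
        )
        assert len(candidates) == 1
        assert best.origin == candidates[0].origin

    def test_constant_image_has_zero_rmsd(self):
        rng = np.random.default_rng(0)
        best = select_background(np.full((64, 64), 2.5), None, 16, rng=rng)
        assert best.rmsd == 0.0

    def test_fully_masked_image_raises(self):
        rng = np.random.default_rng(0)
        img = np.zeros((64, 64))
        masks = np.ones((64, 64), dtype=np.int32)
        with pytest.raises(ConfigurationError):
            select_background(img, masks, 16, rng=rng)

    def test_candidates_avoid_masks(self):
        rng = np.random.default_rng(5)
        img = np.random.default_rng(6).normal(size=(96, 96))
        masks = np.zeros((96, 96), dtype=np.int32)
        masks[:, :60] = 1  # only the right strip is free
        _, candidates = select_background(
            img, masks, 16, n_candidates=20, rng=rng, return_candidates=True
        )
        assert all(c.origin[1] >= 60 for c in candidates)


class TestSelectBackgroundManual:
    def test_full_frame_selection(self):
        img = np.arange(32 * 32, dtype=float).reshape(32, 32)
        patch = select_background_manual(img, (0, 0), 32)
        np.testing.assert_array_equal(patch.block, img)

    def test_mask_overlap_rejected(self):
        img = np.zeros((64, 64))
        masks = np.zeros((64, 64), dtype=np.int32)
        masks[10, 10] = 1
        with pytest.raises(ParameterError):
            select_background_manual(img, (0, 0), 16, masks)
        with pytest.raises(ParameterError):
            select_background_manual(img, (60, 60), 16)

    def test_rmsd_of_two_level_block(self):
        block = np.zeros((4, 4))
        block[:, 2:] = 2.0  # values {0, 2} in equal number -> rms 1 about mean 1
        patch = select_background_manual(block, (0, 0), 4)
        assert patch.rmsd == pytest.approx(1.0)


class TestRandomPatch:
    def _bg(self, side=16, seed=0):
        block = np.random.default_rng(seed).normal(size=(side, side))
        return BackgroundPatch(block=block, origin=(0, 0),
                               rmsd=float(block.std()))

    def test_dihedral_group_involution_and_closure(self):
        block = np.arange(25, dtype=float).reshape(5, 5)
        # 180 degree rotation applied twice is the identity
        np.testing.assert_array_equal(
            dihedral_transform(dihedral_transform(block, 2), 2), block
        )
        # all 8 transforms are distinct symmetries of the square
        seen = {dihedral_transform(block, i).tobytes() for i in range(8)}
        assert len(seen) == 8

    def test_full_size_patch_is_a_dihedral_transform(self):
        bg = self._bg()
        rng = np.random.default_rng(1)
        patch = random_patch(bg, bg.block.shape, rng)
        variants = {dihedral_transform(bg.block, i).tobytes()
                    for i in range(8)}
        assert patch.tobytes() in variants

    def test_transform_frequencies_uniform(self):
        bg = self._bg(side=4, seed=2)
        variants = [dihedral_transform(bg.block, i).tobytes()
                    for i in range(8)]
        rng = np.random.default_rng(42)
        counts = np.zeros(8)
        n = 10_000
        for _ in range(n):
            patch = random_patch(bg, (4, 4), rng)
            counts[variants.index(patch.tobytes())] += 1
        freqs = counts / n
        assert np.all(np.abs(freqs - 0.125) <= 0.02)
        assert chisquare(counts).pvalue > 1e-4

    def test_oversized_patch_rejected(self):
        with pytest.raises(ParameterError):
            random_patch(self._bg(8), (9, 4), np.random.default_rng(0))


class TestSurroundStats:
    def test_constant_field(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[10:14, 10:14] = 1
        mean, rms = surround_stats(np.full((32, 32), 4.2), labels, 1, 3)
        assert mean == pytest.approx(4.2)
        assert rms == pytest.approx(0.0)

    def test_hand_built_ring_values(self):
        # 7x7 grid, single-pixel region at center, ring width 1 ->
        # the ring is the 4-neighborhood; values {1, 3} equally
        img = np.zeros((7, 7))
        img[2, 3], img[4, 3] = 1.0, 1.0
        img[3, 2], img[3, 4] = 3.0, 3.0
        labels = np.zeros((7, 7), dtype=np.int32)
        labels[3, 3] = 1
        mean, rms = surround_stats(img, labels, 1, 1)
        assert mean == pytest.approx(2.0)
        assert rms == pytest.approx(1.0)

    def test_ring_clipped_at_border(self):
        img = np.ones((16, 16)) * 7.0
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[0:3, 0:3] = 1  # touches the corner
        mean, rms = surround_stats(img, labels, 1, 2)
        assert mean == pytest.approx(7.0)

    def test_ring_excludes_other_regions_and_falls_back(self):
        img = np.zeros((16, 16))
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[6:10, 6:10] = 1
        labels[(np.abs(np.arange(16)[:, None] - 7.5) <= 4.5)
               & (np.abs(np.arange(16)[None, :] - 7.5) <= 4.5)] = \
            np.where(labels[(np.abs(np.arange(16)[:, None] - 7.5) <= 4.5)
                            & (np.abs(np.arange(16)[None, :] - 7.5) <= 4.5)]
                     == 1, 1, 2)
        # region 1 fully surrounded by region 2: fallback stats used
        mean, rms = surround_stats(img, labels, 1, 2, fallback=(9.0, 0.5))
        assert (mean, rms) == (9.0, 0.5)

    def test_unknown_label_rejected(self):
        with pytest.raises(ParameterError):
            surround_stats(np.zeros((8, 8)),
                           np.zeros((8, 8), dtype=np.int32), 3, 1)


class TestScalePatch:
    def test_closed_form_two_level_patch(self):
        patch = np.array([[0.0, 2.0], [0.0, 2.0]])
        out = scale_patch(patch, 10.0, 3.0)
        np.testing.assert_allclose(np.sort(np.unique(out)), [7.0, 13.0])

    def test_standardization_and_identity(self):
        rng = np.random.default_rng(0)
        patch = rng.normal(3.0, 2.0, size=(16, 16))
        std = scale_patch(patch, 0.0, 1.0)
        assert std.mean() == pytest.approx(0.0, abs=1e-12)
        assert std.std() == pytest.approx(1.0, rel=1e-12)
        same = scale_patch(patch, patch.mean(), patch.std())
        np.testing.assert_allclose(same, patch, rtol=1e-12)

    def test_flat_patch_warns_and_returns_constant(self):
        with pytest.warns(UserWarning, match="flat patch"):
            out = scale_patch(np.full((4, 4), 2.0), 5.0, 1.0)
        np.testing.assert_array_equal(out, 5.0)


class TestReplaceFiducial:
    def _setup(self, seed=0):
        series, _ = detection_fixture(seed, n_beads=3,
                                      image_shape=(256, 256))
        params = GoldXParams(4.59, 10.0, seed=seed)
        tpl = params.template()
        markers, _, _ = detect_image(series.data[0], params, 0)
        from goldx import segment_image

        fmap = segment_image(series.data[0], markers, tpl,
                             params.resolved_dilate_radius(tpl))
        rng = np.random.default_rng(1)
        bg = select_background(series.data[0], fmap.dilated_labels, 64,
                               rng=rng)
        return series.data[0], fmap, bg, params

    def test_locality_outside_region(self):
        img, fmap, bg, params = self._setup()
        rng = np.random.default_rng(2)
        out = replace_fiducial(img, fmap.dilated_labels, 1, bg, params, rng)
        outside = fmap.dilated_labels != 1
        np.testing.assert_array_equal(out[outside], img[outside])

    def test_region_mean_tracks_ring_mean(self):
        img, fmap, bg, params = self._setup(1)
        rng = np.random.default_rng(3)
        out = replace_fiducial(img, fmap.dilated_labels, 1, bg, params, rng)
        region = fmap.dilated_labels == 1
        ring_mean, ring_rms = surround_stats(
            img, fmap.dilated_labels, 1, params.ring_width_px
        )
        n = region.sum()
        assert abs(out[region].mean() - ring_mean) <= 3 * ring_rms / np.sqrt(n)

    def test_empty_region_is_noop_with_warning(self):
        img, fmap, bg, params = self._setup(2)
        labels = fmap.dilated_labels.copy()
        labels[labels == 1] = 0
        with pytest.warns(UserWarning, match="empty"):
            out = replace_fiducial(img, labels, 1, bg, params,
                                   np.random.default_rng(0))
        np.testing.assert_array_equal(out, img)


class TestProcessStack:
    def test_deterministic_and_order_independent(self):
        series, _ = multi_tilt_fixture(7, n_beads=6, n_tilts=3,
                                       image_shape=(256, 256))
        params = GoldXParams(4.59, 10.0, seed=7)
        a, ta, _ = process_stack(series, params)
        b, tb, _ = process_stack(series, params)
        np.testing.assert_array_equal(a.data, b.data)
        assert ta.equals(tb)
        c, _, _ = process_stack(series, params, tilt_order=[2, 0, 1])
        np.testing.assert_array_equal(a.data, c.data)

    def test_blank_stack_returned_unchanged(self):
        sp = SynthParams(image_shape=(256, 256), n_tilts=2,
                         tilt_range_deg=(0, 0), bead_positions_3d=(), seed=9)
        series, _ = generate_tilt_series(sp)
        params = GoldXParams(4.59, 10.0, seed=9)
        cleaned, markers, report = process_stack(series, params)
        np.testing.assert_array_equal(cleaned.data, series.data)
        assert len(markers) == 0

    def test_self_erasure_single_stack(self):
        series, _ = multi_tilt_fixture(8, n_beads=6, n_tilts=3,
                                       image_shape=(384, 384))
        params = GoldXParams(4.59, 10.0, seed=8)
        cleaned, markers, report = process_stack(series, params)
        assert len(markers) == 18
        for t in range(3):
            again, _, _ = detect_image(cleaned.data[t], params, t)
            assert len(again) == 0

    def test_preview_mode_fills_constant(self):
        series, _ = detection_fixture(10, n_beads=4, image_shape=(256, 256))
        params = GoldXParams(4.59, 10.0, seed=10)
        preview, markers, _ = process_stack(series, params,
                                            preview_value=0.0)
        changed = preview.data[0] != series.data[0]
        assert changed.any()
        assert np.all(preview.data[0][changed] == 0.0)

    def test_manual_background_origin_requires_side(self):
        series, _ = detection_fixture(10, n_beads=4, image_shape=(256, 256))
        params = GoldXParams(4.59, 10.0, seed=10)
        with pytest.raises(ParameterError):
            process_stack(series, params, background_origin=(0, 0))

    def test_texture_continuity_of_inserted_patches(self):
        """Inserted pixels come from the same population as the ring pixels:
        their KS distance is no more than 1.5x that between two disjoint
        background windows of comparable size (no new texture population)."""
        series, _ = detection_fixture(15, n_beads=6, image_shape=(384, 384))
        params = GoldXParams(4.59, 10.0, seed=15)
        tpl = params.template()
        cleaned, _, _ = process_stack(series, params)
        from goldx import segment_image

        m, _, _ = detect_image(series.data[0], params, 0)
        fmap = segment_image(series.data[0], m, tpl,
                             params.resolved_dilate_radius(tpl))
        stats = []
        for k in m["label"].astype(int):
            region = fmap.dilated_labels == k
            ring = _ring(fmap.dilated_labels, k, 3)
            stats.append(ks_2samp(cleaned.data[0][region],
                                  series.data[0][ring]).statistic)
        # reference: disjoint 28x28 windows (approximately region-sized) of
        # a bead-free image from the same generator
        img = blank_noise_image(15, image_shape=(384, 384))
        refs = []
        for (ay, ax), (by, bx) in [((10, 10), (200, 200)),
                                   ((60, 300), (300, 60)),
                                   ((150, 150), (330, 250))]:
            refs.append(ks_2samp(img[ay:ay + 28, ax:ax + 28].ravel(),
                                 img[by:by + 28, bx:bx + 28].ravel()).statistic)
        assert np.mean(stats) <= 1.5 * np.mean(refs)


def _ring(labels, k, width):
    from scipy import ndimage

    region = labels == k
    d = ndimage.distance_transform_edt(~region)
    return (d > 0) & (d <= width) & (labels == 0)
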