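"""In-silico slicing, peak fitting, and cross-modal assembly."""

import numpy as np
import pytest

from trabekit import phantom as ph
from trabekit.cross_modal import (
    InSilicoStack,
    Plane,
    ct_feature_cache,
    fit_peak,
    keypoint_profile,
    register_and_assemble,
    slice_volume,
)
from trabekit.registration import ClassicalMatcher
from trabekit.volumes import CLASS_MISSING


class TestSliceVolume:
    def test_axis_aligned_native_spacing_returns_raw_planes(self, small_volume):
        _, vol, _ = small_volume
        ct = ph.simulate_microct(vol, 1.0, 0.02, seed=0)
        stack = slice_volume(ct, Plane(), voxel_size_um=11.0)
        assert len(stack) == ct.shape[0]
        for k in (0, 17, 63):
            assert np.array_equal(stack.slices[k], ct[k])

    def test_slice_then_restack_roundtrip(self, small_volume):
        _, vol, _ = small_volume
        ct = ph.simulate_microct(vol, 1.0, 0.02, seed=0)
        stack = slice_volume(ct, Plane(), voxel_size_um=11.0)
        assert np.array_equal(np.stack(stack.slices), ct)

    def test_oblique_cut_of_ball_follows_chord_formula(self):
        r = 18.0
        ball = ph.solid_ball(r, pad=6).astype(float)
        normal = (np.cos(np.radians(30)), np.sin(np.radians(30)), 0.0)
        stack = slice_volume(ball, Plane(normal), voxel_size_um=1.0)
        center_k = None
        areas = [s.sum() for s in (sl > 0.5 for sl in stack.slices)]
        center_k = int(np.argmax(areas))
        for dk in range(-int(r) + 3, int(r) - 2):
            sl = stack.slices[center_k + dk] > 0.5
            expected = np.sqrt(max(r**2 - dk**2, 0.0))
            measured = np.sqrt(sl.sum() / np.pi)
            assert abs(measured - expected) <= 1.0

    def test_plane_outside_volume_rejected(self):
        with pytest.raises(ValueError):
            Plane((0.0, 0.0, 0.0)).unit_normal


class TestFitPeak:
    def test_gaussian_counts_recover_mean(self):
        z = np.arange(100)
        counts = 40 * np.exp(-((z - 42.0) ** 2) / (2 * 3.0**2)) + 3
        fit = fit_peak(counts)
        assert abs(fit.mu - 42.0) < 0.1
        assert fit.matched_index == 42
        assert not fit.fallback

    def test_symmetric_tie_resolved_by_symmetry(self):
        z = np.arange(80)
        counts = 30 * np.exp(-((z - 42.0) ** 2) / (2 * 2.0**2)) + 2
        counts[41] = counts[43]  # exact symmetric pair around 42
        fit = fit_peak(counts)
        assert fit.matched_index == 42

    def test_flat_counts_fall_back_to_argmax(self):
        fit = fit_peak(np.full(20, 7.0))
        assert fit.fallback
        assert fit.matched_index == 0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="no correspondence|all-zero"):
            fit_peak(np.zeros(10))

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            fit_peak([1, 2, 1])


class TestKeypointProfile:
    @pytest.fixture(scope="class")
    def ct_fixture(self):
        spec = ph.PhantomSpec(grid_shape=(32, 128, 128), seed=7, correlation_length_um=33.0)
        vol, _ = ph.generate_trabecular_volume(spec)
        ct = ph.simulate_microct(vol, 1.0, 0.05, seed=1)
        stack = slice_volume(ct, Plane(), voxel_size_um=11.0)
        matcher = ClassicalMatcher(n_keypoints=400)
        feats = ct_feature_cache(stack, matcher)
        return vol, stack, matcher, feats

    def test_self_profile_peaks_at_own_index(self, ct_fixture):
        _, stack, matcher, feats = ct_fixture
        prof = keypoint_profile(stack.slices[16], stack, matcher, ct_features=feats)
        assert prof.matched_index == 16

    def test_derived_slide_matches_its_source_plane(self, ct_fixture):
        vol, stack, matcher, feats = ct_fixture
        slide = ph.stain_slide(vol.voxels[20])
        pseudo_ct = 1.0 - slide @ np.array([0.2125, 0.7154, 0.0721])
        prof = keypoint_profile(pseudo_ct, stack, matcher, ct_features=feats)
        assert int(np.argmax(prof.counts)) == 20
        assert prof.matched_index == 20

    def test_peak_to_background_ratio_large(self, ct_fixture):
        vol, stack, matcher, feats = ct_fixture
        slide = ph.stain_slide(vol.voxels[20])
        pseudo_ct = 1.0 - slide @ np.array([0.2125, 0.7154, 0.0721])
        prof = keypoint_profile(pseudo_ct, stack, matcher, ct_features=feats)
        assert prof.peak_to_background() >= 5.0

    def test_unrelated_image_raises_no_correspondence(self, ct_fixture):
        _, stack, matcher, feats = ct_fixture
        blank = np.zeros_like(stack.slices[0])
        with pytest.raises(ValueError, match="no correspondence"):
            keypoint_profile(blank, stack, matcher, ct_features=feats)


class TestAssembly:
    def test_zero_jitter_assembly_matches_ground_truth(self):
        """No jitter, no dropout: the assembled volume equals the truth."""
        spec = ph.PhantomSpec(grid_shape=(32, 96, 96), seed=4, correlation_length_um=33.0)
        vol, _ = ph.generate_trabecular_volume(spec)
        ct = ph.simulate_microct(vol, 0.0, 0.0)  # uncorrupted rendering
        stack = slice_volume(ct, Plane(), voxel_size_um=11.0)
        sim = ph.HistologySimSpec(
            slice_thickness_um=11.0, max_rotation_deg=0, max_translation_px=0,
            max_scale_dev=0, dropout_prob=0, stain_noise_sd=0.0, seed=0,
        )
        slides, truth = ph.simulate_histology_stack(vol, sim)
        pseudo = [1.0 - s @ np.array([0.2125, 0.7154, 0.0721]) for s in slides]
        out, report = register_and_assemble(
            pseudo, truth.class_masks, stack,
            matcher=ClassicalMatcher(n_keypoints=400), z_search_radius=4,
        )
        assert report.matched_indices == truth.z_indices
        agreement = (out.voxels == vol.voxels).mean()
        assert agreement >= 0.99
        assert out.missing_planes == []
        assert out.frame == "ct"

    def test_dropout_planes_marked_missing(self):
        spec = ph.PhantomSpec(grid_shape=(32, 96, 96), seed=4, correlation_length_um=33.0)
        vol, _ = ph.generate_trabecular_volume(spec)
        ct = ph.simulate_microct(vol, 0.0, 0.0)
        stack = slice_volume(ct, Plane(), voxel_size_um=11.0)
        sim = ph.HistologySimSpec(
            slice_thickness_um=11.0, max_rotation_deg=0, max_translation_px=0,
            max_scale_dev=0, dropout_prob=0.15, stain_noise_sd=0.0, seed=6,
        )
        slides, truth = ph.simulate_histology_stack(vol, sim)
        pseudo = [1.0 - s @ np.array([0.2125, 0.7154, 0.0721]) for s in slides]
        out, report = register_and_assemble(
            pseudo, truth.class_masks, stack,
            matcher=ClassicalMatcher(n_keypoints=400), z_search_radius=4,
        )
        assert sorted(out.missing_planes) == sorted(truth.dropped_z_indices)
        for z in out.missing_planes:
            assert (out.voxels[z] == CLASS_MISSING).all()

    def test_mask_count_mismatch_rejected(self):
        stack = InSilicoStack(
            slices=[np.zeros((8, 8))] * 6, plane=Plane(), spacing_um=11.0, pixel_size_um=11.0
        )
        with pytest.raises(ValueError, match="one class mask per slide"):
            register_and_assemble([np.zeros((8, 8))] * 2, [np.zeros((8, 8), np.uint8)], stack)
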