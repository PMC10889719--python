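"""Keypoint matching, sequential affine optimization, stack pre-alignment."""

import numpy as np
import pytest

from trabekit import phantom as ph
from trabekit.registration import (
    AffineBounds,
    ClassicalMatcher,
    estimate_similarity_from_matches,
    get_matcher,
    match_keypoints,
    optimize_affine,
    prealign_stack,
)
from trabekit.transforms import Affine2D, warp_mask


class TestMatcher:
    def test_self_match_has_zero_displacement(self, slice_fixture):
        _, gray = slice_fixture
        mr = match_keypoints(gray, gray)
        assert mr.n_matches > 0
        assert np.abs(mr.displacements).max() == 0.0
        assert mr.parallel_fraction() == 1.0

    def test_translation_recovered_in_median_displacement(self, slice_fixture):
        _, gray = slice_fixture
        shifted = Affine2D(tx=30, ty=0).warp(gray, order=1)
        mr = match_keypoints(gray, shifted)
        med = np.median(mr.displacements, axis=0)
        assert abs(med[0] - 30) <= 1.0 and abs(med[1]) <= 1.0

    def test_noise_field_matches_far_below_self_match(self, slice_fixture):
        _, gray = slice_fixture
        n_self = match_keypoints(gray, gray).n_matches
        noise = np.random.default_rng(0).random(gray.shape)
        n_noise = match_keypoints(gray, noise).n_matches
        assert n_noise <= n_self / 10

    def test_unavailable_backend_names_fallback(self):
        with pytest.raises(ValueError, match="classical"):
            get_matcher("loftr")

    def test_similarity_estimate_exact_on_clean_correspondences(self):
        from trabekit.registration import MatchResult

        rng = np.random.default_rng(1)
        true = Affine2D(8, -5, 12, 1.02)
        b = rng.uniform(10, 118, (40, 2))
        a = true.apply_points(b, (63.5, 63.5))
        mr = MatchResult(keypoints_a=a, keypoints_b=b, confidences=np.ones(40))
        est = estimate_similarity_from_matches(mr, (128, 128))
        assert np.allclose(est.params, true.params, atol=1e-6)


class TestOptimizeAffine:
    def test_identity_on_self_returns_self_entropy(self, slice_fixture):
        _, gray = slice_fixture
        fit = optimize_affine(gray, gray)
        assert np.allclose(fit.transform.params, (0, 0, 0, 1), atol=(0.3, 0.3, 0.1, 0.002))
        f = (gray - gray.min()) / np.ptp(gray)
        f = np.clip(f, 1e-6, 1 - 1e-6)
        self_entropy = float(-(f * np.log(f) + (1 - f) * np.log(1 - f)).mean())
        assert fit.objective == pytest.approx(self_entropy, rel=1e-2)

    def test_known_perturbation_recovered(self, slice_fixture):
        """(12 px, -5 px, 7 deg, 1.03) recovered within (2, 2, 1, 0.01)."""
        _, gray = slice_fixture
        true = Affine2D(12, -5, 7, 1.03)
        moving = true.inverse().warp(gray, order=1)
        fit = optimize_affine(moving, gray)
        tx, ty, th, s = fit.transform.params
        assert abs(tx - 12) <= 2.0
        assert abs(ty + 5) <= 2.0
        assert abs(th - 7) <= 1.0
        assert abs(s - 1.03) <= 0.01

    def test_objective_descends_across_stages(self, slice_fixture):
        _, gray = slice_fixture
        moving = Affine2D(10, 6, -5, 0.98).warp(gray, order=1)
        fit = optimize_affine(moving, gray)
        vals = list(fit.stage_objectives.values())
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))
        assert fit.objective <= vals[0]

    def test_shape_mismatch_rejected(self, slice_fixture):
        _, gray = slice_fixture
        with pytest.raises(ValueError):
            optimize_affine(gray[:-2], gray)


class TestPrealign:
    @pytest.fixture(scope="class")
    def jittered(self):
        spec = ph.PhantomSpec(grid_shape=(32, 128, 128), seed=7, correlation_length_um=66.0)
        vol, _ = ph.generate_trabecular_volume(spec)
        sim = ph.HistologySimSpec(slice_thickness_um=11.0, seed=5)
        slides, truth = ph.simulate_histology_stack(vol, sim)
        lo, hi = 9, 23  # a 14-slide window keeps the test quick
        truth.class_masks = truth.class_masks[lo:hi]
        truth.transforms = truth.transforms[lo:hi]
        return slides[lo:hi], truth

    @staticmethod
    def consecutive_agreement(masks):
        return float(np.mean([(a == b).mean() for a, b in zip(masks, masks[1:])]))

    def test_identical_slides_align_with_identity(self, slice_fixture):
        _, gray = slice_fixture
        rgb = np.stack([gray] * 3, axis=-1)
        res = prealign_stack([rgb, rgb.copy(), rgb.copy()])
        for t in res.transforms:
            assert np.allclose(t.params, (0, 0, 0, 1), atol=(0.5, 0.5, 0.1, 0.002))

    def test_jittered_stack_alignment_recovers_agreement(self, jittered):
        """Pre-alignment restores consecutive-slice agreement close to the
        nearest-neighbour resampling ceiling of exact recovery."""
        slides, truth = jittered
        before = self.consecutive_agreement(truth.class_masks)
        res = prealign_stack(
            slides, matcher=ClassicalMatcher(n_keypoints=400), window=3,
            bounds=AffineBounds(16.0, 22.0),
        )
        aligned = [warp_mask(m, t) for m, t in zip(truth.class_masks, res.transforms)]
        after = self.consecutive_agreement(aligned)
        perfect = self.consecutive_agreement(
            [warp_mask(m, t.inverse()) for m, t in zip(truth.class_masks, truth.transforms)]
        )
        assert before <= 0.85
        assert after >= 0.88
        assert after >= perfect - 0.03

    def test_reference_selection_by_match_count(self, slice_fixture):
        """The reference is the candidate with the most keypoint matches."""
        from trabekit.registration import MatchResult

        _, gray = slice_fixture
        slides = []
        for i in range(4):
            s = gray.copy()
            s[0, 0] = i  # identity tag read back by the stub matcher
            slides.append(np.stack([s] * 3, axis=-1))
        counts_for_candidate = {0: 5, 1: 120, 2: 40}
        rng = np.random.default_rng(0)
        pts = rng.uniform(20, 100, (200, 2))

        def stub(a, b):
            j = int(round(a[0, 0]))
            n = counts_for_candidate.get(j, 50)
            return MatchResult(
                keypoints_a=pts[:n], keypoints_b=pts[:n], confidences=np.ones(n)
            )

        res = prealign_stack(slides, matcher=stub, window=3)
        # slide 3 sees candidates {0, 1, 2}: candidate 1 has the most matches
        assert res.reference_indices[3] == 1

    def test_short_stack_rejected(self, slice_fixture):
        _, gray = slice_fixture
        with pytest.raises(ValueError):
            prealign_stack([np.stack([gray] * 3, -1)])

    def test_prealigning_aligned_stack_is_near_noop(self, slice_fixture):
        """On an already-aligned stack the cumulative transforms stay small
        and consecutive-slice agreement is not degraded."""
        vol, _ = slice_fixture
        zs = (14, 15, 16, 17)
        slides = [ph.stain_slide(vol.voxels[z]) for z in zs]
        masks = [vol.voxels[z] for z in zs]
        res = prealign_stack(slides, window=3)
        for t in res.transforms:
            assert abs(t.tx) < 2.0 and abs(t.ty) < 2.0
            assert abs(t.theta) < 2.0 and abs(t.s - 1) < 0.01
        before = self.consecutive_agreement(masks)
        after = self.consecutive_agreement(
            [warp_mask(m, t) for m, t in zip(masks, res.transforms)]
        )
        # small allowance for nearest-neighbour resampling of the masks
        assert after >= before - 0.02
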