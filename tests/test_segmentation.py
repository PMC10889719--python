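"""Tiling, class weights, ensembling, postprocessing, schedules."""

import numpy as np
import pytest

from trabekit.nn import UNet
from trabekit.segmentation import (
    LRSchedule,
    UNetConfig,
    compute_class_weights,
    kfold_indices,
    postprocess,
    predict_ensemble,
    stitch_tiles,
    tile_image,
)


class TestTiling:
    def test_single_tile_for_exact_fit(self):
        ts = tile_image(np.zeros((512, 512, 3)), tile=512, overlap=64)
        assert ts.origins == [(0, 0)]

    def test_stride_and_border_shift(self):
        ts = tile_image(np.zeros((960, 512)), tile=512, overlap=64)
        assert sorted({y for y, _ in ts.origins}) == [0, 448]
        assert len(ts.origins) == 2

    def test_adjacent_origins_differ_by_stride(self):
        ts = tile_image(np.zeros((1400, 980)), tile=512, overlap=64)
        ys = sorted({y for y, _ in ts.origins})
        assert all(b - a <= 448 for a, b in zip(ys, ys[1:]))
        assert ys[-1] == 1400 - 512  # last tile flush with the border

    def test_small_image_reflect_padded(self):
        ts = tile_image(np.zeros((100, 80)), tile=128, overlap=16)
        assert ts.tiles.shape[1:3] == (128, 128)
        assert ts.parent_shape == (100, 80)

    def test_stitch_reproduces_image_exactly(self):
        rng = np.random.default_rng(0)
        img = rng.random((300, 260))
        ts = tile_image(img, tile=128, overlap=32)
        rec = stitch_tiles(ts.tiles, ts)
        assert np.allclose(rec, img)

    def test_overlap_must_be_smaller_than_tile(self):
        with pytest.raises(ValueError):
            tile_image(np.zeros((64, 64)), tile=32, overlap=32)


class TestClassWeights:
    def test_balanced_masks_give_unit_weights(self):
        m = np.repeat([0, 1, 2], 100).reshape(3, 100)
        assert np.allclose(compute_class_weights([m]), 1.0)

    def test_inverse_frequency_formula(self):
        n = 1000
        m = np.concatenate([np.zeros(700), np.ones(100), np.full(200, 2)]).astype(int)
        w = compute_class_weights([m.reshape(1, -1)])
        assert np.allclose(w, [n / (3 * 700), n / (3 * 100), n / (3 * 200)])
        assert np.allclose(np.round(w, 3), [0.476, 3.333, 1.667])

    def test_duplication_invariance(self):
        m = np.concatenate([np.zeros(70), np.ones(10), np.full(20, 2)]).astype(int)
        w1 = compute_class_weights([m])
        w2 = compute_class_weights([m, m])
        assert np.allclose(w1, w2)

    def test_absent_class_named_in_error(self):
        with pytest.raises(ValueError, match="graft"):
            compute_class_weights([np.array([0, 0, 1, 1])])


class TestFoldsAndSchedule:
    def test_folds_disjoint_and_exhaustive(self):
        folds = kfold_indices(40, 5, seed=1)
        assert [len(f) for f in folds] == [8] * 5
        assert sorted(np.concatenate(folds)) == list(range(40))

    def test_fold_membership_deterministic_in_seed(self):
        f1 = kfold_indices(37, 5, seed=9)
        f2 = kfold_indices(37, 5, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))

    def test_lr_drops_by_factor_after_patience_stalls(self):
        """With patience 30 and no improvement past epoch 30, the rate at
        epoch 61 has dropped by a factor of 10."""
        sched = LRSchedule(lr=1e-3, floor=1e-5, factor=10.0, patience=30)
        lr_at = {}
        for epoch in range(70):
            # improving until epoch 30, stalled afterwards
            val = 1.0 / (epoch + 1) if epoch <= 30 else 1.0
            lr_at[epoch] = sched.update(val)
        assert lr_at[60] == 1e-3
        assert lr_at[61] <= 1e-4 + 1e-12

    def test_lr_never_below_floor(self):
        sched = LRSchedule(lr=1e-3, floor=1e-5, factor=10.0, patience=0)
        for _ in range(100):
            lr = sched.update(5.0)
        assert lr == 1e-5


class _StubModel:
    """Fixed-probability model honouring the UNet predict interface."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=np.float32)

    def forward(self, x, train=False):
        n, _, h, w = x.shape
        logits = np.log(self.probs + 1e-9)
        return np.broadcast_to(logits[None, :, None, None], (n, 3, h, w)).copy()


class TestPredictEnsemble:
    def _ensemble(self, models):
        from trabekit.segmentation import Ensemble

        return Ensemble(
            models=models,
            val_accuracies=[1.0] * len(models),
            cfg=UNetConfig.tiny(seed=0),
            class_weights=np.ones(3),
        )

    def test_constant_stub_fills_map(self):
        ens = self._ensemble([_StubModel([1.0, 0.0, 0.0])])
        prob = predict_ensemble(np.zeros((64, 48, 3)), ens)
        assert prob.shape == (64, 48, 3)
        assert np.allclose(prob[..., 0], 1.0, atol=1e-6)

    def test_two_stub_models_average(self):
        ens = self._ensemble([_StubModel([1, 0, 0]), _StubModel([0, 1, 0])])
        prob = predict_ensemble(np.zeros((40, 40, 3)), ens)
        assert np.allclose(prob[..., :2], 0.5, atol=1e-6)
        assert np.allclose(prob[..., 2], 0.0, atol=1e-6)

    def test_probabilities_sum_to_one_after_stitching(self):
        rng = np.random.default_rng(0)
        net = UNet(depth=2, base_channels=4, seed=3)
        cfg = UNetConfig.tiny(seed=0)
        from trabekit.segmentation import Ensemble

        ens = Ensemble([net], [1.0], cfg, np.ones(3))
        prob = predict_ensemble(rng.random((70, 90, 3)), ens)
        assert np.abs(prob.sum(-1) - 1.0).max() < 1e-5

    def test_empty_ensemble_rejected(self):
        ens = self._ensemble([])
        with pytest.raises(ValueError):
            predict_ensemble(np.zeros((32, 32, 3)), ens)

    def test_overlap_seam_is_model_average(self):
        """Stitching two tiles with different stub outputs averages the seam."""
        from trabekit.segmentation import TileSet, predict_from_stubs

        img_shape = (32, 56)
        ts = tile_image(np.zeros(img_shape), tile=32, overlap=8)
        assert len(ts.origins) == 2
        out_a = np.full((32, 32, 3), (1.0, 0.0, 0.0))
        out_b = np.full((32, 32, 3), (0.0, 1.0, 0.0))
        stitched = predict_from_stubs(img_shape, [out_a, out_b], ts)
        x0 = ts.origins[1][1]
        seam = stitched[:, x0 : 32]  # overlap columns
        assert np.allclose(seam[..., 0], 0.5)
        assert np.allclose(stitched[:, :x0, 0], 1.0)
        assert np.allclose(stitched[:, 32:, 1], 1.0)


class TestPostprocess:
    def test_constant_map_unchanged(self):
        prob = np.zeros((40, 40, 3))
        prob[..., 1] = 1.0
        out = postprocess(prob, filter_size=8, sigma_space=8)
        assert (out == 1).all()

    def test_tie_breaks_by_class_priority(self):
        prob = np.full((12, 12, 3), (0.4, 0.4, 0.2))  # non-min vs bone tie
        out = postprocess(prob, filter_size=4, sigma_space=4)
        assert (out == 1).all()  # bone beats non-mineralized

    def test_salt_noise_removed_edge_preserved(self):
        """Bilateral smoothing removes an isolated wrong pixel but, unlike a
        Gaussian blur, leaves the two-region boundary in place."""
        from scipy.ndimage import gaussian_filter

        prob = np.zeros((40, 60, 3))
        prob[:, :30, 1] = 1.0
        prob[:, 30:, 0] = 1.0
        prob[20, 10] = (1.0, 0.0, 0.0)  # salt pixel inside the bone region
        out = postprocess(prob, filter_size=8, sigma_color=100, sigma_space=8)
        assert out[20, 10] == 1  # noise pixel reassigned to its region
        # boundary position unmoved within 1 px
        boundary = np.argmax(out[5] == 0)
        assert abs(boundary - 30) <= 1
        # control: plain Gaussian smoothing displaces/blurs the hard edge more
        g = gaussian_filter(prob[..., 1], 4.0)
        blurred_span = np.sum((g[5] > 0.05) & (g[5] < 0.95))
        assert blurred_span > 4
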