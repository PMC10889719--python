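"""Morphometry engine against analytic phantom oracles."""

import numpy as np
import pytest

from trabekit import phantom as ph
from trabekit.morphometry import (
    PrismGrid,
    binarize,
    compute_morphometry,
    count_closed_pores,
    count_objects,
    degree_of_anisotropy,
    euler_number,
    local_thickness,
    morphometry_table,
    surface_area_um2,
    tile_volume,
)
from trabekit.volumes import BinaryVolume, LabeledVolume


class TestBinarize:
    def test_label_rules_select_classes(self, small_volume):
        _, vol, _ = small_volume
        both = binarize(vol, "labels:bone,graft")
        bone = binarize(vol, "labels:bone")
        assert np.array_equal(both.voxels, np.isin(vol.voxels, (1, 2)))
        assert np.array_equal(bone.voxels, vol.voxels == 1)

    def test_otsu_recovers_noiseless_two_level_volume(self, small_volume):
        _, vol, _ = small_volume
        ct = ph.simulate_microct(vol, blur_sigma_vox=0.0, noise_sd=0.0)
        bv = binarize(ct, "otsu", spacing_um=(11.0,) * 3)
        assert np.array_equal(bv.voxels, np.isin(vol.voxels, (1, 2)))

    def test_fixed_threshold_rule(self):
        vol = np.linspace(0, 1, 4**3).reshape(4, 4, 4)
        bv = binarize(vol, "fixed:0.5", spacing_um=(1.0,) * 3)
        assert np.array_equal(bv.voxels, vol > 0.5)

    def test_unknown_rule_rejected(self, small_volume):
        _, vol, _ = small_volume
        with pytest.raises(ValueError):
            binarize(vol, "labels:cartilage")


class TestTiling:
    def test_exact_box_division(self):
        roi = np.ones((8, 8, 8), dtype=bool)
        vol = BinaryVolume(np.zeros((8, 8, 8), bool), (115.0, 128.0, 128.0))
        grid = tile_volume(vol, roi, prism_size_um=(460.0, 512.0, 512.0))
        assert grid.count == 8  # 2 x 2 x 2

    def test_partial_prisms_discarded(self):
        vol = BinaryVolume(np.zeros((8, 8, 8), bool), (115.0, 125.0, 128.0))
        # y axis: 8 voxels of 125 µm = 1000 µm -> only one 512 µm prism fits
        grid = tile_volume(vol, prism_size_um=(460.0, 512.0, 512.0))
        assert grid.count == 2 * 1 * 2

    def test_matches_brute_force_enumeration_on_cylinder_roi(self):
        zz, yy, xx = np.mgrid[0:24, 0:40, 0:40]
        roi = (yy - 19.5) ** 2 + (xx - 19.5) ** 2 <= 18**2
        vol = BinaryVolume(np.zeros(roi.shape, bool), (10.0,) * 3)
        size = (8, 8, 8)
        grid = tile_volume(vol, roi, prism_size_um=(80.0, 80.0, 80.0))
        # brute force: every grid-aligned box fully inside the ROI
        lo = [int(a.min()) for a in np.nonzero(roi)]
        expected = 0
        for z in range(lo[0], 24 - size[0] + 1, size[0]):
            for y in range(lo[1], 40 - size[1] + 1, size[1]):
                for x in range(lo[2], 40 - size[2] + 1, size[2]):
                    if roi[z : z + 8, y : y + 8, x : x + 8].all():
                        expected += 1
        assert grid.count == expected

    def test_no_fitting_prism_raises(self):
        vol = BinaryVolume(np.zeros((4, 4, 4), bool), (10.0,) * 3)
        with pytest.raises(ValueError):
            tile_volume(vol, prism_size_um=(1000.0, 1000.0, 1000.0))


class TestGeometricOracles:
    def test_half_slab_volume_fraction(self):
        vox = np.zeros((64, 64, 64), bool)
        vox[:32] = True
        res = compute_morphometry(BinaryVolume(vox, (11.0,) * 3))
        assert res.BVTV_percent == 50.0
        assert res.Po_percent == 50.0

    def test_ball_surface_volume_topology(self):
        r = 20.0
        ball = ph.solid_ball(r)
        res = compute_morphometry(BinaryVolume(ball, (1.0,) * 3))
        assert res.EuN == 1
        assert res.Obj_N == 1
        assert res.Po_N_cl == 0
        assert abs(res.BS - 4 * np.pi * r**2) / (4 * np.pi * r**2) < 0.05
        assert abs(res.BV - 4 / 3 * np.pi * r**3) / (4 / 3 * np.pi * r**3) < 0.02

    def test_hollow_shell_topology(self):
        shell = ph.hollow_shell(16, 9)
        assert euler_number(shell) == 2
        assert count_closed_pores(shell) == 1
        assert count_objects(shell) == 1

    def test_plate_lattice_thickness_and_separation(self):
        plates = ph.parallel_plates((45, 48, 48), 5, 10, axis=0, phase_vox=10)
        res = compute_morphometry(BinaryVolume(plates, (11.0,) * 3))
        assert abs(res.Tb_Th - 5 * 11.0) / (5 * 11.0) <= 0.10 + 1e-9
        assert abs(res.Tb_Sp - 10 * 11.0) / (10 * 11.0) <= 0.10 + 1e-9
        assert res.DA > 3.0

    def test_surface_error_shrinks_under_supersampling(self):
        r = 10.0
        coarse = ph.solid_ball(r)
        fine = ph.solid_ball(2 * r)  # same ball at half the voxel pitch
        a_coarse = surface_area_um2(coarse, 1.0)
        a_fine = surface_area_um2(fine, 0.5)
        true = 4 * np.pi * r**2
        assert abs(a_fine - true) < abs(a_coarse - true)


class TestThicknessProperties:
    def test_slab_thickness_invariant_to_extent(self):
        vals = []
        for ext in (24, 40, 56):
            p = ph.parallel_plates((45, ext, ext), 5, 10, phase_vox=10)
            th = local_thickness(p, 1.0)
            vals.append(th[p].mean())
        assert max(vals) - min(vals) < 1e-9

    def test_separation_equals_thickness_of_complement(self):
        plates = ph.parallel_plates((45, 24, 24), 5, 10, phase_vox=10)
        th_c = local_thickness(~plates, 1.0)[~plates].mean()
        res = compute_morphometry(BinaryVolume(plates, (1.0,) * 3))
        assert res.Tb_Sp == pytest.approx(th_c)


class TestAnisotropy:
    def test_isotropic_field_near_unity(self, small_volume):
        _, vol, _ = small_volume
        mask = np.isin(vol.voxels, (1, 2))
        da = degree_of_anisotropy(mask)
        assert 1.0 <= da <= 1.3

    def test_plates_strongly_anisotropic(self):
        plates = ph.parallel_plates((45, 48, 48), 5, 10, phase_vox=10)
        assert degree_of_anisotropy(plates) > 3.0


class TestDegenerateAndTable:
    def test_all_background_prism_defined(self):
        res = compute_morphometry(BinaryVolume(np.zeros((8, 8, 8), bool), (10.0,) * 3))
        assert res.BVTV_percent == 0.0
        assert res.BS == 0.0
        assert np.isnan(res.Tb_Th)

    def test_all_foreground_prism_defined(self):
        res = compute_morphometry(BinaryVolume(np.ones((8, 8, 8), bool), (10.0,) * 3))
        assert res.BVTV_percent == 100.0
        assert res.BS == 0.0
        assert res.Po_percent == 0.0

    def test_bvtv_plus_porosity_exactly_100(self, small_volume):
        _, vol, _ = small_volume
        res = compute_morphometry(binarize(vol, "labels:bone,graft"))
        assert res.BVTV_percent + res.Po_percent == 100.0

    def test_anisotropic_volume_resampled_before_analysis(self):
        vox = np.zeros((20, 10, 10), bool)
        vox[:10] = True
        bv = BinaryVolume(vox, (5.0, 10.0, 10.0))
        res = compute_morphometry(bv)
        assert res.BVTV_percent == pytest.approx(50.0, abs=1.0)

    def test_table_has_field_abbreviation_columns(self, small_volume):
        _, vol, _ = small_volume
        bv = binarize(vol, "labels:bone,graft")
        grid = tile_volume(bv, prism_size_um=(352.0, 352.0, 352.0))
        table = morphometry_table(bv, grid)
        for col in ("BV/TV", "BS/TV", "Tb.Pf", "Tb.Th", "Tb.Sp", "SMI", "DA", "EuN"):
            assert col in table.columns
        assert len(table) == grid.count
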