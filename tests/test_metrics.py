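import numpy as np
import pytest
from scipy import ndimage

from osseoquant import (
    LabeledVolume,
    class_volume,
    compute_bic,
    compute_bvtv,
    compute_gas_metrics,
    compute_vl_dr,
    surface_area,
)
from osseoquant.metrics import WEEKS_PER_YEAR

from .conftest import make_random_labels
from .oracles import brute_force_bic


class TestClassVolume:
    def test_analytic_block(self):
        vol = LabeledVolume(np.full((10, 10, 10), 3, np.uint8), (0.1, 0.1, 0.1))
        assert class_volume(vol, "bone") == pytest.approx(1.0)

    def test_empty_class_is_zero(self):
        vol = LabeledVolume(np.zeros((4, 4, 4), np.uint8), (1, 1, 1))
        assert class_volume(vol, "gas") == 0.0

    def test_unknown_class_rejected(self):
        vol = LabeledVolume(np.zeros((4, 4, 4), np.uint8), (1, 1, 1))
        with pytest.raises(KeyError):
            class_volume(vol, "cartilage")

    def test_conservation_over_scheme(self, coarse_phantom):
        vol = coarse_phantom.volume
        total = sum(class_volume(vol, name) for name in vol.scheme.to_dict())
        assert total == pytest.approx(vol.physical_volume, abs=1e-9)


class TestSurfaceArea:
    def test_sphere_mesh_area_within_3pct(self, digital_sphere):
        assert surface_area(digital_sphere) == pytest.approx(4 * np.pi * 4.0, rel=0.03)

    def test_single_voxel_face_count(self):
        m = np.zeros((3, 3, 3), np.uint8)
        m[1, 1, 1] = 1
        vol = LabeledVolume(m, (0.25, 0.25, 0.25))
        assert surface_area(vol, method="face_count") == pytest.approx(6 * 0.25**2)

    @pytest.mark.parametrize("seed", range(4))
    def test_face_count_dominates_mesh_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        blob = ndimage.binary_dilation(rng.random((14, 14, 14)) < 0.02, iterations=2)
        blob[7, 7, 7] = True
        vol = LabeledVolume(blob.astype(np.uint8), (0.3, 0.3, 0.3))
        assert surface_area(vol, method="face_count") >= surface_area(vol, method="mesh")

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            surface_area(LabeledVolume(np.zeros((3, 3, 3), np.uint8), (1, 1, 1)))


class TestVolumeLossAndRate:
    def test_no_degradation_gives_zero_rate(self):
        m = compute_vl_dr(Vi=112.03, Vr=112.03, Ai=226.94, t_weeks=4)
        assert m.VL_mm3 == 0.0 and m.DR_mm_per_year == 0.0

    def test_time_conversion_weeks_to_years(self):
        m = compute_vl_dr(Vi=10.0, Vr=5.0, Ai=100.0, t_weeks=WEEKS_PER_YEAR)
        assert m.t_years == pytest.approx(1.0)
        assert m.DR_mm_per_year == pytest.approx(0.05)

    def test_linearity_in_time_and_volume_loss(self):
        base = compute_vl_dr(100.0, 96.0, 200.0, 4.0)
        assert compute_vl_dr(100.0, 96.0, 200.0, 8.0).DR_mm_per_year == pytest.approx(base.DR_mm_per_year / 2)
        assert compute_vl_dr(100.0, 92.0, 200.0, 4.0).DR_mm_per_year == pytest.approx(base.DR_mm_per_year * 2)

    def test_negative_volume_loss_flagged_not_clamped(self):
        with pytest.warns(UserWarning, match="negative"):
            m = compute_vl_dr(100.0, 101.0, 200.0, 4.0)
        assert m.negative_vl and m.VL_mm3 == pytest.approx(-1.0)

    @pytest.mark.parametrize("Ai,t", [(0.0, 4.0), (100.0, 0.0), (-1.0, 4.0)])
    def test_invalid_inputs_rejected(self, Ai, t):
        with pytest.raises(ValueError):
            compute_vl_dr(100.0, 90.0, Ai, t)


class TestBoneToImplantContact:
    def test_single_voxel_enclosed_by_bone(self):
        implant = np.zeros((3, 3, 3), bool)
        implant[1, 1, 1] = True
        bone = ~implant
        res = compute_bic(implant, bone)
        assert res.BIC == 1.0 and res.surface_voxels == 1

    def test_block_in_background_has_zero_contact(self):
        implant = np.zeros((6, 6, 6), bool)
        implant[2:4, 2:4, 2:4] = True
        res = compute_bic(implant, np.zeros_like(implant))
        assert res.BIC == 0.0 and res.surface_voxels == 8

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        labels = make_random_labels(rng)
        implant = (labels == 1) | (labels == 2)
        bone = labels == 3
        if not implant.any():
            pytest.skip("degenerate draw")
        res = compute_bic(implant, bone, connectivity=connectivity)
        surface, contact = brute_force_bic(implant, bone, connectivity)
        assert (res.surface_voxels, res.contact_voxels) == (surface, contact)

    def test_overlapping_masks_rejected(self):
        m = np.ones((3, 3, 3), bool)
        with pytest.raises(ValueError, match="overlap"):
            compute_bic(m, m)

    def test_empty_implant_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_bic(np.zeros((3, 3, 3), bool), np.ones((3, 3, 3), bool))


class TestBoneVolumeFraction:
    def test_all_bone_roi(self):
        vol = LabeledVolume(np.full((4, 4, 4), 3, np.uint8), (1, 1, 1))
        assert compute_bvtv(vol, np.ones((4, 4, 4), bool)).BV_TV == 1.0

    def test_implant_excluded_from_both_counts(self):
        # 40 bone, 40 background, 20 implant -> 0.5 regardless of implant
        labels = np.zeros(100, np.uint8)
        labels[:40] = 3
        labels[40:60] = 1
        vol = LabeledVolume(labels.reshape(4, 5, 5), (1, 1, 1))
        res = compute_bvtv(vol, np.ones((4, 5, 5), bool))
        assert res.BV_TV == pytest.approx(0.5)
        assert res.bone_voxels == 40 and res.background_voxels == 40

    def test_invariant_under_gas_implant_relabeling(self):
        rng = np.random.default_rng(0)
        labels = make_random_labels(rng, (10, 10, 10))
        vol = LabeledVolume(labels, (1, 1, 1))
        roi = rng.random((10, 10, 10)) < 0.5
        swapped = labels.copy()
        swapped[labels == 4] = 1
        swapped[labels == 1] = 4
        vol2 = LabeledVolume(swapped, (1, 1, 1))
        assert compute_bvtv(vol, roi).BV_TV == compute_bvtv(vol2, roi).BV_TV

    def test_roi_without_tissue_rejected(self):
        vol = LabeledVolume(np.full((3, 3, 3), 1, np.uint8), (1, 1, 1))
        with pytest.raises(ValueError, match="undefined|no bone"):
            compute_bvtv(vol, np.ones((3, 3, 3), bool))


class TestGasMetrics:
    def _volume(self):
        labels = np.zeros((10, 10, 10), np.uint8)
        labels[:2] = 4   # 200 voxels gas
        labels[2:6] = 1  # 400 voxels implant
        return LabeledVolume(labels, (0.1, 0.1, 0.1))

    def test_ratio_and_normalization(self):
        vol = self._volume()
        gm = compute_gas_metrics(vol, np.ones(vol.shape, bool))
        assert gm.GV_IV == pytest.approx(0.5)
        assert gm.gas_volume_mm3 == pytest.approx(0.2)
        assert gm.gas_per_100mm3 == pytest.approx(0.2 * 100 / 1.0)

    def test_no_gas_gives_zero_ratio(self):
        vol = self._volume()
        roi = np.zeros(vol.shape, bool)
        roi[2:6] = True
        gm = compute_gas_metrics(vol, roi)
        assert gm.gas_volume_mm3 == 0.0 and gm.GV_IV == 0.0

    def test_gas_without_implant_flagged_infinite(self):
        vol = self._volume()
        roi = np.zeros(vol.shape, bool)
        roi[:2] = True
        gm = compute_gas_metrics(vol, roi)
        assert gm.infinite_ratio and np.isinf(gm.GV_IV)

    def test_phantom_per_roi_gas_recovered_exactly(self, coarse_phantom):
        vol, rois, truth = coarse_phantom.volume, coarse_phantom.rois, coarse_phantom.ground_truth
        for name in rois.names:
            region = rois[name]
            if not region.any():
                continue
            gm = compute_gas_metrics(vol, region)
            assert gm.gas_volume_mm3 == pytest.approx(truth.gas_volume_per_roi_mm3[name], abs=1e-12)
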