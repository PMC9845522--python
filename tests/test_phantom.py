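import numpy as np
import pytest
from scipy import ndimage

from osseoquant import (
    BoneEnvironmentSpec,
    DegradationSpec,
    LabeledVolume,
    ScrewSpec,
    apply_degradation,
    class_volume,
    generate_bone_environment,
    generate_phantom,
    generate_screw,
    insert_gas_pockets,
)


class TestGenerateScrew:
    def test_threadless_cylinder_volume_analytic(self):
        """A degenerate spec (no thread, head, or taper) is a plain cylinder."""
        d, L = 3.5, 16.0
        spec = ScrewSpec(outer_diameter=d, core_diameter=d, length=L,
                         head_length=0.0, tip_taper_length=0.0)
        vol = generate_screw(spec, d / 40.0)
        measured = class_volume(vol, "residual_metal")
        expected = np.pi * (d / 2) ** 2 * L
        assert measured == pytest.approx(expected, rel=0.02)

    def test_voxelization_convergence_under_refinement(self, screw_spec):
        # generic (posed) position: center-in-solid voxelization converges at
        # O(spacing^2); in exact grid alignment flat faces converge only at O(spacing)
        from osseoquant.phantom import default_pose

        pose = default_pose(screw_spec)
        v_coarse = class_volume(generate_screw(screw_spec, 0.2, margin_mm=0.5, pose=pose),
                                "residual_metal")
        v_fine = class_volume(generate_screw(screw_spec, 0.1, margin_mm=0.5, pose=pose),
                              "residual_metal")
        assert abs(v_fine - v_coarse) / v_fine < 0.01

    def test_single_connected_component(self, screw_spec):
        vol = generate_screw(screw_spec, 0.05)
        _, n = ndimage.label(vol.labels != 0,
                             structure=ndimage.generate_binary_structure(3, 1))
        assert n == 1

    def test_unresolvable_thread_spacing_rejected(self, screw_spec):
        with pytest.raises(ValueError, match="resolve"):
            generate_screw(screw_spec, 0.5)

    def test_realistic_screw_volume(self, coarse_screw):
        """Default spec lands near a real 3.5 x 16 mm cortical screw (~112 mm^3)."""
        assert class_volume(coarse_screw, "residual_metal") == pytest.approx(112.0, rel=0.05)


class TestApplyDegradation:
    def test_zero_recession_is_identity(self, coarse_screw):
        out = apply_degradation(coarse_screw, DegradationSpec(recession_depth=0.0))
        np.testing.assert_array_equal(out.mask("residual_metal"), coarse_screw.labels != 0)

    def test_full_recession_empties_residual_with_warning(self, coarse_screw):
        with pytest.warns(UserWarning, match="inscribed"):
            out = apply_degradation(coarse_screw, DegradationSpec(recession_depth=10.0))
        assert not out.mask("residual_metal").any()

    def test_sphere_recession_matches_analytic(self, digital_sphere):
        for d in (0.3, 0.5):
            out = apply_degradation(digital_sphere, DegradationSpec(recession_depth=d))
            expected = 4.0 / 3.0 * np.pi * (2.0 - d) ** 3
            assert class_volume(out, "residual_metal") == pytest.approx(expected, rel=0.03)

    def test_residual_volume_monotone_in_depth(self, coarse_screw):
        volumes = [
            class_volume(apply_degradation(coarse_screw, DegradationSpec(recession_depth=d)),
                         "residual_metal")
            for d in (0.0, 0.1, 0.3, 0.6)
        ]
        assert all(a >= b for a, b in zip(volumes, volumes[1:]))

    def test_layer_wraps_residual_metal(self, coarse_screw):
        out = apply_degradation(coarse_screw, DegradationSpec(recession_depth=0.2, layer_thickness=0.3))
        residual = out.mask("residual_metal")
        layer = out.mask("degradation_layer")
        assert layer.any() and not (residual & layer).any()
        # every residual surface voxel is adjacent to the layer shell
        grown = ndimage.binary_dilation(residual)
        assert (layer & grown).any()


class TestBoneEnvironment:
    def test_trabecular_fill_fraction_recovered(self, coarse_phantom):
        spec = BoneEnvironmentSpec(rng_seed=7)
        vol, rois = coarse_phantom.volume, coarse_phantom.rois
        for name in ("dpROI", "ppROI"):
            roi = rois[name]
            # gas pockets overwrite some bone, so measure where no gas landed
            no_gas = roi & ~vol.mask("gas")
            frac = (vol.mask("bone") & no_gas).sum() / no_gas.sum()
            assert frac == pytest.approx(spec.trabecular_fill_fraction, abs=0.03)

    def test_sub_rois_pairwise_disjoint(self, coarse_phantom):
        rois = coarse_phantom.rois
        names = ["dpROI", "ppROI", "cROI", "iROI"]
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not (rois[a] & rois[b]).any()

    def test_screw_carved_out_of_rois_and_bone(self, coarse_phantom):
        vol, rois = coarse_phantom.volume, coarse_phantom.rois
        screw = vol.mask("implant")
        for name in rois.names:
            assert not (rois[name] & screw).any()

    def test_deterministic_for_fixed_seed(self):
        kwargs = dict(seed=3, spacing=0.25, screw_spec=ScrewSpec())
        a = generate_phantom(**kwargs)
        b = generate_phantom(**kwargs)
        np.testing.assert_array_equal(a.volume.labels, b.volume.labels)

    def test_insufficient_margin_rejected(self, coarse_screw):
        with pytest.raises(ValueError, match="margin"):
            generate_bone_environment(BoneEnvironmentSpec(), coarse_screw)


class TestGasPockets:
    def test_sphere_volume_analytic(self):
        vol = LabeledVolume(np.zeros((60, 60, 60), np.uint8), (0.05,) * 3)
        out, truth = insert_gas_pockets(vol, DegradationSpec(gas_pockets=(((1.5, 1.5, 1.5), 1.0),)))
        expected = 4.0 / 3.0 * np.pi
        assert class_volume(out, "gas") == pytest.approx(expected, rel=0.03)
        assert truth.class_volumes_mm3["gas"] == pytest.approx(expected, rel=0.03)

    def test_zero_pockets_identity(self, coarse_phantom):
        out, _ = insert_gas_pockets(coarse_phantom.volume, DegradationSpec())
        np.testing.assert_array_equal(out.labels, coarse_phantom.volume.labels)

    def test_overlapping_spheres_count_union_not_sum(self):
        vol = LabeledVolume(np.zeros((40, 40, 40), np.uint8), (0.1,) * 3)
        pockets = (((2.0, 2.0, 2.0), 0.8), ((2.0, 2.0, 2.6), 0.8))
        out, _ = insert_gas_pockets(vol, DegradationSpec(gas_pockets=pockets))
        # brute-force union of the two analytic spheres over voxel centers
        ax = np.arange(40) * 0.1
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        in_a = (zz - 2) ** 2 + (yy - 2) ** 2 + (xx - 2) ** 2 <= 0.64
        in_b = (zz - 2) ** 2 + (yy - 2) ** 2 + (xx - 2.6) ** 2 <= 0.64
        assert (out.labels == out.scheme["gas"]).sum() == (in_a | in_b).sum()

    def test_pocket_center_in_residual_metal_rejected(self, coarse_screw):
        with pytest.raises(ValueError, match="residual metal"):
            insert_gas_pockets(coarse_screw, DegradationSpec(gas_pockets=(((8.0, 0.0, 0.0), 0.5),)))

    def test_gas_never_overwrites_implant(self, coarse_phantom):
        vol = coarse_phantom.volume
        assert not (vol.mask("gas") & vol.mask("implant")).any()


class TestGroundTruth:
    def test_class_volumes_conserve_grid_volume(self, coarse_phantom):
        truth = coarse_phantom.ground_truth
        assert sum(truth.class_volumes_mm3.values()) == pytest.approx(
            coarse_phantom.volume.physical_volume, abs=1e-9)

    def test_per_roi_gas_matches_rasterization(self, coarse_phantom):
        vol, rois, truth = coarse_phantom.volume, coarse_phantom.rois, coarse_phantom.ground_truth
        gas = vol.mask("gas")
        for name in rois.names:
            expected = (gas & rois[name]).sum() * vol.voxel_volume
            assert truth.gas_volume_per_roi_mm3[name] == pytest.approx(expected, abs=1e-12)
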