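"""Phantom construction: geometry, ground truth, signal void, degradation."""
import numpy as np
import pytest

import implantac as ia
from implantac.phantom import L_VOID, VOID_NAME


class TestGroundTruth:
    def test_default_phantom_matches_known_activities(self, default_phantom):
        labels, activity, truth = default_phantom
        assert truth.total_activity_mbq == pytest.approx(4.68, abs=1e-12)
        # realised volumes within half a voxel volume of the dispensed volumes
        voxvol = labels.voxel_volume_ml
        for spec in ia.PhantomConfig().vial_specs:
            realised = truth.vial(spec.name).volume_ml
            assert abs(realised - spec.volume_ml) <= 0.5 * voxvol + 1e-12

    def test_activity_image_integrates_to_dispensed_activity(self, default_phantom):
        _, activity, truth = default_phantom
        assert ia.total_volume_activity(activity) == pytest.approx(
            truth.total_activity_mbq, rel=1e-12
        )

    def test_zero_vials_gives_zero_activity(self):
        cfg = ia.PhantomConfig(vial_specs=[])
        _, activity, truth = ia.build_knee_phantom(cfg)
        assert not activity.values.any()
        assert truth.total_activity_mbq == 0.0

    def test_hand_counted_four_voxel_vial(self):
        # one 4-voxel vial at 2 MBq/mL in 1 mm^3 voxels -> 2 * 4 * 0.001 MBq
        spec = ia.VialSpec(
            "reference", volume_ml=0.004, activity_mbq=0.008,
            center=(100.0, 60.0, 0.5), diameter_mm=2.0,
        )
        cfg = ia.PhantomConfig(
            grid_shape=(160, 160, 1), voxel_size_mm=(1.0, 1.0, 1.0),
            vial_specs=[spec], min_vial_voxels=1,
        )
        labels, activity, truth = ia.build_knee_phantom(cfg)
        vial = truth.vial("reference")
        assert vial.volume_ml == pytest.approx(0.004)
        assert vial.activity_mbq == pytest.approx(2 * 4 * 0.001)
        assert np.count_nonzero(activity.values) == 4

    def test_unrealizable_vial_volume_raises(self):
        spec = ia.VialSpec("reference", 0.004, 0.008, (100.0, 60.0, 0.5), 2.0)
        cfg = ia.PhantomConfig(
            grid_shape=(160, 160, 1), voxel_size_mm=(1.0, 1.0, 1.0),
            vial_specs=[spec],  # default minimum of 10 voxels
        )
        with pytest.raises(ValueError, match="unrealizable"):
            ia.build_knee_phantom(cfg)

    def test_vial_overlapping_metal_raises(self):
        bad = ia.VialSpec("anterior", 1.53, 1.16, (100.0, 100.0, 42.0))
        cfg = ia.PhantomConfig(vial_specs=[bad])
        with pytest.raises(ValueError, match="anterior"):
            ia.build_knee_phantom(cfg)

    def test_voxelised_volume_close_to_analytic_cylinder(self, default_phantom):
        labels, _, truth = default_phantom
        for spec in ia.PhantomConfig().vial_specs:
            r = spec.diameter_mm / 2
            analytic_ml = np.pi * r**2 * (1000 * spec.volume_ml / (np.pi * r**2)) / 1000
            assert truth.vial(spec.name).volume_ml == pytest.approx(
                analytic_ml, abs=labels.voxel_volume_ml
            )


class TestDeterminism:
    def test_identical_configs_yield_bit_identical_volumes(self):
        cfg = ia.PhantomConfig(grid_shape=(64, 64, 20), voxel_size_mm=(3.125, 3.125, 6.0))
        a = ia.build_knee_phantom(cfg)
        b = ia.build_knee_phantom(cfg)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)


class TestSignalVoid:
    def test_zero_dilation_equals_metal(self, default_phantom):
        labels, _, _ = default_phantom
        metal = labels.mask("cobalt_chromium")
        assert np.array_equal(ia.simulate_signal_void(labels, 0.0), metal)

    def test_negative_dilation_raises(self, default_phantom):
        with pytest.raises(ValueError):
            ia.simulate_signal_void(default_phantom[0], -1.0)

    def test_no_metal_gives_empty_mask(self):
        cfg = ia.PhantomConfig(
            grid_shape=(160, 160, 1), voxel_size_mm=(1.0, 1.0, 1.0), vial_specs=[]
        )
        labels, _, _ = ia.build_knee_phantom(cfg)  # single slice holds no implant
        assert not labels.mask("cobalt_chromium").any()
        assert not ia.simulate_signal_void(labels, 5.0).any()

    def test_single_voxel_unit_dilation_is_six_connected_ball(self):
        values = np.zeros((7, 7, 7), dtype=np.int16)
        values[3, 3, 3] = 1
        labels = ia.LabelVolume(
            values, (1.0, 1.0, 1.0), label_names={0: "air", 1: "cobalt_chromium"}
        )
        mask = ia.simulate_signal_void(labels, 1.0)
        assert mask.sum() == 7
        assert mask[3, 3, 3] and mask[2, 3, 3] and mask[3, 4, 3]

    @pytest.mark.parametrize("small,large", [(0.0, 2.0), (2.0, 4.0), (4.0, 8.0)])
    def test_mask_contains_metal_and_grows_monotonically(
        self, default_phantom, small, large
    ):
        labels, _, _ = default_phantom
        metal = labels.mask("cobalt_chromium")
        m_small = ia.simulate_signal_void(labels, small)
        m_large = ia.simulate_signal_void(labels, large)
        assert np.all(metal <= m_small)
        assert np.all(m_small <= m_large)


class TestDegradedLabels:
    def test_empty_mask_is_identity(self, default_phantom):
        labels, _, _ = default_phantom
        degraded = ia.make_degraded_labels(labels, np.zeros(labels.shape, bool))
        assert np.array_equal(degraded.values, labels.values)

    def test_full_mask_saturates_to_void(self, default_phantom):
        labels, _, _ = default_phantom
        degraded = ia.make_degraded_labels(labels, np.ones(labels.shape, bool))
        assert np.all(degraded.values == L_VOID)
        assert degraded.label_names[L_VOID] == VOID_NAME

    def test_void_count_matches_independent_dilation(self, default_phantom):
        # oracle: morphological dilation with an explicit ellipsoidal
        # structuring element (independent of the distance-transform path)
        labels, _, _ = default_phantom
        from scipy import ndimage

        metal = labels.mask("cobalt_chromium")
        radius_mm = 2.0
        d = labels.voxel_size_mm
        half = [int(np.floor(radius_mm / di)) for di in d]
        offs = np.meshgrid(
            *[np.arange(-h, h + 1) * di for h, di in zip(half, d)], indexing="ij"
        )
        struct = sum(o**2 for o in offs) <= radius_mm**2 + 1e-9
        expected = int(ndimage.binary_dilation(metal, structure=struct).sum())
        degraded = ia.make_degraded_labels(
            labels, ia.simulate_signal_void(labels, radius_mm)
        )
        assert int((degraded.values == L_VOID).sum()) == expected

    def test_grid_mismatch_raises(self, default_phantom):
        labels, _, _ = default_phantom
        with pytest.raises(ValueError, match="mask"):
            ia.make_degraded_labels(labels, np.zeros((2, 2, 2), bool))
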