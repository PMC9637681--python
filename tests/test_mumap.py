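"""Mu-map construction, void inpainting strategies, and rigid model placement."""
import numpy as np
import pytest

import implantac as ia


@pytest.fixture(scope="module")
def degraded_setup():
    """Default phantom with its 4 mm signal void and truth mu map."""
    labels, _, _ = ia.build_knee_phantom(ia.PhantomConfig())
    truth_mu = ia.mumap_from_labels(labels)
    void = ia.simulate_signal_void(labels, 4.0)
    degraded = ia.make_degraded_labels(labels, void)
    return labels, truth_mu, void, degraded


class TestMumapFromLabels:
    def test_lookup_against_material_table(self):
        values = np.array([[[0, 1], [3, 6]]], dtype=np.int16)  # air, soft, bone, poly
        labels = ia.LabelVolume(
            values, (1.0, 1.0, 1.0),
            label_names={0: "air", 1: "soft_tissue", 3: "bone", 6: "polyethylene"},
        )
        mu = ia.mumap_from_labels(labels)
        assert mu.values.flatten().tolist() == [0.0, 0.0927, 0.13, 0.079]

    def test_all_air_is_zero(self):
        labels = ia.LabelVolume(
            np.zeros((4, 4, 2), np.int16), (1, 1, 1), label_names={0: "air"}
        )
        assert not ia.mumap_from_labels(labels).values.any()

    def test_cobalt_chromium_value(self, degraded_setup):
        labels, truth_mu, _, _ = degraded_setup
        metal = labels.mask("cobalt_chromium")
        assert np.all(truth_mu.values[metal] == 0.72)

    def test_unknown_label_raises_with_name(self):
        labels = ia.LabelVolume(
            np.full((2, 2, 2), 7, np.int16), (1, 1, 1), label_names={7: "titanium"}
        )
        with pytest.raises(ValueError, match="titanium"):
            ia.mumap_from_labels(labels)

    def test_void_label_directs_to_inpainting(self, degraded_setup):
        *_, degraded = degraded_setup
        with pytest.raises(ValueError, match="inpaint"):
            ia.mumap_from_labels(degraded)

    def test_user_supplied_lac_supports_titanium(self):
        labels = ia.LabelVolume(
            np.full((2, 2, 2), 7, np.int16), (1, 1, 1), label_names={7: "titanium"}
        )
        table = ia.MaterialTable.default().with_updates(titanium=0.44)
        assert np.all(ia.mumap_from_labels(labels, table).values == 0.44)


class TestInpainting:
    def test_no_void_all_strategies_equal_truth(self, degraded_setup):
        labels, truth_mu, _, _ = degraded_setup
        for fn in (ia.inpaint_original, ia.inpaint_simple_tissue):
            assert np.array_equal(fn(labels).values, truth_mu.values)

    def test_all_void_saturates(self):
        values = np.full((3, 3, 3), 99, np.int16)
        labels = ia.LabelVolume(values, (1, 1, 1), label_names={99: "void"})
        assert not ia.inpaint_original(labels).values.any()
        assert np.all(ia.inpaint_simple_tissue(labels).values == 0.0927)

    def test_original_differs_from_truth_exactly_on_void(self, degraded_setup):
        _, truth_mu, void, degraded = degraded_setup
        mu = ia.inpaint_original(degraded)
        diff = mu.values != truth_mu.values
        assert np.all(mu.values[void] == 0.0)
        # differences only where the void covers non-air material
        assert np.array_equal(diff, void & (truth_mu.values != 0))

    def test_simple_tissue_fills_void_with_soft_tissue(self, degraded_setup):
        _, truth_mu, void, degraded = degraded_setup
        mu = ia.inpaint_simple_tissue(degraded)
        assert np.all(mu.values[void] == 0.0927)
        assert np.array_equal(mu.values[~void], truth_mu.values[~void])

    def test_values_are_drawn_from_the_table(self, degraded_setup):
        labels, _, _, degraded = degraded_setup
        model = ia.build_implant_model(labels.shape, labels.voxel_size_mm)
        allowed = set(ia.MaterialTable.default().lacs.values())
        for mu in (
            ia.inpaint_original(degraded),
            ia.inpaint_simple_tissue(degraded),
            ia.inpaint_with_model(degraded, model=model),
        ):
            assert set(np.unique(mu.values)).issubset(allowed | {0.0})

    def test_model_restores_metal_and_insert_lacs(self, degraded_setup):
        labels, _, void, degraded = degraded_setup
        model = ia.build_implant_model(labels.shape, labels.voxel_size_mm)
        mu = ia.inpaint_with_model(degraded, model=model)
        femoral = model.occupancy["femoral"]
        insert = model.occupancy["insert"]
        assert np.all(mu.values[femoral & void] == 0.72)
        assert np.all(mu.values[insert & void] == 0.079)

    def test_accurate_model_matches_truth_inside_void_except_rim(self, degraded_setup):
        labels, truth_mu, void, degraded = degraded_setup
        model = ia.build_implant_model(labels.shape, labels.voxel_size_mm)
        mu = ia.inpaint_with_model(degraded, model=model)
        implant = (
            model.occupancy["femoral"]
            | model.occupancy["tibial"]
            | model.occupancy["insert"]
        )
        # exact on the implant itself; the dilated rim is filled with soft tissue
        assert np.array_equal(mu.values[implant], truth_mu.values[implant])
        rim = void & ~implant
        assert np.all(mu.values[rim] == 0.0927)

    def test_non_void_voxels_bit_identical_to_truth(self, degraded_setup):
        labels, truth_mu, void, degraded = degraded_setup
        model = ia.build_implant_model(labels.shape, labels.voxel_size_mm)
        for mu in (
            ia.inpaint_original(degraded),
            ia.inpaint_simple_tissue(degraded),
            ia.inpaint_with_model(degraded, model=model),
        ):
            assert np.array_equal(mu.values[~void], truth_mu.values[~void])

    def test_void_mae_ordering_accurate_below_simple_below_original(
        self, degraded_setup
    ):
        labels, truth_mu, void, degraded = degraded_setup
        model = ia.build_implant_model(labels.shape, labels.voxel_size_mm)
        def mae(mu):
            return float(np.abs(mu.values[void] - truth_mu.values[void]).mean())
        assert (
            mae(ia.inpaint_with_model(degraded, model=model))
            < mae(ia.inpaint_simple_tissue(degraded))
            < mae(ia.inpaint_original(degraded))
        )

    def test_component_outside_grid_raises(self, degraded_setup):
        labels, *_ , degraded = degraded_setup
        model = ia.build_implant_model(labels.shape, labels.voxel_size_mm)
        pose = ia.RigidTransform(translation_mm=(500.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="outside the grid"):
            ia.inpaint_with_model(degraded, model=model, pose=pose)

    def test_misregistered_component_logs_warning(self, degraded_setup, caplog):
        labels, *_, degraded = degraded_setup
        model = ia.build_implant_model(labels.shape, labels.voxel_size_mm)
        pose = ia.RigidTransform(translation_mm=(0.0, 25.0, 0.0))
        with caplog.at_level("WARNING", logger="implantac.mumap"):
            ia.inpaint_with_model(degraded, model=model, pose=pose)
        assert any("non-void anatomy" in r.getMessage() for r in caplog.records)


class TestRigidPlacement:
    def test_identity_pose_reproduces_occupancy(self):
        model = ia.build_implant_model((64, 64, 20), (3.125, 3.125, 6.0))
        occ = ia.apply_rigid(model, ia.RigidTransform())
        for name in model.components:
            assert np.array_equal(occ[name], model.occupancy[name])

    def test_one_voxel_pitch_translation_shifts_indices(self):
        model = ia.build_implant_model((64, 64, 20), (3.125, 3.125, 6.0))
        occ = ia.apply_rigid(model, ia.RigidTransform(translation_mm=(3.125, 0, 0)))
        src = model.occupancy["tibial"]
        assert np.array_equal(occ["tibial"][1:], src[:-1])

    def test_double_half_turn_is_identity(self):
        model = ia.build_implant_model((64, 64, 20), (3.125, 3.125, 6.0))
        half_turn = ia.RigidTransform(rotation_deg=(0, 0, 180))
        once = ia.apply_rigid(model, half_turn)
        twice_model = ia.ImplantModel(once, model.voxel_size_mm, variant="accurate")
        twice = ia.apply_rigid(twice_model, half_turn)
        for name in model.components:
            assert np.array_equal(twice[name], model.occupancy[name])

    def test_transform_inverse_roundtrip(self):
        pose = ia.RigidTransform(rotation_deg=(10.0, -20.0, 35.0),
                                 translation_mm=(4.0, -7.5, 2.0))
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 200, size=(50, 3))
        center = (100.0, 100.0, 60.0)
        back = pose.apply_inverse(pose.apply(pts, center), center)
        assert np.max(np.abs(back - pts)) < 1e-6

    @pytest.mark.parametrize("variant", ["accurate", "alternative"])
    def test_components_pairwise_disjoint(self, variant):
        model = ia.build_implant_model((160, 160, 40), (1.25, 1.25, 3.0), variant)
        names = model.components
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                assert not np.any(
                    model.occupancy[names[a]] & model.occupancy[names[b]]
                )

    def test_alternative_variant_differs_from_accurate(self):
        acc = ia.build_implant_model((160, 160, 40), (1.25, 1.25, 3.0), "accurate")
        alt = ia.build_implant_model((160, 160, 40), (1.25, 1.25, 3.0), "alternative")
        assert any(
            not np.array_equal(acc.occupancy[c], alt.occupancy[c])
            for c in acc.components
        )
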