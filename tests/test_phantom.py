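"""Phantom generator: geometry, gaps, density raster, calibration inserts."""

import dataclasses

import numpy as np
import pytest

import tibfrac as tf
from tibfrac import phantom as ph


class TestGeometry:
    def test_expected_labels_present(self, phantom_bundle):
        labels = phantom_bundle.label_image.values
        for lab in (ph.SHAFT, ph.PLATEAU, ph.FRAG_DEPRESSED,
                    ph.FRAG_SEPARATED, ph.SCREW, ph.CEMENT):
            assert np.any(labels == lab), ph.LABEL_NAMES[lab]

    def test_fragment_labels_disjoint_and_gap_fidelity(self, phantom_bundle,
                                                       default_params):
        """Residual fracture gaps are reproduced within one voxel diagonal."""
        img = phantom_bundle.label_image
        diag = np.linalg.norm(img.spacing)
        d = tf.min_label_distance(img, ph.FRAG_DEPRESSED, ph.PLATEAU)
        assert abs(d - default_params.depressed_gap) <= diag
        s = tf.min_label_distance(img, ph.FRAG_SEPARATED, ph.PLATEAU)
        assert abs(s - default_params.separated_gap) <= diag

    def test_fused_state_merges_fragments(self, default_params):
        params = dataclasses.replace(default_params, healing_state="fused")
        label_image, _ = tf.build_geometry(params)
        labels = label_image.values
        assert not np.any(labels == ph.FRAG_DEPRESSED)
        assert not np.any(labels == ph.FRAG_SEPARATED)
        # gaps filled: the plateau region is simply connected around the
        # would-be fracture (no interior background)
        from scipy import ndimage
        interior = ndimage.binary_closing(labels > 0, np.ones((3, 3, 3)),
                                          iterations=3) & (labels == 0)
        assert interior.sum() == 0

    def test_mobile_and_bonded_share_geometry(self, default_params):
        a, _ = tf.build_geometry(
            dataclasses.replace(default_params, healing_state="mobile"))
        b, _ = tf.build_geometry(
            dataclasses.replace(default_params, healing_state="bonded"))
        assert np.array_equal(a.values, b.values)

    def test_cement_flag_semantics(self, default_params):
        """Dropping cement only returns its voxels to plateau bone or void."""
        with_c, _ = tf.build_geometry(
            dataclasses.replace(default_params, cement=True))
        without, _ = tf.build_geometry(
            dataclasses.replace(default_params, cement=False))
        assert not np.any(without.values == ph.CEMENT)
        changed = with_c.values != without.values
        assert np.all(with_c.values[changed] == ph.CEMENT)
        assert set(np.unique(without.values[changed])) <= {ph.PLATEAU,
                                                           ph.BACKGROUND}
        for lab in (ph.SHAFT, ph.FRAG_DEPRESSED, ph.FRAG_SEPARATED, ph.SCREW):
            assert (with_c.values == lab).sum() == (without.values == lab).sum()

    def test_unicortical_void_track(self, default_params):
        params = dataclasses.replace(default_params,
                                     screw_variant="unicortical_50")
        label_image, meta = tf.build_geometry(params)
        assert np.any(label_image.values == ph.SCREW_VOID)
        assert meta["screw_axis"]["length"] == 50.0
        assert meta["screw_axis"]["thread_length"] == 20.0
        bi, _ = tf.build_geometry(default_params)
        assert not np.any(bi.values == ph.SCREW_VOID)

    @pytest.mark.parametrize("field,value", [
        ("shaft_length", -1.0), ("plateau_width", 0.0), ("noise_sd", -0.1),
        ("depressed_gap", -0.5), ("screw_variant", "tricortical"),
        ("healing_state", "welded"),
    ])
    def test_invalid_params_rejected(self, field, value):
        with pytest.raises(ValueError):
            tf.PhantomParams(**{field: value})


class TestDensityRaster:
    def test_zero_noise_identity_map_exact(self, default_params):
        params = dataclasses.replace(default_params, noise_sd=0.0,
                                     truth_slope=1.0, truth_intercept=0.0)
        label_image, meta = tf.build_geometry(params)
        img = tf.rasterize_density(label_image, params, meta)
        labels = label_image.values
        trab = img.values[labels == ph.PLATEAU]
        # plateau interior voxels: trabecular mean; shell voxels: cortical
        assert set(np.round(np.unique(trab), 9)) <= {
            params.trabecular_density_mean, params.cortical_density_mean}
        assert np.any(np.isclose(trab, params.trabecular_density_mean))

    def test_affine_truth_map(self, default_params):
        """density 1.0 through the map (slope .005, intercept -.5) -> raw 300."""
        params = dataclasses.replace(default_params, noise_sd=0.0,
                                     truth_slope=0.005, truth_intercept=-0.5,
                                     trabecular_density_mean=1.0)
        label_image, meta = tf.build_geometry(params)
        img = tf.rasterize_density(label_image, params, meta)
        interior = img.values[label_image.values == ph.FRAG_DEPRESSED]
        assert np.any(np.isclose(interior, 300.0))

    def test_screw_void_density(self, default_params):
        params = dataclasses.replace(default_params, noise_sd=0.0,
                                     truth_slope=1.0, truth_intercept=0.0,
                                     screw_variant="unicortical_50")
        label_image, meta = tf.build_geometry(params)
        img = tf.rasterize_density(label_image, params, meta)
        void = img.values[label_image.values == ph.SCREW_VOID]
        assert np.allclose(void, 0.94)

    def test_determinism_byte_identical(self, default_params):
        a = tf.build_phantom(default_params)
        b = tf.build_phantom(default_params)
        assert a.density_image.values.tobytes() == b.density_image.values.tobytes()
        assert a.label_image.values.tobytes() == b.label_image.values.tobytes()
        c = tf.build_phantom(dataclasses.replace(default_params, seed=1))
        assert a.density_image.values.tobytes() != c.density_image.values.tobytes()

    def test_nonfinite_density_rejected(self, default_params):
        params = dataclasses.replace(default_params)
        params.trabecular_density_mean = float("nan")   # bypass validation
        label_image, meta = tf.build_geometry(default_params)
        with pytest.raises(ValueError):
            tf.rasterize_density(label_image, params, meta)


class TestInserts:
    def test_insert_means_map_through_truth(self, default_params):
        params = dataclasses.replace(default_params, noise_sd=0.0)
        bundle = tf.build_phantom(params)
        from tibfrac.calibration import extract_insert_statistics
        pairs = extract_insert_statistics(bundle.density_image,
                                          bundle.insert_spec)
        for raw, rho in pairs:
            expected = (rho - params.truth_intercept) / params.truth_slope
            assert raw == pytest.approx(expected, abs=1e-9)

    def test_too_few_distinct_densities(self, phantom_bundle, default_params):
        spec = [{"center": (10, 10, 10), "radius": 3, "density": 0.5},
                {"center": (30, 10, 10), "radius": 3, "density": 0.5}]
        with pytest.raises(ValueError, match="underdetermined"):
            tf.place_calibration_inserts(phantom_bundle.density_image, spec,
                                         default_params)

    def test_overlapping_inserts_rejected(self, phantom_bundle, default_params):
        spec = [{"center": (10, 10, 10), "radius": 4, "density": 0.0},
                {"center": (14, 10, 10), "radius": 4, "density": 1.0}]
        with pytest.raises(ValueError, match="overlap"):
            tf.place_calibration_inserts(phantom_bundle.density_image, spec,
                                         default_params)

    def test_insert_outside_image_rejected(self, phantom_bundle, default_params):
        spec = [{"center": (2, 10, 10), "radius": 4, "density": 0.0},
                {"center": (30, 10, 10), "radius": 4, "density": 1.0}]
        with pytest.raises(ValueError, match="outside"):
            tf.place_calibration_inserts(phantom_bundle.density_image, spec,
                                         default_params)


class TestIO:
    def test_nifti_round_trip(self, phantom_bundle, tmp_path):
        path = tmp_path / "density.nii.gz"
        phantom_bundle.density_image.save(path)
        back = tf.VoxelImage.from_nifti(path)
        assert back.units == "raw"
        assert np.allclose(back.values, phantom_bundle.density_image.values)
        assert np.allclose(back.spacing, phantom_bundle.density_image.spacing)

    def test_bundle_save(self, phantom_bundle, tmp_path):
        phantom_bundle.save(tmp_path / "out")
        assert (tmp_path / "out" / "labels.nii.gz").exists()
        assert (tmp_path / "out" / "phantom.json").exists()
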