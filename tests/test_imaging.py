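import numpy as np
import pytest

from sifyield import synthetic
from sifyield.imaging import (
    angle_mask,
    calibrate_dn,
    cluster_image,
    identify_sunlit_leaves,
    identify_white_panel,
    plot_mean_spectra,
)
from sifyield.spectra import Spectrum, SpectrumKind, ndvi


def _cluster_scene(scene, seed=0, restarts=2):
    radiance, saturated = calibrate_dn(scene.dn, scene.gain, scene.offset)
    cm = cluster_image(radiance, k=len(scene.material_names), seed=seed,
                       restarts=restarts, exclude=saturated,
                       wavelengths=scene.wavelengths)
    return radiance, cm


def _r_white(wl, level=0.99):
    return Spectrum(wl, np.full(wl.size, level), SpectrumKind.REFLECTANCE)


def _agreement(labels_a, labels_b, k):
    """Best-permutation pixel agreement between two label images."""
    from scipy.optimize import linear_sum_assignment
    conf = np.zeros((k, k))
    for a, b in zip(labels_a.ravel(), labels_b.ravel()):
        conf[a, b] += 1
    r, c = linear_sum_assignment(-conf)
    return conf[r, c].sum() / labels_a.size


class TestCalibrate:
    def test_linear_map(self):
        dn = np.full((1, 1, 3), 1000.0)
        radiance, sat = calibrate_dn(dn, np.full(3, 0.001), np.zeros(3))
        assert np.allclose(radiance, 1.0)
        assert not sat.any()

    def test_zero_dn_gives_offset(self):
        dn = np.zeros((1, 1, 3))
        radiance, _ = calibrate_dn(dn, np.ones(3), np.full(3, 0.25))
        assert np.allclose(radiance, 0.25)

    def test_saturated_flagged(self):
        dn = np.zeros((1, 2, 3))
        dn[0, 1, 2] = 4095.0
        _, sat = calibrate_dn(dn, np.ones(3), np.zeros(3))
        assert sat.tolist() == [[False, True]]

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError, match="gain"):
            calibrate_dn(np.zeros((1, 1, 2)), np.array([1.0, 0.0]), np.zeros(2))

    def test_roundtrip_vs_synthetic(self, small_scene, irradiance):
        radiance, _ = calibrate_dn(small_scene.dn, small_scene.gain,
                                   small_scene.offset)
        # white-panel pixels must carry exactly R_white * E / pi
        from sifyield.spectra import resample_spectrum
        e_cam = resample_spectrum(irradiance, small_scene.wavelengths)
        white = small_scene.labels == small_scene.material_names.index("white_panel")
        expected = 0.99 * e_cam.values / np.pi
        assert np.allclose(radiance[white], expected, rtol=1e-9)


class TestClusterImage:
    def test_noiseless_reproduces_layout(self, small_scene):
        _, cm = _cluster_scene(small_scene)
        assert _agreement(cm.labels, small_scene.labels, cm.k) == 1.0

    def test_two_seeds_same_partition(self, small_scene):
        _, cm1 = _cluster_scene(small_scene, seed=1)
        _, cm2 = _cluster_scene(small_scene, seed=99)
        assert _agreement(cm1.labels, cm2.labels, cm1.k) == 1.0

    def test_moderate_noise_99_percent(self, materials, irradiance):
        layout = synthetic.default_layout(16, 64)
        scene = synthetic.make_scene(materials, layout, irradiance,
                                     noise_sd=5.0, seed=7)
        _, cm = _cluster_scene(scene)
        assert _agreement(cm.labels, scene.labels, cm.k) >= 0.99

    def test_k_larger_than_distinct_pixels(self):
        cube = np.ones((2, 2, 5))
        with pytest.raises(ValueError, match="distinct"):
            cluster_image(cube, k=3)

    def test_deterministic_given_seed(self, small_scene):
        _, cm1 = _cluster_scene(small_scene, seed=5)
        _, cm2 = _cluster_scene(small_scene, seed=5)
        assert np.array_equal(cm1.labels, cm2.labels)


class TestIdentifyWhitePanel:
    def test_synthetic_panel_found(self, small_scene):
        _, cm = _cluster_scene(small_scene)
        white_id = identify_white_panel(cm)
        panel_label = small_scene.material_names.index("white_panel")
        # majority of pixels in the winning cluster are true panel pixels
        member = cm.labels == white_id
        assert (small_scene.labels[member] == panel_label).mean() == 1.0

    def test_two_cluster_argmax(self):
        from sifyield.imaging import ClusterMap
        wl = np.arange(3.0)
        specs = [Spectrum(wl, np.full(3, 5.0)), Spectrum(wl, np.full(3, 1.0))]
        cm = ClusterMap(labels=np.array([[0, 1]]), k=2,
                        mean_radiance=np.array([5.0, 1.0]), mean_spectra=specs,
                        valid=np.ones((1, 2), bool))
        assert identify_white_panel(cm) == 0

    def test_small_panel_still_found(self, materials, irradiance):
        # panel occupies ~2% of pixels
        layout = synthetic.default_layout(10, 100)
        layout[layout == 0] = 5
        layout[0, 48:50] = 0
        layout[1, 48:50] = 0  # wait: keep >=4 panel pixels
        scene = synthetic.make_scene(materials, layout, irradiance, noise_sd=0.0)
        _, cm = _cluster_scene(scene)
        white_id = identify_white_panel(cm)
        assert (scene.labels[cm.labels == white_id] == 0).all()

    def test_tie_raises(self):
        from sifyield.imaging import ClusterMap
        wl = np.arange(3.0)
        specs = [Spectrum(wl, np.full(3, 2.0))] * 2
        cm = ClusterMap(labels=np.array([[0, 1]]), k=2,
                        mean_radiance=np.array([2.0, 2.0]), mean_spectra=specs,
                        valid=np.ones((1, 2), bool))
        with pytest.raises(ValueError, match="tie"):
            identify_white_panel(cm)


class TestIdentifySunlitLeaves:
    def test_sunlit_brighter_than_shaded(self, small_scene):
        _, cm = _cluster_scene(small_scene)
        white_id = identify_white_panel(cm)
        sunlit_id, ndvi_map = identify_sunlit_leaves(
            cm, white_id, _r_white(small_scene.wavelengths))
        sun_label = small_scene.material_names.index("sunlit_leaf")
        assert (small_scene.labels[cm.labels == sunlit_id] == sun_label).all()

    def test_soil_excluded_by_threshold(self, small_scene):
        _, cm = _cluster_scene(small_scene)
        white_id = identify_white_panel(cm)
        _, ndvi_map = identify_sunlit_leaves(cm, white_id,
                                             _r_white(small_scene.wavelengths))
        veg = {c for c, v in ndvi_map.items() if v > 0.1}
        assert len(veg) == 2
        soil_label = small_scene.material_names.index("soil")
        for c in ndvi_map:
            member_true = small_scene.labels[cm.labels == c]
            if member_true.size and (member_true == soil_label).all():
                assert ndvi_map[c] <= 0.1

    def test_no_vegetation_errors(self, wl_cam, irradiance):
        from sifyield.synthetic import MaterialSpec, flat_reflectance, make_scene
        wl = wl_cam
        zero_f = Spectrum(wl, np.zeros(wl.size))
        mats = [
            MaterialSpec("white_panel", flat_reflectance(wl, 0.99), zero_f, 1.0),
            MaterialSpec("soil", flat_reflectance(wl, 0.3), zero_f, 1.0),
            MaterialSpec("background", flat_reflectance(wl, 0.05), zero_f, 1.0),
        ]
        layout = np.tile(np.array([[0, 1, 2]]), (4, 4))[:, :6]
        scene = make_scene(mats, layout, irradiance, noise_sd=0.0)
        radiance, _ = calibrate_dn(scene.dn, scene.gain, scene.offset)
        cm = cluster_image(radiance, k=3, seed=0, wavelengths=wl)
        white_id = identify_white_panel(cm)
        with pytest.raises(ValueError, match="NDVI threshold"):
            identify_sunlit_leaves(cm, white_id, _r_white(wl))

    def test_three_vegetation_clusters_brightest_wins(self, wl_fine, irradiance):
        from sifyield.synthetic import (MaterialSpec, flat_reflectance,
                                        leaf_reflectance, make_scene)
        zero_f_fine = Spectrum(wl_fine, np.zeros(wl_fine.size))
        leaf = leaf_reflectance(wl_fine)
        mats = [
            MaterialSpec("white_panel", flat_reflectance(wl_fine, 0.99), zero_f_fine, 1.0),
            MaterialSpec("sunlit_leaf", leaf, zero_f_fine, 1.0),
            MaterialSpec("shaded_leaf", leaf, zero_f_fine, 0.55),
            MaterialSpec("deep_shade_leaf", leaf, zero_f_fine, 0.3),
        ]
        layout = np.tile(np.array([[0, 1, 2, 3]]), (6, 2))
        scene = make_scene(mats, layout, irradiance, noise_sd=0.0)
        radiance, _ = calibrate_dn(scene.dn, scene.gain, scene.offset)
        cm = cluster_image(radiance, k=4, seed=0, wavelengths=scene.wavelengths)
        white_id = identify_white_panel(cm)
        with pytest.raises(ValueError, match="exactly 2"):
            identify_sunlit_leaves(cm, white_id, _r_white(scene.wavelengths))
        sunlit_id, _ = identify_sunlit_leaves(cm, white_id,
                                              _r_white(scene.wavelengths),
                                              require_two=False)
        assert (scene.labels[cm.labels == sunlit_id] == 1).all()


class TestAngleMask:
    def test_full_field(self):
        m = angle_mask(640, 46.1, 46.1)
        assert m.kept_columns.size == 640

    def test_zero_keeps_centre_only(self):
        m = angle_mask(641, 46.1, 0.0)  # odd count -> exact centre column
        assert m.kept_columns.tolist() == [320]

    def test_defaults_match_brute_force(self):
        m = angle_mask()
        # independent brute force over all columns
        kept = [i for i in range(640)
                if abs(-46.1 + i * (2 * 46.1 / 639)) <= 15.0]
        assert m.kept_columns.tolist() == kept
        assert kept[0] == 216 and kept[-1] == 423 and len(kept) == 208

    def test_symmetric_about_centre(self):
        m = angle_mask(640, 46.1, 15.0)
        assert m.kept_columns[0] + m.kept_columns[-1] == 639

    def test_monotone_shrinking(self):
        prev = None
        for keep in (40.0, 30.0, 20.0, 10.0, 5.0):
            cols = set(angle_mask(640, 46.1, keep).kept_columns.tolist())
            if prev is not None:
                assert cols <= prev
            prev = cols

    def test_keep_beyond_fov_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            angle_mask(640, 46.1, 50.0)


class TestPlotMeanSpectra:
    def _pipeline(self, scene):
        radiance, cm = None, None
        radiance, cm = _cluster_scene(scene)
        white_id = identify_white_panel(cm)
        r_white = _r_white(scene.wavelengths)
        sunlit_id, _ = identify_sunlit_leaves(cm, white_id, r_white)
        mask = angle_mask(n_channels=scene.dn.shape[1], half_fov=46.1,
                          keep_half_angle=15.0)
        return radiance, cm, white_id, sunlit_id, mask, r_white

    def test_uniform_material_mean_is_material_spectrum(self, small_scene, irradiance):
        radiance, cm, white_id, sunlit_id, mask, r_white = self._pipeline(small_scene)
        mean_rad, mean_refl, _ = plot_mean_spectra(
            radiance, small_scene.wavelengths, cm, sunlit_id, mask, white_id, r_white)
        sun = small_scene.labels == small_scene.material_names.index("sunlit_leaf")
        expected = radiance[sun][0]  # uniform material: every pixel identical
        assert np.allclose(mean_rad.values, expected, rtol=1e-12)

    def test_ndvi_close_to_material_truth(self, small_scene, materials):
        radiance, cm, white_id, sunlit_id, mask, r_white = self._pipeline(small_scene)
        _, _, ndvi_value = plot_mean_spectra(
            radiance, small_scene.wavelengths, cm, sunlit_id, mask, white_id, r_white)
        leaf = next(m for m in materials if m.name == "sunlit_leaf")
        # fluorescence contaminates NIR slightly; tolerance covers it
        assert ndvi_value == pytest.approx(ndvi(leaf.reflectance_spectrum), abs=0.02)

    def test_mean_of_mixed_levels(self):
        # half pixels at L, half at 3L -> mean 2L
        wl = np.linspace(400, 900, 5)
        cube = np.ones((2, 2, 5))
        cube[1] = 3.0
        from sifyield.imaging import AngleMask, ClusterMap
        cm = ClusterMap(labels=np.zeros((2, 2), int), k=1,
                        mean_radiance=np.array([2.0]),
                        mean_spectra=[Spectrum(wl, np.full(5, 2.0))],
                        valid=np.ones((2, 2), bool))
        mask = AngleMask(2, 46.1, 46.1, np.array([0, 1]))
        mean_rad, _, _ = plot_mean_spectra(
            cube, wl, cm, 0, mask, 0, _r_white(wl, 1.0))
        assert np.allclose(mean_rad.values, 2.0)

    def test_empty_selection_errors(self, small_scene):
        radiance, cm, white_id, sunlit_id, mask, r_white = self._pipeline(small_scene)
        from sifyield.imaging import AngleMask
        # a mask keeping only columns where no sunlit pixel lives
        sun_cols = np.nonzero((cm.labels == sunlit_id).any(axis=0))[0]
        other = np.setdiff1d(np.arange(small_scene.dn.shape[1]), sun_cols)[:1]
        tiny = AngleMask(small_scene.dn.shape[1], 46.1, 0.1, other)
        with pytest.raises(ValueError, match="no sunlit"):
            plot_mean_spectra(radiance, small_scene.wavelengths, cm, sunlit_id,
                              tiny, white_id, r_white)

    def test_noiseless_reflectance_matches_material(self, small_scene, materials):
        radiance, cm, white_id, sunlit_id, mask, r_white = self._pipeline(small_scene)
        _, mean_refl, _ = plot_mean_spectra(
            radiance, small_scene.wavelengths, cm, sunlit_id, mask, white_id, r_white)
        from sifyield.spectra import resample_spectrum
        leaf = next(m for m in materials if m.name == "sunlit_leaf")
        r_cam = resample_spectrum(leaf.reflectance_spectrum, small_scene.wavelengths)
        # outside the fluorescence emission region the match is machine-tight
        vis = small_scene.wavelengths < 500
        assert np.allclose(mean_refl.values[vis], r_cam.values[vis], atol=1e-9)
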