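import numpy as np
import pytest

import npvret as nv
from npvret import forward_model as fm
from npvret.exceptions import ValidationError


@pytest.fixture()
def smooth_baseline():
    wl = np.arange(1500.0, 2100.0, 10.0)
    return wl, 0.2 + 0.05 * np.sin(wl / 300.0)


class TestDespike:
    def test_single_spike_replaced(self, smooth_baseline):
        wl, base = smooth_baseline
        spiked = base.copy()
        spiked[20] += 0.05
        cleaned = nv.despike(spiked)
        assert abs(cleaned[20] - base[20]) < 0.005
        np.testing.assert_array_equal(cleaned[:20], spiked[:20])

    def test_negative_spike_replaced(self, smooth_baseline):
        wl, base = smooth_baseline
        spiked = base.copy()
        spiked[30] -= 0.05
        cleaned = nv.despike(spiked)
        assert abs(cleaned[30] - base[30]) < 0.005

    def test_below_threshold_untouched(self, smooth_baseline):
        wl, base = smooth_baseline
        spiked = base.copy()
        spiked[20] += 0.01
        np.testing.assert_array_equal(nv.despike(spiked), spiked)

    def test_linear_identity(self):
        x = np.linspace(0.1, 0.4, 50)
        np.testing.assert_array_equal(nv.despike(x), x)

    def test_idempotent(self, smooth_baseline):
        wl, base = smooth_baseline
        rng = np.random.default_rng(0)
        spiked = base + np.where(rng.random(base.size) < 0.1,
                                 rng.uniform(0.02, 0.08, base.size), 0.0)
        once = nv.despike(spiked)
        twice = nv.despike(once)
        np.testing.assert_array_equal(once, twice)

    def test_degenerate_warns(self):
        x = np.zeros(9)
        x[1::2] = 1.0  # alternating comb: everything is a spike
        with pytest.warns(UserWarning, match="degenerate"):
            nv.despike(x, threshold=0.01)

    def test_too_few_bands(self):
        with pytest.raises(ValidationError):
            nv.despike(np.array([0.1, 0.2]))


class TestSmoothSpline:
    def test_reproduces_smooth_input(self, smooth_baseline):
        wl, base = smooth_baseline
        out = nv.smooth_spline(wl, base)
        assert np.max(np.abs(out - base)) < 1e-3

    def test_gap_filling(self, smooth_baseline):
        wl, base = smooth_baseline
        gappy = base.copy()
        gappy[25:30] = np.nan
        out = nv.smooth_spline(wl, gappy)
        assert np.all(np.isfinite(out))
        assert np.max(np.abs(out[25:30] - base[25:30])) < 0.01

    def test_noise_reduction(self, smooth_baseline):
        wl, base = smooth_baseline
        rng = np.random.default_rng(1)
        noisy = base + rng.normal(0, 0.01, base.size)
        out = nv.smooth_spline(wl, noisy)
        rms_before = np.sqrt(np.mean((noisy - base) ** 2))
        rms_after = np.sqrt(np.mean((out - base) ** 2))
        assert rms_after < rms_before

    def test_too_few_valid(self):
        wl = np.arange(10.0)
        x = np.full(10, np.nan)
        x[:3] = 0.2
        with pytest.raises(ValidationError):
            nv.smooth_spline(wl, x)


class TestResampleToSensor:
    def test_flat_spectrum_preserved(self):
        spec = fm.CanopySpectrum(fm.WAVELENGTHS,
                                 np.full_like(fm.WAVELENGTHS, 0.3))
        sensor = nv.SensorSpec(np.array([500.0, 1500.0, 2400.0]),
                               np.array([10.0, 10.0, 10.0]))
        out = nv.resample_to_sensor(spec, sensor)
        np.testing.assert_allclose(out, 0.3, rtol=1e-12)

    def test_linear_spectrum_exact_at_centers(self):
        refl = 0.1 + 1e-4 * (fm.WAVELENGTHS - 400.0)
        spec = fm.CanopySpectrum(fm.WAVELENGTHS, refl)
        centers = np.array([800.0, 1600.0, 2200.0])
        sensor = nv.SensorSpec(centers, np.full(3, 12.0))
        out = nv.resample_to_sensor(spec, sensor)
        np.testing.assert_allclose(out, 0.1 + 1e-4 * (centers - 400.0),
                                   atol=1e-6)

    def test_tiny_fwhm_picks_nearest(self):
        rng = np.random.default_rng(2)
        refl = rng.random(fm.WAVELENGTHS.size)
        spec = fm.CanopySpectrum(fm.WAVELENGTHS, refl)
        sensor = nv.SensorSpec(np.array([1000.2]), np.array([1e-4]))
        out = nv.resample_to_sensor(spec, sensor)
        assert out[0] == refl[600]  # 1000 nm is the nearest 1 nm sample

    def test_center_outside_grid(self):
        spec = fm.CanopySpectrum(fm.WAVELENGTHS,
                                 np.full_like(fm.WAVELENGTHS, 0.3))
        sensor = nv.SensorSpec(np.array([300.0, 600.0]), np.array([10.0, 10.0]))
        with pytest.raises(ValidationError, match="300"):
            nv.resample_to_sensor(spec, sensor)


class TestClassifyScene:
    def test_self_match_and_report(self, small_scene, basis):
        cube, truth = small_scene
        spectra, codes = nv.scene_training_samples(cube, truth, per_class=15,
                                                   seed=0)
        classmap, report = nv.classify_scene(cube, spectra, codes, basis,
                                             seed=0)
        assert report["overall_accuracy"] >= 0.9
        assert (classmap.labels == truth.labels).mean() >= 0.9

    def test_training_pixel_gets_own_label(self, small_scene, basis):
        cube, truth = small_scene
        spectra, codes = nv.scene_training_samples(cube, truth, per_class=10,
                                                   seed=1)
        feats = nv.features_from_full_grid(basis, cube.wavelengths, spectra)
        from scipy.spatial.distance import cdist
        self_idx = np.argmin(cdist(feats, feats) + np.eye(len(feats)) * 1e9,
                             axis=1)
        # 1-NN applied to a training pixel itself returns its own label
        d = cdist(feats, feats)
        assert np.all(codes[np.argmin(d, axis=1)] == codes)

    def test_tie_breaks_to_lowest_index(self, basis, small_scene):
        cube, truth = small_scene
        spectra, codes = nv.scene_training_samples(cube, truth, per_class=3,
                                                   seed=2)
        # duplicate one spectrum under two labels; queries equal to it must
        # resolve to the first occurrence
        dup = np.vstack([spectra, spectra[:1]])
        dup_codes = np.concatenate([codes, [(codes[0] + 1) % 5]])
        from scipy.spatial.distance import cdist
        feats = nv.features_from_full_grid(basis, cube.wavelengths, dup)
        d = cdist(feats[:1], feats)
        assert int(np.argmin(d)) == 0

    def test_thin_class_rejected(self, small_scene, basis):
        cube, truth = small_scene
        spectra, codes = nv.scene_training_samples(cube, truth, per_class=5,
                                                   seed=0)
        codes = codes.copy()
        codes[codes == 4] = 3
        codes[-1] = 4  # a single sample of class 4
        with pytest.raises(ValidationError, match="3 samples"):
            nv.classify_scene(cube, spectra, codes, basis)


@pytest.fixture(scope="module")
def mapping(small_scene, small_db, basis):
    cube, truth = small_scene
    nv_spectra = nv.extract_nonvegetated(cube, truth, 24, seed=0)
    ts = nv.add_nonvegetated(small_db, nv_spectra)
    feats = nv.features_from_full_grid(basis, ts.wavelengths, ts.spectra)
    model = nv.train_gpr(feats, ts.labels, seed=0)
    return cube, truth, model


class TestMapNpv:
    def test_all_water_is_nodata(self, small_scene, small_db, basis, mapping):
        cube, truth, model = mapping
        water = nv.ClassMap(np.full_like(truth.labels, 1), truth.legend)
        out = nv.map_npv(cube, water, model, basis)
        assert not out.valid_mask().any()

    def test_crop_above_soil_and_sd_ordering(self, mapping, basis):
        cube, truth, model = mapping
        out = nv.map_npv(cube, truth, model, basis)
        valid = out.valid_mask()
        crop = (truth.labels == 3) & valid
        soil = (truth.labels == 4) & valid
        assert out.estimate[crop].mean() > out.estimate[soil].mean()
        assert out.sd[soil].mean() >= out.sd[crop].mean()
        assert np.all(out.sd[valid] >= 0)

    def test_mask_conservation(self, mapping, basis):
        cube, truth, model = mapping
        out = nv.map_npv(cube, truth, model, basis)
        n_mask = np.isin(truth.labels, [3, 4]).sum()
        assert out.valid_mask().sum() <= n_mask

    def test_absent_classes_warn(self, mapping, basis):
        cube, truth, model = mapping
        water_only = nv.ClassMap(np.full_like(truth.labels, 1), truth.legend)
        with pytest.warns(UserWarning, match="mask classes"):
            out = nv.map_npv(cube, water_only, model, basis)
        assert not out.valid_mask().any()


class TestEnviIO:
    def test_cube_roundtrip(self, tmp_path, small_scene):
        cube, _ = small_scene
        stem = tmp_path / "scene"
        nv.write_envi(cube, stem)
        back = nv.read_envi(stem)
        np.testing.assert_allclose(back.data, cube.data, atol=1e-6)
        np.testing.assert_allclose(back.wavelengths, cube.wavelengths)
        assert back.nodata == cube.nodata

    def test_classmap_roundtrip(self, tmp_path, small_scene):
        from npvret.scene_pipeline import read_classmap, write_classmap
        _, truth = small_scene
        write_classmap(truth, tmp_path / "cls")
        back = read_classmap(tmp_path / "cls")
        np.testing.assert_array_equal(back.labels, truth.labels)
        assert back.legend == truth.legend

    def test_npv_map_roundtrip(self, tmp_path):
        est = np.array([[10.0, nv.scene_pipeline.NODATA], [30.0, 40.0]]) \
            if hasattr(nv, "scene_pipeline") else None
        from npvret.scene_pipeline import NODATA, NPVMap, write_npv_map
        est = np.array([[10.0, NODATA], [30.0, 40.0]])
        sd = np.array([[1.0, NODATA], [2.0, 3.0]])
        cv = np.array([[0.1, NODATA], [0.066, 0.075]])
        npv = NPVMap(est, sd, cv, ("bare soils",))
        write_npv_map(npv, tmp_path / "npv", provenance={"note": "test"})
        back = nv.read_envi(tmp_path / "npv")
        np.testing.assert_allclose(back.data[:, :, 0], est, atol=1e-4)
        import json
        meta = json.loads((tmp_path / "npv.json").read_text())
        assert meta["layers"][0] == "estimate_g_m2"
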