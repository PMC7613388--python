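import numpy as np
import pytest

import npvret as nv
from npvret import forward_model as fm
from npvret.exceptions import DimensionError, ValidationError

from _oracle import canopy_brf, leaf_rt, leaf_rt_adding, load_tables
from conftest import random_canopy, random_leaf

WL = fm.WAVELENGTHS


def idx(wavelength_nm):
    return int(wavelength_nm - WL[0])


class TestParamValidation:
    def test_out_of_bound_names_field(self):
        with pytest.raises(ValidationError, match="CBC"):
            nv.LeafParams(CBC=0.01)
        with pytest.raises(ValidationError, match="ALIA"):
            nv.CanopyParams(ALIA=80.0)

    def test_zenith_range(self):
        with pytest.raises(ValidationError):
            nv.ViewGeometry(sza=90.0)
        nv.ViewGeometry(sza=0.0, vza=89.9)

    @pytest.mark.parametrize("field,value", [("N", 0.5), ("Cw", -0.001),
                                             ("Cab", 25.0)])
    def test_leaf_bounds(self, field, value):
        with pytest.raises(ValidationError, match=field):
            nv.LeafParams(**{field: value})


class TestProspectPro:
    def test_energy_conservation_midrange(self):
        lo = nv.prospect_pro(nv.LeafParams())
        assert np.all(lo.reflectance >= 0) and np.all(lo.reflectance <= 1)
        assert np.all(lo.transmittance >= 0) and np.all(lo.transmittance <= 1)
        assert np.all(lo.reflectance + lo.transmittance <= 1.0)

    def test_cbc_darkens_2100(self):
        low = nv.prospect_pro(nv.LeafParams(CBC=0.001)).reflectance[idx(2100)]
        high = nv.prospect_pro(nv.LeafParams(CBC=0.007)).reflectance[idx(2100)]
        assert high < low

    def test_matches_scalar_oracle(self):
        rows, _ = load_tables()
        rng = np.random.default_rng(42)
        for _ in range(20):
            leaf = random_leaf(rng)
            lo = nv.prospect_pro(leaf)
            leaf_d = {k: getattr(leaf, k) for k in nv.LeafParams.BOUNDS}
            for wl_nm in (450, 680, 900, 1300, 1700, 2100, 2400):
                r, t = leaf_rt(rows[idx(wl_nm)], leaf_d)
                assert lo.reflectance[idx(wl_nm)] == pytest.approx(r, abs=1e-9)
                assert lo.transmittance[idx(wl_nm)] == pytest.approx(t, abs=1e-9)

    def test_integer_stack_matches_adding_method(self):
        # the closed-form continuous stack must agree with sequentially
        # added discrete layers when N is an integer
        rows, _ = load_tables()
        leaf = nv.LeafParams(N=2.0)
        leaf_d = {k: getattr(leaf, k) for k in nv.LeafParams.BOUNDS}
        lo = nv.prospect_pro(leaf)
        for wl_nm in (500, 1100, 1650, 2200):
            r_add, t_add = leaf_rt_adding(rows[idx(wl_nm)], leaf_d)
            assert lo.reflectance[idx(wl_nm)] == pytest.approx(r_add, abs=1e-9)
            assert lo.transmittance[idx(wl_nm)] == pytest.approx(t_add, abs=1e-9)


class TestMixSoil:
    def test_endpoints(self):
        dry = nv.mix_soil(1.0).reflectance
        wet = nv.mix_soil(0.0).reflectance
        half = nv.mix_soil(0.5).reflectance
        assert np.all(dry > wet)
        np.testing.assert_allclose(half, 0.5 * (dry + wet), rtol=0, atol=0)

    @pytest.mark.parametrize("psoil", [-0.1, 1.1, np.nan])
    def test_validation(self, psoil):
        with pytest.raises(ValidationError):
            nv.mix_soil(psoil)


class TestFoursail:
    def test_bare_soil_limit(self):
        soil = nv.mix_soil(0.7)
        lo = nv.prospect_pro(nv.LeafParams())
        out = nv.foursail(lo, nv.CanopyParams(LAI=0.0, psoil=0.7), soil=soil)
        assert np.max(np.abs(out.reflectance - soil.reflectance)) < 1e-9

    def test_psoil_mixing_endpoints(self):
        lo = nv.prospect_pro(nv.LeafParams())
        for psoil, pure in ((0.0, nv.mix_soil(0.0)), (1.0, nv.mix_soil(1.0))):
            canopy = nv.CanopyParams(psoil=psoil)
            via_param = nv.foursail(lo, canopy)
            via_soil = nv.foursail(lo, canopy, soil=pure)
            np.testing.assert_array_equal(via_param.reflectance,
                                          via_soil.reflectance)

    def test_grid_mismatch(self):
        lo = nv.prospect_pro(nv.LeafParams())
        bad = nv.CanopySpectrum(WL[:-5], nv.mix_soil(0.5).reflectance[:-5])
        with pytest.raises(DimensionError):
            nv.foursail(lo, nv.CanopyParams(), soil=bad)

    def test_matches_scalar_oracle(self):
        rows, soil_rows = load_tables()
        rng = np.random.default_rng(7)
        for _ in range(20):
            leaf = random_leaf(rng)
            canopy = random_canopy(rng)
            geom = nv.ViewGeometry(rng.uniform(20, 60), rng.uniform(0, 20),
                                   rng.uniform(0, 180))
            out = nv.simulate_canopy(leaf, canopy, geom)
            leaf_d = {k: getattr(leaf, k) for k in nv.LeafParams.BOUNDS}
            canopy_d = {k: getattr(canopy, k) for k in nv.CanopyParams.BOUNDS}
            geom_d = {"sza": geom.sza, "vza": geom.vza, "raa": geom.raa}
            for wl_nm in (550, 1000, 1550, 1750, 2100, 2350):
                ref = canopy_brf(rows[idx(wl_nm)], soil_rows[idx(wl_nm)],
                                 leaf_d, canopy_d, geom_d)
                assert out.reflectance[idx(wl_nm)] == pytest.approx(
                    ref, abs=1e-6)


class TestSimulateCanopy:
    def test_deterministic(self):
        a = nv.simulate_canopy(nv.LeafParams(), nv.CanopyParams())
        b = nv.simulate_canopy(nv.LeafParams(), nv.CanopyParams())
        np.testing.assert_array_equal(a.reflectance, b.reflectance)

    def test_pigments_do_not_touch_swir(self):
        base = dict(Cw=0.01, CBC=0.004)
        lo_pig = nv.simulate_canopy(
            nv.LeafParams(Cab=0, Cxc=0, Cant=0, **base), nv.CanopyParams())
        hi_pig = nv.simulate_canopy(
            nv.LeafParams(Cab=20, Cxc=15, Cant=2, **base), nv.CanopyParams())
        swir = WL >= 1500
        assert np.max(np.abs(lo_pig.reflectance[swir]
                             - hi_pig.reflectance[swir])) < 1e-9

    def test_cbc_sweep_monotone_at_2100(self):
        values = [nv.simulate_canopy(nv.LeafParams(CBC=c),
                                     nv.CanopyParams(LAI=2.0)
                                     ).reflectance[idx(2100)]
                  for c in np.linspace(0.0, 0.007, 9)]
        assert np.all(np.diff(values) < 0)

    def test_energy_conservation_many_draws(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            leaf = random_leaf(rng)
            canopy = random_canopy(rng)
            r = nv.foursail(nv.prospect_pro(leaf), canopy).reflectance
            assert np.all(np.isfinite(r))
            assert r.min() >= 0.0 and r.max() <= 1.0


class TestSensitivityOat:
    def test_single_step_equals_base(self):
        base_leaf, base_canopy = nv.LeafParams(), nv.CanopyParams()
        out = nv.sensitivity_oat(base_leaf, base_canopy, "CBC", 1)
        assert len(out) == 1
        np.testing.assert_array_equal(
            out[0].reflectance,
            nv.simulate_canopy(base_leaf, base_canopy).reflectance)

    def test_unknown_parameter(self):
        with pytest.raises(ValidationError):
            nv.sensitivity_oat(nv.LeafParams(), nv.CanopyParams(), "bogus", 3)

    def test_cbc_absorption_windows(self):
        # the swept-CBC spread must be deepest inside the lignocellulose
        # windows, compared against a quiet reference wavelength
        out = nv.sensitivity_oat(nv.LeafParams(), nv.CanopyParams(), "CBC", 6)
        stack = np.array([s.reflectance for s in out])
        spread = stack.max(axis=0) - stack.min(axis=0)

        def mean_spread(lo_nm, hi_nm):
            return spread[idx(lo_nm):idx(hi_nm)].mean()

        quiet = spread[idx(1515)]
        assert mean_spread(1600, 1800) > quiet
        assert mean_spread(2100, 2300) > quiet

    def test_hotspot_effect_bounded_by_lai(self):
        hot = nv.sensitivity_oat(nv.LeafParams(), nv.CanopyParams(),
                                 "hotspot", 5)
        lai = nv.sensitivity_oat(nv.LeafParams(), nv.CanopyParams(), "LAI", 5)
        swir = WL >= 1500

        def swir_range(spectra):
            stack = np.array([s.reflectance[swir] for s in spectra])
            return float((stack.max(axis=0) - stack.min(axis=0)).max())

        assert swir_range(hot) <= swir_range(lai)
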