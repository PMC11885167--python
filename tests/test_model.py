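"""PT-JPL model: closed-form oracles for each primitive, conservation and
monotonicity invariants, and equivalence of the gridded engine with a
plain scalar re-implementation."""

import math

import numpy as np
import pytest
import xarray as xr

from ptjpl import (
    DriverSpec,
    ForcingConfig,
    PTJPLParams,
    compute_constraints,
    compute_et,
    et_from_factors,
    fipar_from_ndvi,
    generate_grid_forcing,
    lai_from_fipar,
    partition_net_radiation,
    prepare_forcing,
    saturation_slope,
    saturation_vapor_pressure,
    vpd_from_tm_rh,
)

P = PTJPLParams()


def esat_oracle(tm):
    """Independent Tetens evaluation (math module, no numpy)."""
    return 0.6108 * math.exp(17.27 * tm / (tm + 237.3))


class TestSaturationSlope:
    def test_value_at_20C(self):
        assert saturation_slope(20.0) == pytest.approx(0.1448, abs=2e-4)

    def test_strictly_increasing_over_plant_range(self):
        tms = np.linspace(-10, 45, 200)
        d = saturation_slope(tms)
        assert (np.diff(d) > 0).all()
        assert (d > 0).all()

    def test_matches_finite_difference_of_esat(self):
        for tm in np.linspace(-20, 50, 30):
            h = 1e-3
            fd = (esat_oracle(tm + h) - esat_oracle(tm - h)) / (2 * h)
            assert saturation_slope(tm) == pytest.approx(fd, abs=1e-4)

    def test_out_of_physical_range_raises(self):
        with pytest.raises(ValueError, match="tm"):
            saturation_slope(-80.0)


class TestVPD:
    @pytest.mark.parametrize(
        "tm, rh, expected",
        [
            (20.0, 100.0, 0.0),                       # saturation
            (20.0, 50.0, 1.169),                      # half-saturated air
            (20.0, 0.0, 2.339),                       # fully dry: VPD = e_sat
        ],
    )
    def test_values(self, tm, rh, expected):
        assert vpd_from_tm_rh(tm, rh) == pytest.approx(expected, abs=1e-3)

    def test_rh_out_of_range_raises(self):
        with pytest.raises(ValueError, match="rh"):
            vpd_from_tm_rh(20.0, 105.0)


class TestVegetationStructure:
    def test_fipar_examples(self):
        assert fipar_from_ndvi(0.05) == pytest.approx(0.0, abs=1e-12)
        assert fipar_from_ndvi(0.55) == pytest.approx(0.50, abs=1e-12)
        assert fipar_from_ndvi(0.02) == 0.0  # raw -0.03, clamped

    def test_fipar_out_of_range_raises(self):
        with pytest.raises(ValueError, match="ndvi"):
            fipar_from_ndvi(1.5)

    def test_lai_examples_and_round_trip(self):
        assert lai_from_fipar(0.0) == 0.0
        assert lai_from_fipar(0.5) == pytest.approx(1.3863, abs=1e-4)
        assert lai_from_fipar(fipar_from_ndvi(0.55)) == pytest.approx(
            -math.log(0.5) / 0.5, rel=1e-12
        )

    def test_lai_at_singularity_raises(self):
        with pytest.raises(ValueError, match="f_ipar"):
            lai_from_fipar(1.0)


class TestRadiationPartition:
    def test_bare_ground(self):
        r_ns, r_nc = partition_net_radiation(10.0, 0.0)
        assert r_ns == 10.0 and r_nc == 0.0

    def test_beer_lambert_value(self):
        r_ns, r_nc = partition_net_radiation(10.0, 1.0)
        assert r_ns == pytest.approx(10.0 * math.exp(-0.6), rel=1e-12)
        assert r_nc == pytest.approx(10.0 - 10.0 * math.exp(-0.6), rel=1e-12)

    def test_closed_canopy_limit(self):
        r_ns, _ = partition_net_radiation(10.0, 50.0)
        assert r_ns == pytest.approx(0.0, abs=1e-12)

    def test_conservation_on_random_inputs(self, rng):
        rn = rng.uniform(-5, 30, 1000)
        lai = rng.uniform(0, 8, 1000)
        r_ns, r_nc = partition_net_radiation(rn, lai)
        np.testing.assert_allclose(r_ns + r_nc, rn, rtol=0, atol=1e-12)


class TestConstraints:
    def test_fwet_at_saturation_and_basin_mean_humidity(self, tiny_cube):
        prepared = prepare_forcing(tiny_cube)
        cs = compute_constraints(prepared)
        # direct check of the wetness law against the cube's own humidity
        np.testing.assert_allclose(
            cs["f_wet"].values, (prepared["Rh"].values / 100.0) ** 4, rtol=1e-12
        )
        assert float(((100.0 / 100.0) ** 4)) == 1.0
        assert (59.26 / 100.0) ** 4 == pytest.approx(0.1233, abs=1e-4)

    def test_all_factors_within_unit_interval(self, tiny_cube):
        cs = compute_constraints(tiny_cube)
        for name in ("f_wet", "f_g", "f_T", "f_M", "f_SM"):
            vals = cs[name].values
            assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0, name

    def test_fg_is_one_when_fapar_equals_fipar(self, tiny_cube):
        # default parameters use the same linear NDVI pathway for both
        cs = compute_constraints(tiny_cube)
        prepared = prepare_forcing(tiny_cube)
        veg = prepared["fIPAR"].values > 0
        assert np.allclose(cs["f_g"].values[veg], 1.0)

    def test_fsm_decreasing_in_vpd_at_fixed_rh(self):
        rh = 60.0
        vpds = np.array([0.2, 0.5, 1.0, 2.0])
        fsm = (rh / 100.0) ** (vpds / P.beta_sm)
        assert (np.diff(fsm) < 0).all()

    def test_missing_field_error_names_it(self, tiny_cube):
        broken = tiny_cube.drop_vars("Rn")
        with pytest.raises(ValueError, match="Rn"):
            compute_constraints(broken)


def scalar_ptjpl(tm, rn, lai, f_wet, f_g, f_t, f_m, f_sm, g=0.0):
    """Straightforward scalar re-implementation of the component model."""
    es = 0.6108 * math.exp(17.27 * tm / (tm + 237.3))
    delta = 4098.0 * es / (tm + 237.3) ** 2
    pt = 1.26 * delta / (delta + 0.066)
    r_ns = rn * math.exp(-0.6 * lai)
    r_nc = rn - r_ns
    et_c = max((1 - f_wet) * f_g * f_t * f_m * pt * r_nc / 2.45, 0.0)
    et_s = max((f_wet + f_sm * (1 - f_wet)) * pt * (r_ns - g) / 2.45, 0.0)
    et_i = max(f_wet * pt * r_nc / 2.45, 0.0)
    return et_c, et_s, et_i


class TestComponentFluxes:
    def test_hand_worked_example(self):
        # tm=20, rn=10, lai=1, factors (0,1,1,1,0.5):
        # alpha*delta/(delta+gamma) = 1.26*0.14474/0.21074 = 0.86537
        r_ns, r_nc = partition_net_radiation(10.0, 1.0)
        et_c, et_s, et_i, _ = et_from_factors(
            20.0, r_nc, r_ns, 0.0, 1.0, 1.0, 1.0, 0.5
        )
        assert et_c == pytest.approx(1.594, abs=2e-3)
        assert et_s == pytest.approx(0.969, abs=2e-3)
        assert et_i == 0.0

    def test_fully_wet_surface_kills_transpiration(self):
        r_ns, r_nc = partition_net_radiation(8.0, 2.0)
        et_c, et_s, et_i, _ = et_from_factors(
            15.0, r_nc, r_ns, 1.0, 1.0, 1.0, 1.0, 0.3
        )
        delta = saturation_slope(15.0)
        pt = P.alpha * delta / (delta + P.gamma)
        assert et_c == 0.0
        # at f_wet = 1 the soil multiplier f_wet + f_SM(1-f_wet) is also 1
        assert et_s == pytest.approx(pt * r_ns / P.lam, rel=1e-12)
        assert et_i == pytest.approx(pt * r_nc / P.lam, rel=1e-12)

    def test_bare_ground_has_soil_evaporation_only(self):
        r_ns, r_nc = partition_net_radiation(10.0, 0.0)
        et_c, et_s, et_i, _ = et_from_factors(
            20.0, r_nc, r_ns, 0.2, 1.0, 1.0, 1.0, 0.5
        )
        assert et_c == 0.0 and et_i == 0.0 and et_s > 0.0

    def test_negative_radiation_clamps_all_components_to_zero(self):
        r_ns, r_nc = partition_net_radiation(-3.0, 1.0)
        et_c, et_s, et_i, n_clamped = et_from_factors(
            5.0, r_nc, r_ns, 0.2, 1.0, 1.0, 1.0, 0.5
        )
        assert et_c == 0.0 and et_s == 0.0 and et_i == 0.0
        assert n_clamped == 3

    def test_monotone_in_canopy_factors(self):
        r_ns, r_nc = partition_net_radiation(10.0, 1.5)
        base, *_ = et_from_factors(20.0, r_nc, r_ns, 0.1, 0.5, 0.5, 0.5, 0.5)
        for bumped in (
            et_from_factors(20.0, r_nc, r_ns, 0.1, 0.8, 0.5, 0.5, 0.5),
            et_from_factors(20.0, r_nc, r_ns, 0.1, 0.5, 0.8, 0.5, 0.5),
            et_from_factors(20.0, r_nc, r_ns, 0.1, 0.5, 0.5, 0.8, 0.5),
        ):
            assert bumped[0] >= base

    def test_engine_matches_scalar_reimplementation(self, rng):
        for _ in range(100):
            tm = rng.uniform(-10, 40)
            rn = rng.uniform(-2, 25)
            lai = rng.uniform(0, 6)
            fw, fg, ft, fm, fsm = rng.uniform(0, 1, 5)
            r_ns, r_nc = partition_net_radiation(rn, lai)
            got = et_from_factors(tm, r_nc, r_ns, fw, fg, ft, fm, fsm)[:3]
            want = scalar_ptjpl(tm, rn, lai, fw, fg, ft, fm, fsm)
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-14)

    def test_printed_soil_radiation_variant_uses_canopy_energy(self):
        params = PTJPLParams(printed_soil_radiation=True)
        r_ns, r_nc = partition_net_radiation(10.0, 1.0)
        _, et_s, _, _ = et_from_factors(
            20.0, r_nc, r_ns, 0.0, 1.0, 1.0, 1.0, 1.0, params=params
        )
        delta = saturation_slope(20.0)
        pt = params.alpha * delta / (delta + params.gamma)
        assert et_s == pytest.approx(pt * r_nc / params.lam, rel=1e-12)


class TestGriddedModel:
    def test_additivity_and_conservation_exact(self, tiny_cube):
        prepared = prepare_forcing(tiny_cube)
        et = compute_et(prepared)
        np.testing.assert_array_equal(
            et["ET"].values,
            et["ET_c"].values + et["ET_s"].values + et["ET_i"].values,
        )
        np.testing.assert_allclose(
            et["R_nc"].values + et["R_ns"].values,
            prepared["Rn"].values, rtol=0, atol=1e-12,
        )

    def test_all_fluxes_non_negative(self, tiny_cube):
        et = compute_et(tiny_cube)
        for name in ("ET", "ET_c", "ET_s", "ET_i"):
            assert float(et[name].min()) >= 0.0

    def test_zero_lai_kills_canopy_terms(self):
        drivers = {
            "Rn": DriverSpec(mean=8.0), "Tm": DriverSpec(mean=15.0),
            "Rh": DriverSpec(mean=50.0), "Ws": DriverSpec(mean=2.0),
            "Pre": DriverSpec(mean=1.0), "NDVI": DriverSpec(mean=0.0),
        }
        cfg = ForcingConfig(rows=2, cols=2, start_year=2001, end_year=2002,
                            drivers=drivers, spatial_gradient=0.0, seed=0)
        et = compute_et(generate_grid_forcing(cfg))
        assert float(abs(et["ET_c"]).max()) == 0.0
        assert float(abs(et["ET_i"]).max()) == 0.0
        np.testing.assert_array_equal(et["ET"].values, et["ET_s"].values)

    def test_deterministic_given_forcing(self, tiny_cube):
        a = compute_et(tiny_cube)
        b = compute_et(tiny_cube)
        np.testing.assert_array_equal(a["ET"].values, b["ET"].values)
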