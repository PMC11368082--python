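"""Indicator formulas against hand-computed values and scalar oracles."""

import math

import numpy as np
import pytest

from rseli.indicators import (
    EmissivityModel,
    TasseledCapCoefficients,
    bare_soil_index,
    blackbody_radiance,
    built_up_index,
    emissivity,
    fvc,
    lst,
    ndbsi,
    ndvi,
    slope_from_dem,
    wetness,
)
from rseli.raster import GridTransform, RasterGrid
from rseli.scene import AtmosphericParams, MissingBandError, PlanckConstants


class TestNdvi:
    @pytest.mark.parametrize(
        "nir, red, expected",
        [(0.5, 0.5, 0.0), (0.6, 0.2, 0.5), (0.1, 0.3, -0.5)],
    )
    def test_values(self, make_scene, nir, red, expected):
        out = ndvi(make_scene(nir=nir, red=red))
        assert out.values[0, 0] == pytest.approx(expected, abs=1e-15)

    def test_zero_denominator_is_nodata(self, make_scene):
        out = ndvi(make_scene(nir=0.0, red=0.0))
        assert out.nodata_mask.all()

    def test_missing_band(self, make_scene):
        with pytest.raises(MissingBandError, match="red"):
            ndvi(make_scene(nir=0.5))


class TestWetness:
    def test_zero_reflectance_gives_zero(self, make_scene):
        scene = make_scene(blue=0, green=0, red=0, nir=0, swir1=0, swir2=0)
        assert (wetness(scene).values == 0).all()

    def test_unit_swir1_returns_printed_coefficient(self, make_scene):
        scene = make_scene(blue=0, green=0, red=0, nir=0, swir1=1.0, swir2=0)
        assert wetness(scene).values[0, 0] == -0.6806

    def test_sum_of_positive_coefficients(self, make_scene):
        scene = make_scene(blue=1, green=1, red=1, nir=1, swir1=0, swir2=0)
        assert wetness(scene).values[0, 0] == pytest.approx(0.7032, abs=1e-12)

    def test_custom_coefficients(self, make_scene):
        scene = make_scene(blue=1, green=0, red=0, nir=0, swir1=0, swir2=0)
        coeffs = TasseledCapCoefficients(blue=0.1)
        assert wetness(scene, coeffs).values[0, 0] == pytest.approx(0.1)


class TestBareSoilIndex:
    def test_equal_bands_give_zero(self, make_scene):
        scene = make_scene(swir1=0.3, red=0.3, nir=0.3, blue=0.3)
        assert bare_soil_index(scene).values[0, 0] == pytest.approx(0.0)

    def test_direct_evaluation(self, make_scene):
        scene = make_scene(swir1=0.4, red=0.4, nir=0.2, blue=0.2)
        assert bare_soil_index(scene).values[0, 0] == pytest.approx(1 / 3)

    def test_all_zero_is_nodata(self, make_scene):
        scene = make_scene(swir1=0.0, red=0.0, nir=0.0, blue=0.0)
        assert bare_soil_index(scene).nodata_mask.all()


class TestBuiltUpIndex:
    def test_equal_bands_give_zero(self, make_scene):
        scene = make_scene(swir1=0.3, nir=0.3, red=0.3, green=0.3)
        assert built_up_index(scene).values[0, 0] == pytest.approx(0.0, abs=1e-15)

    def test_matches_scalar_oracle(self, make_scene):
        s1, n, r, g = 0.6, 0.2, 0.2, 0.1
        a, b, c = 2 * s1 / (s1 + n), n / (n + r), g / (g + s1)
        expected = (a - b - c) / (a + b + c)
        scene = make_scene(swir1=s1, nir=n, red=r, green=g)
        assert built_up_index(scene).values[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_degenerate_subratio_is_nodata(self, make_scene):
        scene = make_scene(swir1=0.3, nir=0.0, red=0.0, green=0.2)
        assert built_up_index(scene).nodata_mask.all()


class TestNdbsi:
    def test_arithmetic_mean(self, make_grid):
        out = ndbsi(make_grid(0.2), make_grid(0.4))
        assert out.values[0, 0] == pytest.approx(0.3)

    def test_identity_when_equal(self, make_grid):
        out = ndbsi(make_grid(0.37), make_grid(0.37))
        assert out.values[0, 0] == pytest.approx(0.37)

    def test_nodata_propagates(self, make_grid):
        ibi = make_grid([[np.nan, 0.2], [0.2, 0.2]])
        out = ndbsi(ibi, make_grid(0.4, shape=(2, 2)))
        assert out.nodata_mask[0, 0] and not out.nodata_mask[0, 1]


class TestFvcAndEmissivity:
    @pytest.mark.parametrize(
        "v, expected", [(0.04, 0.0), (0.8, 1.0), (0.375, 0.5), (0.05, 0.0), (0.7, 1.0)]
    )
    def test_fvc_piecewise(self, make_grid, v, expected):
        assert fvc(make_grid(v)).values[0, 0] == pytest.approx(expected, abs=1e-15)

    def test_water_emissivity_constant(self, make_grid):
        nd = make_grid(-0.1)
        assert emissivity(nd, fvc(nd)).values[0, 0] == 0.995

    def test_natural_polynomial_at_full_cover(self, make_grid):
        nd = make_grid(0.9)
        expected = 0.9625 + 0.0614 - 0.0461
        assert emissivity(nd, fvc(nd)).values[0, 0] == pytest.approx(expected, abs=1e-15)

    def test_building_polynomial_at_half_cover(self, make_grid):
        nd = make_grid(0.375)  # FVC 0.5
        expected = 0.9589 + 0.086 * 0.5 - 0.0671 * 0.25
        assert emissivity(nd, fvc(nd)).values[0, 0] == pytest.approx(expected, abs=1e-15)

    def test_breakpoint_0_7_belongs_to_natural_branch(self, make_grid):
        nd = make_grid(0.7)  # FVC 1
        expected = 0.9625 + 0.0614 - 0.0461
        assert emissivity(nd, fvc(nd)).values[0, 0] == pytest.approx(expected, abs=1e-15)

    def test_emissivity_range(self, make_grid):
        rng = np.random.default_rng(1)
        nd = make_grid(rng.uniform(-1, 1, (10, 10)), shape=(10, 10))
        out = emissivity(nd, fvc(nd)).valid_values()
        assert (out > 0).all() and (out <= 1).all()


class TestThermalChain:
    def test_identity_limit(self, make_scene, make_grid):
        scene = make_scene(tir_radiance=9.3)
        out = blackbody_radiance(scene, make_grid(1.0))
        assert out.values[0, 0] == pytest.approx(9.3)

    def test_direct_evaluation(self, make_scene, make_grid):
        scene = make_scene(
            tir_radiance=9.0, atmos=AtmosphericParams(l_up=1.0, l_down=2.0, t=0.9)
        )
        out = blackbody_radiance(scene, make_grid(0.95))
        expected = (9.0 - 1.0 - 0.9 * 0.05 * 2.0) / (0.9 * 0.95)
        assert out.values[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_radiance_is_nodata(self, make_scene, make_grid):
        scene = make_scene(
            tir_radiance=0.5, atmos=AtmosphericParams(l_up=1.0, l_down=0.0, t=0.9)
        )
        assert blackbody_radiance(scene, make_grid(0.95)).nodata_mask.all()

    def test_planck_inversion_recovers_temperature(self, make_grid):
        k1, k2 = 774.8853, 1321.0789
        b = k1 / (math.exp(k2 / 300.0) - 1.0)
        out = lst(make_grid(b), PlanckConstants(k1=k1, k2=k2), output_celsius=False)
        assert out.values[0, 0] == pytest.approx(300.0, abs=1e-6)

    def test_lst_direct_evaluation(self, make_grid):
        pl = PlanckConstants(k1=774.89, k2=1321.08)
        out = lst(make_grid(10.0), pl, output_celsius=False)
        assert out.values[0, 0] == pytest.approx(1321.08 / math.log(774.89 / 10 + 1))

    def test_lst_monotone_in_radiance(self, make_grid):
        pl = PlanckConstants(k1=774.89, k2=1321.08)
        bs = np.linspace(1.0, 20.0, 16).reshape(4, 4)
        out = lst(make_grid(bs), pl, output_celsius=False).values.ravel()
        assert (np.diff(out) > 0).all()

    def test_celsius_offset(self, make_grid):
        pl = PlanckConstants(k1=774.89, k2=1321.08)
        k = lst(make_grid(10.0), pl, output_celsius=False).values[0, 0]
        c = lst(make_grid(10.0), pl, output_celsius=True).values[0, 0]
        assert k - c == pytest.approx(273.15)


class TestSlope:
    def test_flat_surface_is_zero(self, make_grid):
        out = slope_from_dem(make_grid(500.0, shape=(6, 6)))
        assert np.allclose(out.values, 0.0)

    def test_inclined_plane_45_degrees_interior(self, transform_1km):
        # plane rising 1 m per metre along x (1000 m per 1 km pixel)
        cols = np.arange(8) * 1000.0
        dem = RasterGrid(np.tile(cols, (8, 1)), transform_1km)
        out = slope_from_dem(dem)
        assert np.allclose(out.values[1:-1, 1:-1], 45.0)

    def test_rotational_symmetry(self, transform_1km):
        cols = np.arange(8) * 250.0
        along_x = RasterGrid(np.tile(cols, (8, 1)), transform_1km)
        along_y = RasterGrid(np.tile(cols, (8, 1)).T, transform_1km)
        sx = slope_from_dem(along_x).values
        sy = slope_from_dem(along_y).values
        np.testing.assert_allclose(sx, sy.T)

    def test_too_small_grid(self, make_grid):
        with pytest.raises(ValueError, match="3x3"):
            slope_from_dem(make_grid(0.0, shape=(2, 5)))


def test_indicators_match_scalar_reference(make_scene):
    """Each spectral indicator equals an independent per-pixel scalar
    re-evaluation of its formula on random reflectance cells."""
    rng = np.random.default_rng(42)
    shape = (10, 12)  # 120 cells
    refl = {
        b: rng.uniform(0.01, 0.9, shape)
        for b in ("blue", "green", "red", "nir", "swir1", "swir2")
    }
    scene = make_scene(shape=shape, **refl)
    nd = ndvi(scene).values
    wet = wetness(scene).values
    si = bare_soil_index(scene).values
    ibi = built_up_index(scene).values
    c = TasseledCapCoefficients()
    for i in range(shape[0]):
        for j in range(shape[1]):
            b, g, r = refl["blue"][i, j], refl["green"][i, j], refl["red"][i, j]
            n, s1, s2 = refl["nir"][i, j], refl["swir1"][i, j], refl["swir2"][i, j]
            assert nd[i, j] == pytest.approx((n - r) / (n + r), rel=1e-10)
            ref_wet = (
                b * c.blue + g * c.green + r * c.red
                + n * c.nir + s1 * c.swir1 + s2 * c.swir2
            )
            assert wet[i, j] == pytest.approx(ref_wet, rel=1e-10)
            assert si[i, j] == pytest.approx(
                ((s1 + r) - (n + b)) / ((s1 + r) + (n + b)), rel=1e-10
            )
            t1, t2, t3 = 2 * s1 / (s1 + n), n / (n + r), g / (g + s1)
            assert ibi[i, j] == pytest.approx(
                (t1 - t2 - t3) / (t1 + t2 + t3), rel=1e-10
            )
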