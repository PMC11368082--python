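"""The eight ecological indicators computed from a Scene.

Greenness is NDVI; wetness is the tasseled-cap wetness transform of the
six reflectance bands; dryness (NDBSI) averages the built-up index IBI and
the bare-soil index SI; heat is land surface temperature retrieved by
atmospherically correcting the thermal radiance for emissivity and
inverting the Planck function; elevation and slope come from the DEM; and
aerosol optical depth and population density are validated pass-through
layers.

Emissivity is modelled piecewise by cover type: water (NDVI <= 0) takes a
fixed 0.995, built/mixed surfaces (0 < NDVI < 0.7) and dense natural
vegetation (NDVI >= 0.7) take quadratic polynomials in fractional
vegetation cover.  The NDVI = 0.7 breakpoint is assigned to the natural
branch so the two ranges cannot overlap.

Note on the wetness coefficients: the default weights are the Landsat-TM
tasseled-cap set; the coefficient table is configurable for sensors whose
published transform differs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rseli.raster import RasterGrid, assert_aligned
from rseli.scene import REFLECTANCE_BANDS, PlanckConstants, Scene

__all__ = [
    "TasseledCapCoefficients",
    "EmissivityModel",
    "ndvi",
    "wetness",
    "bare_soil_index",
    "built_up_index",
    "ndbsi",
    "fvc",
    "emissivity",
    "blackbody_radiance",
    "lst",
    "slope_from_dem",
    "compute_indicators",
]

_KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class TasseledCapCoefficients:
    """Per-band weights of the tasseled-cap wetness transform."""

    blue: float = 0.0315
    green: float = 0.2021
    red: float = 0.3102
    nir: float = 0.1594
    swir1: float = -0.6806
    swir2: float = -0.6109

    def as_dict(self) -> dict[str, float]:
        return {b: getattr(self, b) for b in REFLECTANCE_BANDS}

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in self.as_dict().values()):
            raise ValueError("tasseled-cap coefficients must be finite")


@dataclass(frozen=True)
class EmissivityModel:
    """Piecewise emissivity model by cover type.

    Polynomials are (c0, c1, c2) applied as ``c0 + c1*FVC + c2*FVC**2``.
    """

    e_water: float = 0.995
    building_poly: tuple[float, float, float] = (0.9589, 0.086, -0.0671)
    natural_poly: tuple[float, float, float] = (0.9625, 0.0614, -0.0461)
    ndvi_water_max: float = 0.0
    ndvi_natural_min: float = 0.7
    fvc_soil_max: float = 0.05
    fvc_veg_min: float = 0.7


# ---------------------------------------------------------------------------
# Spectral indices
# ---------------------------------------------------------------------------


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """num/den with zero denominators yielding NaN instead of warnings."""
    out = np.full(num.shape, np.nan)
    ok = den != 0
    np.divide(num, den, out=out, where=ok & ~np.isnan(den))
    return out


def ndvi(scene: Scene) -> RasterGrid:
    """Normalized Difference Vegetation Index (NIR - red)/(NIR + red).

    Dimensionless, in [-1, 1] on valid cells; zero-denominator cells
    become nodata.
    """
    nir, red = scene.require("nir", "red")
    values = _safe_ratio(nir.values - red.values, nir.values + red.values)
    return nir.with_values(values, red.nodata_mask | np.isnan(values))


def wetness(
    scene: Scene, coeffs: TasseledCapCoefficients | None = None
) -> RasterGrid:
    """Tasseled-cap wetness: fixed linear combination of the six bands."""
    if coeffs is None:
        coeffs = TasseledCapCoefficients()
    grids = scene.require(*REFLECTANCE_BANDS)
    weights = coeffs.as_dict()
    total = np.zeros(grids[0].shape)
    mask = np.zeros(grids[0].shape, dtype=bool)
    for role, grid in zip(REFLECTANCE_BANDS, grids):
        total = total + weights[role] * grid.values
        mask |= grid.nodata_mask
    return grids[0].with_values(total, mask)


def bare_soil_index(scene: Scene) -> RasterGrid:
    """Bare Soil Index SI = ((SWIR1+red)-(NIR+blue)) / ((SWIR1+red)+(NIR+blue))."""
    swir1, red, nir, blue = scene.require("swir1", "red", "nir", "blue")
    plus = swir1.values + red.values
    minus = nir.values + blue.values
    values = _safe_ratio(plus - minus, plus + minus)
    mask = (
        swir1.nodata_mask
        | red.nodata_mask
        | nir.nodata_mask
        | blue.nodata_mask
        | np.isnan(values)
    )
    return swir1.with_values(values, mask)


def built_up_index(scene: Scene) -> RasterGrid:
    """Built-up Index IBI from SWIR1, NIR, red and green.

    IBI = (A - B - C) / (A + B + C) with A = 2·S1/(S1+N), B = N/(N+R),
    C = G/(G+S1).  Any zero sub-denominator or zero outer denominator
    makes the cell nodata.
    """
    s1, n, r, g = (x.values for x in scene.require("swir1", "nir", "red", "green"))
    a = _safe_ratio(2.0 * s1, s1 + n)
    b = _safe_ratio(n, n + r)
    c = _safe_ratio(g, g + s1)
    values = _safe_ratio(a - b - c, a + b + c)
    grids = scene.require("swir1", "nir", "red", "green")
    mask = np.zeros(values.shape, dtype=bool)
    for grid in grids:
        mask |= grid.nodata_mask
    return grids[0].with_values(values, mask | np.isnan(values))


def ndbsi(ibi: RasterGrid, si: RasterGrid) -> RasterGrid:
    """Dryness index: arithmetic mean of IBI and SI."""
    assert_aligned([ibi, si])
    return ibi.with_values((ibi.values + si.values) / 2.0, si.nodata_mask)


# ---------------------------------------------------------------------------
# Heat (LST) chain
# ---------------------------------------------------------------------------


def fvc(ndvi_grid: RasterGrid, model: EmissivityModel | None = None) -> RasterGrid:
    """Fractional vegetation cover from NDVI (dimidiate-pixel rescaling).

    0 below the bare-soil threshold (0.05), 1 above the full-vegetation
    threshold (0.7), linear in between.
    """
    if model is None:
        model = EmissivityModel()
    v = ndvi_grid.values
    lo, hi = model.fvc_soil_max, model.fvc_veg_min
    out = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    return ndvi_grid.with_values(out)


def emissivity(
    ndvi_grid: RasterGrid,
    fvc_grid: RasterGrid,
    model: EmissivityModel | None = None,
) -> RasterGrid:
    """Surface emissivity by cover type.

    Water (NDVI <= 0) is constant; built/mixed (0 < NDVI < 0.7) and natural
    (NDVI >= 0.7) are quadratics in FVC.  Output lies in (0, 1].
    """
    if model is None:
        model = EmissivityModel()
    assert_aligned([ndvi_grid, fvc_grid])
    v, f = ndvi_grid.values, fvc_grid.values

    def poly(coeffs: tuple[float, float, float]) -> np.ndarray:
        c0, c1, c2 = coeffs
        return c0 + c1 * f + c2 * f * f

    out = np.where(
        v <= model.ndvi_water_max,
        model.e_water,
        np.where(
            v >= model.ndvi_natural_min,
            poly(model.natural_poly),
            poly(model.building_poly),
        ),
    )
    return ndvi_grid.with_values(out, fvc_grid.nodata_mask)


def blackbody_radiance(scene: Scene, emissivity_grid: RasterGrid) -> RasterGrid:
    """Surface-leaving blackbody radiance B(Ts) from at-sensor radiance.

    B(Ts) = (L_sensor - L_up - t·(1-ε)·L_down) / (t·ε).  Cells where the
    corrected radiance is non-positive become nodata (the Planck inversion
    is undefined there).
    """
    if scene.atmos is None:
        raise ValueError("scene has no atmospheric parameters")
    tir = scene.band("tir_radiance")
    assert_aligned([tir, emissivity_grid])
    a = scene.atmos
    if a.t <= 0:
        raise ValueError("transmittance t must be positive")
    eps = emissivity_grid.values
    if np.any(eps[emissivity_grid.valid_mask] <= 0):
        raise ValueError("emissivity must be positive on valid cells")
    num = tir.values - a.l_up - a.t * (1.0 - eps) * a.l_down
    bts = num / (a.t * eps)
    nonpos = np.zeros(bts.shape, dtype=bool)
    np.less_equal(bts, 0.0, out=nonpos, where=~np.isnan(bts))
    bts = np.where(nonpos, np.nan, bts)
    return tir.with_values(bts, emissivity_grid.nodata_mask | nonpos)


def lst(
    bts: RasterGrid,
    planck: PlanckConstants,
    output_celsius: bool = True,
) -> RasterGrid:
    """Land surface temperature by Planck inversion.

    LST = K2 / ln(K1 / B(Ts) + 1), in °C by default (Kelvin available via
    ``output_celsius=False``).  Strictly increasing in B(Ts).
    """
    t_kelvin = planck.k2 / np.log(planck.k1 / bts.values + 1.0)
    if output_celsius:
        return bts.with_values(t_kelvin - _KELVIN_OFFSET)
    return bts.with_values(t_kelvin)


# ---------------------------------------------------------------------------
# Terrain
# ---------------------------------------------------------------------------


def slope_from_dem(dem: RasterGrid) -> RasterGrid:
    """Slope in degrees from a metric DEM.

    Interior cells use the Horn 3x3 weighted finite difference (the common
    GIS convention); edge cells fall back to one-sided/central differences.
    Cells adjacent to nodata inherit nodata, since the stencil is undefined
    there.
    """
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError(f"DEM must be at least 3x3, got {dem.shape}")
    z = dem.values
    dx = abs(dem.transform.pixel_width)
    dy = abs(dem.transform.pixel_height)

    # Horn stencil on the interior.
    dzdx = np.full(z.shape, np.nan)
    dzdy = np.full(z.shape, np.nan)
    dzdx[1:-1, 1:-1] = (
        (z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])
    ) / (8.0 * dx)
    dzdy[1:-1, 1:-1] = (
        (z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])
    ) / (8.0 * dy)

    # Edges: numpy-style one-sided/central differences.
    gy, gx = np.gradient(z, dy, dx)
    edge = np.zeros(z.shape, dtype=bool)
    edge[0, :] = edge[-1, :] = True
    edge[:, 0] = edge[:, -1] = True
    dzdx[edge] = gx[edge]
    dzdy[edge] = gy[edge]

    slope_deg = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return dem.with_values(slope_deg, np.isnan(slope_deg))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def compute_indicators(
    scene: Scene,
    coeffs: TasseledCapCoefficients | None = None,
    emissivity_model: EmissivityModel | None = None,
    lst_celsius: bool = True,
) -> dict[str, RasterGrid]:
    """Compute all eight indicator rasters for a scene.

    Returns a mapping with keys ``ndvi``, ``wet``, ``dem``, ``slope``,
    ``aod``, ``ndbsi``, ``lst``, ``pd`` (raw physical scales, before any
    normalization).  DEM, AOD and PD are validated pass-through layers.
    """
    model = emissivity_model or EmissivityModel()
    ndvi_grid = ndvi(scene)
    wet_grid = wetness(scene, coeffs)
    si = bare_soil_index(scene)
    ibi = built_up_index(scene)
    dry = ndbsi(ibi, si)
    fvc_grid = fvc(ndvi_grid, model)
    eps = emissivity(ndvi_grid, fvc_grid, model)
    bts = blackbody_radiance(scene, eps)
    if scene.planck is None:
        raise ValueError("scene has no Planck constants")
    heat = lst(bts, scene.planck, output_celsius=lst_celsius)
    dem = scene.band("dem")
    return {
        "ndvi": ndvi_grid,
        "wet": wet_grid,
        "dem": dem,
        "slope": slope_from_dem(dem),
        "aod": scene.band("aod"),
        "ndbsi": dry,
        "lst": heat,
        "pd": scene.band("pd"),
    }
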