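"""Seeded synthetic scenes with a known latent livability gradient.

The generator emulates the statistical structure of an arid-region study
area — vegetated plains grading into bare desert, with mountains as an
independent terrain driver — so the whole pipeline can be exercised and
validated without any satellite download.  A smooth latent field in
[0, 1] ("livability truth") drives all observable layers coherently:

* reflectance = latent·vegetation-endmember + (1-latent)·soil-endmember
  plus Gaussian noise, clipped to [0, 1] (linear spectral mixing);
* surface temperature decreases linearly with latent (greener = cooler),
  and the thermal band carries the exact forward radiance model —
  Planck emission at that temperature, attenuated by the emissivity the
  scene's own NDVI implies and by the configured atmosphere — so the
  pipeline's LST retrieval is its exact inverse;
* AOD and population density decrease with latent plus noise (both load
  negatively on livability in arid urban clusters);
* the DEM mixes an independent smooth relief with a component
  anti-correlated with the latent field (``dem_latent_coupling``, default
  0.5): in arid mountain-and-plain regions terrain is itself strongly
  expressed in the livability gradient, while retaining an independent
  relief component keeps it a partial nuisance driver.  Setting the
  coupling to 0 makes terrain fully independent for harder recovery
  experiments.

Everything is deterministic given (config, seed): regeneration is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from rseli.indicators import EmissivityModel
from rseli.raster import GridTransform, RasterGrid
from rseli.scene import (
    REFLECTANCE_BANDS,
    AtmosphericParams,
    PlanckConstants,
    Scene,
)

__all__ = [
    "SceneConfig",
    "generate_latent",
    "generate_scene",
    "planck_forward",
    "forward_radiance",
]

#: Typical spectra (blue, green, red, nir, swir1, swir2), surface reflectance.
_VEG_ENDMEMBER = (0.03, 0.06, 0.04, 0.45, 0.20, 0.10)
_SOIL_ENDMEMBER = (0.12, 0.18, 0.26, 0.33, 0.44, 0.38)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Defaults describe a 128x128 scene of 1 km pixels over an arid urban
    cluster: moderate reflectance noise (sd 0.02), surface temperatures
    spanning 293-318 K inversely with the livability gradient, 1500 m of
    terrain relief, AOD between 0.1 and 0.8, population density up to 50
    people per cell, and 2% of cells masked as nodata.
    """

    rows: int = 128
    cols: int = 128
    seed: int = 0
    year: int = 0
    pixel_size: float = 1000.0  # metres
    latent_scale: float = 12.0  # smoothing length of the latent field, pixels
    veg_endmember: tuple[float, ...] = _VEG_ENDMEMBER
    soil_endmember: tuple[float, ...] = _SOIL_ENDMEMBER
    reflectance_noise_sd: float = 0.02
    t_min: float = 293.0  # kelvin, at latent = 1
    t_max: float = 318.0  # kelvin, at latent = 0
    thermal_noise_sd: float = 0.0  # radiance units
    atmos: AtmosphericParams = field(
        default_factory=lambda: AtmosphericParams(l_up=2.5, l_down=4.0, t=0.85)
    )
    planck: PlanckConstants = field(
        default_factory=lambda: PlanckConstants(k1=774.8853, k2=1321.0789)
    )
    dem_relief: float = 1500.0  # metres
    dem_base: float = 400.0  # metres
    dem_scale: float = 12.0  # smoothing length of the relief, pixels
    dem_latent_coupling: float = 0.5  # 0 = independent terrain, 1 = fully coupled
    aod_range: tuple[float, float] = (0.1, 0.8)
    aod_noise_sd: float = 0.02
    pd_range: tuple[float, float] = (0.0, 50.0)
    pd_noise_sd: float = 2.0
    nodata_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")
        for em in (self.veg_endmember, self.soil_endmember):
            if len(em) != 6 or not all(0.0 <= v <= 1.0 for v in em):
                raise ValueError(f"endmember out of [0, 1]: {em}")
        if self.reflectance_noise_sd < 0 or self.aod_noise_sd < 0 or self.pd_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not 0.0 <= self.nodata_fraction < 1.0:
            raise ValueError("nodata_fraction must be in [0, 1)")
        if self.t_min >= self.t_max or self.t_min <= 0:
            raise ValueError("need 0 < t_min < t_max")

    def transform(self) -> GridTransform:
        return GridTransform(500000.0, 4800000.0, self.pixel_size, -self.pixel_size)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["atmos"] = asdict(self.atmos)
        d["planck"] = asdict(self.planck)
        return d


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Low-pass-filtered Gaussian noise rescaled to span exactly [0, 1]."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=scale, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    if hi == lo:  # pathological but possible at size 1
        return np.zeros(shape)
    return (smooth - lo) / (hi - lo)


def generate_latent(config: SceneConfig) -> RasterGrid:
    """The latent livability truth field: smooth, seeded, spanning [0, 1]."""
    rng = np.random.default_rng(config.seed)
    return RasterGrid(
        _smooth_field(rng, (config.rows, config.cols), config.latent_scale),
        config.transform(),
    )


def planck_forward(t_kelvin: RasterGrid, planck: PlanckConstants) -> RasterGrid:
    """Blackbody radiance B = K1 / (exp(K2/T) - 1); exact inverse of the
    pipeline's Planck-function LST retrieval."""
    t = t_kelvin.values
    if np.any(t[t_kelvin.valid_mask] <= 0):
        raise ValueError("temperature must be positive")
    return t_kelvin.with_values(planck.k1 / (np.expm1(planck.k2 / t)))


def forward_radiance(
    b: RasterGrid, emissivity: RasterGrid, atmos: AtmosphericParams
) -> RasterGrid:
    """At-sensor radiance L = B·t·ε + L_up + t·(1-ε)·L_down; exact inverse
    of the pipeline's atmospheric correction."""
    eps = emissivity.values
    values = b.values * atmos.t * eps + atmos.l_up + atmos.t * (1.0 - eps) * atmos.l_down
    return b.with_values(values, emissivity.nodata_mask)


def _implied_emissivity(ndvi: np.ndarray, model: EmissivityModel) -> np.ndarray:
    """Emissivity the pipeline will infer from this NDVI (same piecewise model)."""
    f = np.clip((ndvi - model.fvc_soil_max) / (model.fvc_veg_min - model.fvc_soil_max), 0, 1)

    def poly(c):
        return c[0] + c[1] * f + c[2] * f * f

    return np.where(
        ndvi <= model.ndvi_water_max,
        model.e_water,
        np.where(ndvi >= model.ndvi_natural_min, poly(model.natural_poly), poly(model.building_poly)),
    )


def generate_scene(config: SceneConfig) -> tuple[Scene, RasterGrid]:
    """Generate a full Scene plus its latent truth grid.

    All bands share one planted nodata mask (``nodata_fraction`` of cells,
    chosen uniformly at random).  The thermal band is produced by the
    exact forward radiance model, using the emissivity implied by the
    scene's own (noisy) NDVI, so retrieval errors measure only noise, not
    model mismatch.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.rows, config.cols)
    transform = config.transform()

    latent = _smooth_field(rng, shape, config.latent_scale)

    # Reflectance bands: linear mixing of endmembers along the gradient.
    bands: dict[str, RasterGrid] = {}
    reflectances: dict[str, np.ndarray] = {}
    for i, role in enumerate(REFLECTANCE_BANDS):
        clean = latent * config.veg_endmember[i] + (1.0 - latent) * config.soil_endmember[i]
        noisy = clean + rng.normal(0.0, config.reflectance_noise_sd, shape)
        reflectances[role] = np.clip(noisy, 0.0, 1.0)

    # Thermal band via the exact forward model.
    t_true = config.t_max - latent * (config.t_max - config.t_min)
    nir, red = reflectances["nir"], reflectances["red"]
    with np.errstate(invalid="ignore"):
        ndvi = np.where(nir + red != 0, (nir - red) / (nir + red), 0.0)
    eps = _implied_emissivity(ndvi, EmissivityModel())
    b_true = config.planck.k1 / np.expm1(config.planck.k2 / t_true)
    radiance = (
        b_true * config.atmos.t * eps
        + config.atmos.l_up
        + config.atmos.t * (1.0 - eps) * config.atmos.l_down
    )
    if config.thermal_noise_sd > 0:
        radiance = radiance + rng.normal(0.0, config.thermal_noise_sd, shape)

    # Terrain: smooth relief, by default independent of the latent field.
    relief = _smooth_field(rng, shape, config.dem_scale)
    c = config.dem_latent_coupling
    if c != 0.0:
        relief = np.clip((1.0 - abs(c)) * relief + abs(c) * (1.0 - latent if c > 0 else latent), 0, 1)
    dem = config.dem_base + config.dem_relief * relief

    # Air quality and population: anti-correlated with livability.
    aod_lo, aod_hi = config.aod_range
    aod = aod_lo + (1.0 - latent) * (aod_hi - aod_lo)
    aod = np.clip(aod + rng.normal(0.0, config.aod_noise_sd, shape), 0.0, None)
    pd_lo, pd_hi = config.pd_range
    pd = pd_lo + (1.0 - latent) * (pd_hi - pd_lo)
    pd = np.clip(pd + rng.normal(0.0, config.pd_noise_sd, shape), 0.0, None)

    # One shared planted nodata mask.
    mask = np.zeros(shape, dtype=bool)
    n_bad = int(round(config.nodata_fraction * latent.size))
    if n_bad:
        flat = rng.choice(latent.size, size=n_bad, replace=False)
        mask.flat[flat] = True

    for role in REFLECTANCE_BANDS:
        bands[role] = RasterGrid(reflectances[role], transform, mask)
    bands["tir_radiance"] = RasterGrid(radiance, transform, mask)
    bands["dem"] = RasterGrid(dem, transform, mask)
    bands["aod"] = RasterGrid(aod, transform, mask)
    bands["pd"] = RasterGrid(pd, transform, mask)

    scene = Scene(
        year=config.year,
        bands=bands,
        atmos=config.atmos,
        planck=config.planck,
    )
    return scene, RasterGrid(latent, transform)
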