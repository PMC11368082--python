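"""Scene container: co-registered bands plus scalar physics constants.

A :class:`Scene` bundles everything the indicator computations need for one
year: the six surface-reflectance bands, the at-sensor thermal radiance,
the elevation model, aerosol optical depth and population density grids,
together with the atmospheric correction parameters (upward/downward
radiance, transmittance) and the sensor's Planck calibration constants.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from rseli.raster import RasterGrid, assert_aligned, read_grid

__all__ = [
    "BAND_ROLES",
    "REFLECTANCE_BANDS",
    "AtmosphericParams",
    "PlanckConstants",
    "Scene",
    "MissingBandError",
    "load_scene",
]

#: Every band role a Scene may carry.
BAND_ROLES = (
    "blue",
    "green",
    "red",
    "nir",
    "swir1",
    "swir2",
    "tir_radiance",
    "dem",
    "aod",
    "pd",
)

#: The optical surface-reflectance subset (dimensionless, ~0-1).
REFLECTANCE_BANDS = ("blue", "green", "red", "nir", "swir1", "swir2")


class MissingBandError(KeyError):
    """A computation needs a band the scene does not carry."""


@dataclass(frozen=True)
class AtmosphericParams:
    """Thermal-band atmospheric correction terms.

    ``l_up`` and ``l_down`` are the atmospheric upward and downward
    radiances (W·m⁻²·sr⁻¹·µm⁻¹); ``t`` is the thermal-band transmittance.
    """

    l_up: float
    l_down: float
    t: float

    def __post_init__(self) -> None:
        if not 0.0 < self.t <= 1.0:
            raise ValueError(f"transmittance t must be in (0, 1], got {self.t}")


@dataclass(frozen=True)
class PlanckConstants:
    """Sensor Planck calibration constants.

    ``k1`` in radiance units (W·m⁻²·sr⁻¹·µm⁻¹), ``k2`` in kelvin.
    """

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError(f"Planck constants must be positive, got {self}")


@dataclass
class Scene:
    """Named collection of co-registered grids for one year.

    All present bands must share shape, transform and pixel area; this is
    checked at construction.
    """

    year: int
    bands: dict[str, RasterGrid] = field(default_factory=dict)
    atmos: AtmosphericParams | None = None
    planck: PlanckConstants | None = None

    def __post_init__(self) -> None:
        unknown = set(self.bands) - set(BAND_ROLES)
        if unknown:
            raise ValueError(f"unknown band roles: {sorted(unknown)}")
        if self.bands:
            assert_aligned(list(self.bands.values()))

    def band(self, role: str) -> RasterGrid:
        try:
            return self.bands[role]
        except KeyError:
            raise MissingBandError(
                f"scene {self.year} is missing required band '{role}'"
            ) from None

    def require(self, *roles: str) -> tuple[RasterGrid, ...]:
        return tuple(self.band(r) for r in roles)

    @property
    def shape(self) -> tuple[int, int]:
        if not self.bands:
            raise ValueError("scene has no bands")
        return next(iter(self.bands.values())).shape

    @property
    def pixel_area(self) -> float:
        return next(iter(self.bands.values())).pixel_area


def load_scene(config: Mapping | str | os.PathLike, year: int | None = None) -> Scene:
    """Build a Scene from a config mapping or YAML file.

    The config must contain ``bands`` (role -> GeoTIFF path, with optional
    ``band_index``), ``atmos`` (``l_up``, ``l_down``, ``t``) and ``planck``
    (``k1``, ``k2``).  Relative band paths are resolved against the config
    file's directory.
    """
    base = ""
    if not isinstance(config, Mapping):
        base = os.path.dirname(os.fspath(config))
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if year is None:
        year = int(config["year"])
    bands = {}
    for role, entry in config["bands"].items():
        if isinstance(entry, Mapping):
            path, idx = entry["path"], int(entry.get("band_index", 0))
        else:
            path, idx = entry, 0
        if base and not os.path.isabs(path):
            path = os.path.join(base, path)
        bands[role] = read_grid(path, idx)
    atmos = AtmosphericParams(**{k: float(v) for k, v in config["atmos"].items()})
    planck = PlanckConstants(**{k: float(v) for k, v in config["planck"].items()})
    return Scene(year=year, bands=bands, atmos=atmos, planck=planck)
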