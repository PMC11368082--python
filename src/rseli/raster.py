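"""Core raster data model and GeoTIFF input/output.

A :class:`RasterGrid` couples a 2-D value array with an affine
georeferencing transform, a nodata mask and the area of one pixel in km².
Grids are the common currency of the pipeline: every reflectance band,
indicator, normalized layer and the final livability surface is one.

Conventions
-----------
* Row-major arrays; the transform maps (col, row) pixel indices to
  projected map coordinates of the pixel's upper-left corner
  (pixel-is-area, as in the GeoTIFF standard).
* Nodata is ``NaN`` internally and the sentinel ``-9999`` on disk, so
  invalid cells propagate unambiguously through arithmetic.
* Inputs must already be co-registered: no reprojection or resampling is
  performed, and misaligned grids raise :class:`AlignmentError`.
* Coordinates must be projected (metric).  Files tagged as geographic
  (degree) rasters are rejected rather than approximated.

GeoTIFFs are read and written with :mod:`tifffile`; georeferencing is
carried by the standard ``ModelPixelScale`` / ``ModelTiepoint`` /
``GeoKeyDirectory`` tags and nodata by the ``GDAL_NODATA`` tag.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import tifffile

__all__ = [
    "GridTransform",
    "RasterGrid",
    "RasterError",
    "AlignmentError",
    "GeoreferencingError",
    "NODATA_SENTINEL",
    "read_grid",
    "write_grid",
    "assert_aligned",
    "combined_mask",
]

#: Sentinel value encoding nodata cells on disk.
NODATA_SENTINEL = -9999.0

# GeoTIFF tag codes.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids / values (GeoTIFF 1.1).
_KEY_MODEL_TYPE = 1024
_MODEL_TYPE_PROJECTED = 1
_MODEL_TYPE_GEOGRAPHIC = 2


class RasterError(Exception):
    """Base class for raster-model failures."""


class AlignmentError(RasterError):
    """Two grids that must share a layout do not."""


class GeoreferencingError(RasterError):
    """A file lacks usable projected georeferencing."""


@dataclass(frozen=True)
class GridTransform:
    """Axis-aligned affine transform from pixel indices to map coordinates.

    ``x = x_origin + col * pixel_width``;
    ``y = y_origin + row * pixel_height`` (``pixel_height`` is negative for
    the usual north-up raster).  Units are metres.
    """

    x_origin: float
    y_origin: float
    pixel_width: float
    pixel_height: float

    def __post_init__(self) -> None:
        if self.pixel_width == 0 or self.pixel_height == 0:
            raise GeoreferencingError("pixel dimensions must be non-zero")

    def pixel_area_km2(self) -> float:
        """Area of one cell in km², from metric pixel dimensions."""
        return abs(self.pixel_width * self.pixel_height) / 1e6

    def allclose(self, other: "GridTransform", atol: float = 1e-9) -> bool:
        return all(
            math.isclose(a, b, rel_tol=0.0, abs_tol=atol)
            for a, b in (
                (self.x_origin, other.x_origin),
                (self.y_origin, other.y_origin),
                (self.pixel_width, other.pixel_width),
                (self.pixel_height, other.pixel_height),
            )
        )


class RasterGrid:
    """A single-band raster: values, georeferencing and validity mask.

    Parameters
    ----------
    values
        2-D array of cell values.  Stored as float64; cells flagged invalid
        are forced to NaN.
    transform
        Pixel-to-map :class:`GridTransform` in metric coordinates.
    nodata_mask
        Boolean array, same shape as ``values``; True marks invalid cells.
        NaNs in ``values`` are always treated as invalid regardless.
    """

    __slots__ = ("values", "transform", "nodata_mask")

    def __init__(
        self,
        values: np.ndarray,
        transform: GridTransform,
        nodata_mask: np.ndarray | None = None,
    ) -> None:
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2:
            raise RasterError(f"values must be 2-D, got shape {values.shape}")
        if nodata_mask is None:
            mask = np.isnan(values)
        else:
            mask = np.asarray(nodata_mask, dtype=bool)
            if mask.shape != values.shape:
                raise RasterError(
                    f"mask shape {mask.shape} != values shape {values.shape}"
                )
            mask = mask | np.isnan(values)
        values = values.copy()
        values[mask] = np.nan
        self.values = values
        self.transform = transform
        self.nodata_mask = mask

    # -- basic properties -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area(self) -> float:
        """km² per cell."""
        return self.transform.pixel_area_km2()

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_values(self) -> np.ndarray:
        """1-D array of values at valid cells only."""
        return self.values[self.valid_mask]

    # -- statistics over valid cells --------------------------------------

    def min(self) -> float:
        return float(np.nanmin(self.values))

    def max(self) -> float:
        return float(np.nanmax(self.values))

    def mean(self) -> float:
        return float(np.nanmean(self.values))

    def percentile(self, q: float | Sequence[float]) -> np.ndarray | float:
        out = np.nanpercentile(self.values, q)
        return float(out) if np.isscalar(q) or np.ndim(q) == 0 else out

    # -- derivation helpers ------------------------------------------------

    def with_values(
        self, values: np.ndarray, extra_mask: np.ndarray | None = None
    ) -> "RasterGrid":
        """New grid sharing this grid's layout; masks propagate and may grow."""
        mask = self.nodata_mask if extra_mask is None else self.nodata_mask | extra_mask
        return RasterGrid(values, self.transform, mask)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RasterGrid(shape={self.shape}, valid={self.n_valid}/"
            f"{self.values.size}, pixel_area={self.pixel_area:g} km²)"
        )


# ---------------------------------------------------------------------------
# Alignment and masking
# ---------------------------------------------------------------------------


def assert_aligned(grids: Iterable[RasterGrid], atol: float = 1e-9) -> None:
    """Check that all grids share shape and transform.

    Raises :class:`AlignmentError` naming the first offending grid (by
    position) and the mismatched attribute.
    """
    grids = list(grids)
    if not grids:
        raise RasterError("assert_aligned requires at least one grid")
    ref = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if g.shape != ref.shape:
            raise AlignmentError(
                f"grid {i}: shape {g.shape} != reference shape {ref.shape}"
            )
        if not g.transform.allclose(ref.transform, atol=atol):
            raise AlignmentError(
                f"grid {i}: transform {g.transform} != reference {ref.transform}"
            )


def combined_mask(grids: Iterable[RasterGrid]) -> np.ndarray:
    """Union of nodata masks: a cell is invalid if invalid in ANY grid."""
    grids = list(grids)
    assert_aligned(grids)
    mask = np.zeros(grids[0].shape, dtype=bool)
    for g in grids:
        mask |= g.nodata_mask
    return mask


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------


def write_grid(grid: RasterGrid, path: str | os.PathLike) -> None:
    """Write a grid as a single-band float32 GeoTIFF.

    Nodata cells are stored as the ``-9999`` sentinel and declared via the
    ``GDAL_NODATA`` tag; georeferencing goes into ``ModelPixelScale`` and
    ``ModelTiepoint``; a minimal GeoKey directory marks the CRS as
    projected.  ``read_grid`` inverts this exactly (at float32 precision).
    """
    data = grid.values.astype(np.float32)
    data[grid.nodata_mask] = np.float32(NODATA_SENTINEL)
    t = grid.transform
    # GeoTIFF pixel scale is (sx, sy, sz) with sy positive for north-up.
    pixel_scale = (abs(t.pixel_width), abs(t.pixel_height), 0.0)
    tiepoint = (0.0, 0.0, 0.0, t.x_origin, t.y_origin, 0.0)
    # Minimal key directory: version 1.1.0, one key: projected model type.
    geokeys = (1, 1, 0, 1, _KEY_MODEL_TYPE, 0, 1, _MODEL_TYPE_PROJECTED)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, pixel_scale, True),
        (_TAG_MODEL_TIEPOINT, "d", 6, tiepoint, True),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys, True),
        (_TAG_GDAL_NODATA, "s", 0, str(NODATA_SENTINEL), True),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_grid(path: str | os.PathLike, band_index: int = 0) -> RasterGrid:
    """Read one band of a GeoTIFF into a :class:`RasterGrid`.

    Multi-band files may store bands either as separate pages or as a
    sample dimension; ``band_index`` addresses either layout.  Missing
    georeferencing tags or a geographic (degree) CRS raise
    :class:`GeoreferencingError`; a declared nodata value becomes the mask.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        n_pages = len(tif.pages)
        page = tif.pages[0]
        tags = page.tags

        scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
        tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
        if scale is None or tiepoint is None:
            raise GeoreferencingError(
                f"{path}: missing ModelPixelScale/ModelTiepoint georeferencing"
            )
        geokeys = tags.get(_TAG_GEO_KEY_DIRECTORY)
        if geokeys is not None:
            kv = np.asarray(geokeys.value).ravel()
            # Key entries start after the 4-word header, in 4-word records.
            for k in range(4, len(kv) - 3, 4):
                if kv[k] == _KEY_MODEL_TYPE and kv[k + 3] == _MODEL_TYPE_GEOGRAPHIC:
                    raise GeoreferencingError(
                        f"{path}: geographic (degree) rasters are not supported; "
                        "provide a projected, metric grid"
                    )

        sx, sy = float(scale.value[0]), float(scale.value[1])
        tp = tiepoint.value
        # Tiepoint maps raster (i, j) to model (x, y); shift to pixel (0, 0).
        x_origin = float(tp[3]) - float(tp[0]) * sx
        y_origin = float(tp[4]) + float(tp[1]) * sy
        transform = GridTransform(x_origin, y_origin, sx, -sy)

        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        nodata = float(nodata_tag.value) if nodata_tag is not None else None

        if n_pages > 1:
            if not 0 <= band_index < n_pages:
                raise IndexError(
                    f"band_index {band_index} out of range for {n_pages} pages"
                )
            data = tif.pages[band_index].asarray()
        else:
            data = page.asarray()
            if data.ndim == 3:  # samples-per-pixel > 1
                axis = 0 if data.shape[0] < min(data.shape[1:]) else 2
                n_bands = data.shape[axis]
                if not 0 <= band_index < n_bands:
                    raise IndexError(
                        f"band_index {band_index} out of range for {n_bands} bands"
                    )
                data = np.take(data, band_index, axis=axis)
            elif band_index != 0:
                raise IndexError(
                    f"band_index {band_index} out of range for single-band file"
                )

    data = np.asarray(data, dtype=np.float64)
    mask = np.isnan(data)
    if nodata is not None:
        mask |= data == nodata
    return RasterGrid(data, transform, mask)
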