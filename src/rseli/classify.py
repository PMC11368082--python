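"""Grading, area accounting and change detection on the RSELI surface.

The [0, 1] index is cut into five livability grades at 0.2 intervals:

====  =========  ====================  ===========
code  grade      meaning               RSELI range
====  =========  ====================  ===========
1     Poor       Extremely Unlivable   [0.0, 0.2)
2     Fair       Unlivable             [0.2, 0.4)
3     Moderate   Moderately Livable    [0.4, 0.6)
4     Good       Relatively Livable    [0.6, 0.8)
5     Excellent  Livable               [0.8, 1.0]
====  =========  ====================  ===========

Bins are lower-inclusive with the top bin closed so no pixel is lost.
Change between two years differences the integer grade codes
(later - earlier, range -4..+4) and categorizes the difference as
Improved (> 0), No Change (= 0) or Degraded (< 0).  Differencing codes
rather than the continuous index makes "unchanged" a meaningful category.
Areas are reported in 10^4 km² alongside proportions of the valid area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rseli.raster import RasterGrid, assert_aligned

__all__ = [
    "GRADE_LABELS",
    "CHANGE_LABELS",
    "ClassMap",
    "ChangeMap",
    "classify",
    "area_table",
    "change_map",
    "change_table",
    "scene_summary",
]

GRADE_LABELS = {
    1: "Poor",
    2: "Fair",
    3: "Moderate",
    4: "Good",
    5: "Excellent",
}

CHANGE_LABELS = ("Degraded", "No Change", "Improved")

#: km² per 10^4 km² reporting unit.
_AREA_UNIT = 1e4


@dataclass(frozen=True)
class ClassMap:
    """Integer-coded livability grades (1..5) with mask and pixel area."""

    codes: np.ndarray  # int, 0 on invalid cells
    nodata_mask: np.ndarray
    pixel_area: float  # km² per cell
    year: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape


@dataclass(frozen=True)
class ChangeMap:
    """Grade-code differences (later - earlier) in -4..+4 with mask."""

    diff: np.ndarray  # int
    nodata_mask: np.ndarray
    pixel_area: float
    years: tuple[int, int]

    def categories(self) -> np.ndarray:
        """Categorical view: -1 Degraded, 0 No Change, +1 Improved."""
        return np.sign(self.diff)


def classify(rseli: RasterGrid, year: int = 0) -> ClassMap:
    """Cut the RSELI surface into the five 0.2-wide grades.

    Values must lie in [0, 1] on valid cells; 1.0 belongs to the top
    grade (Excellent).
    """
    vals = rseli.valid_values()
    if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
        raise ValueError(
            f"RSELI values out of [0, 1]: range [{vals.min():g}, {vals.max():g}]"
        )
    # digitize with right=False: [0,0.2) -> 1 ... [0.8,1) -> 5; clip 1.0 into 5.
    codes = np.digitize(np.nan_to_num(rseli.values, nan=-1.0), [0.2, 0.4, 0.6, 0.8]) + 1
    codes = np.minimum(codes, 5)
    codes[rseli.nodata_mask] = 0
    return ClassMap(
        codes=codes.astype(np.int16),
        nodata_mask=rseli.nodata_mask.copy(),
        pixel_area=rseli.pixel_area,
        year=year,
    )


def _make_table(
    labels: list[str], counts: np.ndarray, pixel_area: float, **extra
) -> pd.DataFrame:
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid cells to tabulate")
    areas = counts * pixel_area / _AREA_UNIT
    table = pd.DataFrame(
        {
            **extra,
            "class": labels,
            "cell_count": counts,
            "area_1e4_km2": areas,
            "proportion_pct": 100.0 * counts / total,
        }
    )
    return table


def area_table(classmap: ClassMap) -> pd.DataFrame:
    """Per-grade area (10^4 km²) and proportion (%) of the valid area.

    All five grades are always listed; proportions sum to 100 and areas
    to the total valid area exactly (integer cell counting).
    """
    valid_codes = classmap.codes[~classmap.nodata_mask]
    counts = np.bincount(valid_codes, minlength=6)[1:6]
    return _make_table(
        [GRADE_LABELS[c] for c in range(1, 6)],
        counts,
        classmap.pixel_area,
        year=classmap.year,
    )


def change_map(earlier: ClassMap, later: ClassMap) -> ChangeMap:
    """Difference two classified years (later - earlier) per valid cell."""
    if earlier.shape != later.shape:
        raise ValueError(f"shape mismatch {earlier.shape} vs {later.shape}")
    if not np.isclose(earlier.pixel_area, later.pixel_area):
        raise ValueError("pixel areas differ between years")
    mask = earlier.nodata_mask | later.nodata_mask
    diff = (later.codes.astype(np.int16) - earlier.codes.astype(np.int16))
    diff[mask] = 0
    return ChangeMap(
        diff=diff,
        nodata_mask=mask,
        pixel_area=earlier.pixel_area,
        years=(earlier.year, later.year),
    )


def change_table(changemap: ChangeMap) -> pd.DataFrame:
    """Areas and proportions of the Degraded / No Change / Improved classes."""
    cats = changemap.categories()[~changemap.nodata_mask]
    counts = np.array([(cats < 0).sum(), (cats == 0).sum(), (cats > 0).sum()])
    period = f"{changemap.years[0]}-{changemap.years[1]}"
    return _make_table(
        list(CHANGE_LABELS), counts, changemap.pixel_area, period=period
    )


def scene_summary(
    rseli: RasterGrid, indicators: dict[str, RasterGrid], year: int = 0
) -> pd.DataFrame:
    """Valid-cell means of RSELI and the raw indicators for one year.

    Mirrors the conventional per-year factor summary: RSELI plus AOD, LST
    (°C), NDBSI, NDVI, WET and PD on their raw, pre-normalization scales.
    """
    rows = {"RSELI": rseli.mean()}
    for key, label in [
        ("aod", "AOD"),
        ("lst", "LST"),
        ("ndbsi", "NDBSI"),
        ("ndvi", "NDVI"),
        ("wet", "WET"),
        ("pd", "PD"),
    ]:
        if key in indicators:
            rows[label] = indicators[key].mean()
    return pd.DataFrame({"factor": list(rows), "mean": list(rows.values()), "year": year})
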