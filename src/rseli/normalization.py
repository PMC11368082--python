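"""Winsorization and min-max normalization of indicator layers.

The eight indicators carry incommensurable units (°C, metres, people per
cell, dimensionless ratios), so before PCA each layer is clamped to its
5th-95th percentile interval (winsorization: outliers are set to the
bound, no cells are discarded) and rescaled to [0, 1] with the standard
min-max transform XI = (I - I_min) / (I_max - I_min).

Normalization is done per year and per indicator; each step emits a
:class:`NormalizationRecord` so the bounds actually used are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from rseli.raster import RasterGrid

__all__ = [
    "NormalizationRecord",
    "percentile_clip",
    "minmax_normalize",
    "normalize_layer",
    "records_to_frame",
]


@dataclass(frozen=True)
class NormalizationRecord:
    """Audit record of one layer's normalization."""

    indicator: str
    lower_bound: float  # winsorization lower percentile value
    upper_bound: float  # winsorization upper percentile value
    i_min: float  # minimum used in the min-max rescale
    i_max: float  # maximum used in the min-max rescale
    n_cells: int

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound or self.i_min > self.i_max:
            raise ValueError(f"inconsistent bounds in {self}")


def percentile_clip(
    grid: RasterGrid, lo_pct: float = 5.0, hi_pct: float = 95.0
) -> RasterGrid:
    """Winsorize valid cells to the [lo_pct, hi_pct] percentile interval.

    Percentiles are computed over valid cells with linear interpolation;
    values beyond a bound are set to the bound.  The mask is unchanged.
    """
    if not 0.0 <= lo_pct < hi_pct <= 100.0:
        raise ValueError(f"need 0 <= lo < hi <= 100, got ({lo_pct}, {hi_pct})")
    if grid.n_valid == 0:
        raise ValueError("percentile_clip needs at least one valid cell")
    lo, hi = np.nanpercentile(grid.values, [lo_pct, hi_pct])
    return grid.with_values(np.clip(grid.values, lo, hi))


def minmax_normalize(
    grid: RasterGrid, indicator: str = ""
) -> tuple[RasterGrid, NormalizationRecord]:
    """Rescale valid cells to [0, 1] via (I - I_min) / (I_max - I_min).

    The valid-cell minimum maps to exactly 0 and the maximum to exactly 1.
    A constant grid (max == min) is a degenerate input and raises.
    """
    if grid.n_valid == 0:
        raise ValueError("minmax_normalize needs at least one valid cell")
    i_min, i_max = grid.min(), grid.max()
    if i_max == i_min:
        raise ValueError(
            f"layer '{indicator or '?'}' is constant ({i_min}); "
            "min-max normalization is undefined"
        )
    out = (grid.values - i_min) / (i_max - i_min)
    record = NormalizationRecord(
        indicator=indicator,
        lower_bound=i_min,
        upper_bound=i_max,
        i_min=i_min,
        i_max=i_max,
        n_cells=grid.n_valid,
    )
    return grid.with_values(out), record


def normalize_layer(
    grid: RasterGrid,
    indicator: str = "",
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
) -> tuple[RasterGrid, NormalizationRecord]:
    """Winsorize then min-max normalize one layer; the standard pipeline step.

    The record carries both the winsorization bounds and the min/max used
    by the rescale (after clipping these coincide).
    """
    lo, hi = np.nanpercentile(grid.values, [lo_pct, hi_pct])
    clipped = grid.with_values(np.clip(grid.values, lo, hi))
    normalized, _ = minmax_normalize(clipped, indicator)
    record = NormalizationRecord(
        indicator=indicator,
        lower_bound=float(lo),
        upper_bound=float(hi),
        i_min=clipped.min(),
        i_max=clipped.max(),
        n_cells=grid.n_valid,
    )
    return normalized, record


def records_to_frame(records: list[NormalizationRecord]) -> pd.DataFrame:
    """Tabulate audit records (one row per indicator) for CSV export."""
    return pd.DataFrame([asdict(r) for r in records])
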