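"""PCA compositing of the eight normalized indicators into the RSELI surface.

The normalized layers are stacked in a fixed canonical order
(NDVI, WET, DEM, SLOPE, AOD, NDBSI, LST, PD), the 8x8 covariance matrix of
the valid-pixel vectors is eigendecomposed (covariance PCA — the layers
were already brought to a common [0, 1] scale by normalization, so no
second standardization is applied), and the first principal component is
projected and min-max rescaled into the final [0, 1] livability index.

An eigenvector's sign is arbitrary; PC1 is oriented so that greenness
(NDVI) loads positively — higher index therefore always means more
livable.  If the NDVI loading is exactly zero, the wetness loading breaks
the tie.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from rseli.normalization import NormalizationRecord, normalize_layer
from rseli.raster import RasterGrid, assert_aligned, combined_mask

__all__ = [
    "LAYER_ORDER",
    "IndicatorStack",
    "PCAResult",
    "build_stack",
    "fit_pca",
    "orient_pc1",
    "project_pc1",
    "rescale_rseli",
    "compose_rseli",
    "pca_to_frame",
]

#: Canonical layer order of the composite.
LAYER_ORDER = ("ndvi", "wet", "dem", "slope", "aod", "ndbsi", "lst", "pd")


@dataclass(frozen=True)
class IndicatorStack:
    """The eight normalized indicator layers sharing one validity mask."""

    layers: tuple[RasterGrid, ...]  # canonical order
    mask: np.ndarray  # True = invalid, intersection-of-valid
    year: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0].shape

    @property
    def n_valid(self) -> int:
        return int((~self.mask).sum())

    def matrix(self) -> np.ndarray:
        """(n_valid, 8) matrix of valid-pixel indicator vectors."""
        valid = ~self.mask
        return np.column_stack([g.values[valid] for g in self.layers])


@dataclass(frozen=True)
class PCAResult:
    """Eigendecomposition of the indicator covariance matrix.

    ``loadings`` is 8x8 with columns = components (descending eigenvalue)
    and rows in canonical layer order; ``contribution_rates`` are each
    eigenvalue's fraction of total variance.
    """

    eigenvalues: np.ndarray  # (8,), descending, >= 0
    loadings: np.ndarray  # (8, 8), orthonormal columns
    contribution_rates: np.ndarray  # (8,), sums to 1
    means: np.ndarray  # (8,) layer means over valid pixels
    oriented: bool = False

    @property
    def pc1(self) -> np.ndarray:
        return self.loadings[:, 0]


def build_stack(
    layers: dict[str, RasterGrid] | list[RasterGrid], year: int
) -> IndicatorStack:
    """Assemble eight aligned normalized layers into a stack.

    Accepts either a mapping keyed by canonical layer names or a list
    already in canonical order.  Layers must be aligned and in [0, 1] on
    valid cells; the stack's mask is the intersection of layer validity.
    """
    if isinstance(layers, dict):
        missing = [k for k in LAYER_ORDER if k not in layers]
        if missing:
            raise ValueError(f"missing layers: {missing}")
        ordered = [layers[k] for k in LAYER_ORDER]
    else:
        ordered = list(layers)
    if len(ordered) != len(LAYER_ORDER):
        raise ValueError(f"expected {len(LAYER_ORDER)} layers, got {len(ordered)}")
    assert_aligned(ordered)
    for name, g in zip(LAYER_ORDER, ordered):
        vals = g.valid_values()
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError(
                f"layer '{name}' is not normalized to [0, 1]: "
                f"range [{vals.min():g}, {vals.max():g}]"
            )
    mask = combined_mask(ordered)
    return IndicatorStack(tuple(ordered), mask, year)


def fit_pca(stack: IndicatorStack) -> PCAResult:
    """Covariance PCA over the stack's valid-pixel vectors.

    Eigendecomposition of the sample covariance matrix (means subtracted,
    no variance scaling); components sorted by descending eigenvalue.
    Rank-deficient stacks are fine (zero eigenvalues are kept so the
    8-layer contract stays stable); tiny negative rounding is clipped to 0.
    """
    n_layers = len(LAYER_ORDER)
    if stack.n_valid <= n_layers:
        raise ValueError(
            f"need more than {n_layers} valid pixels, got {stack.n_valid}"
        )
    x = stack.matrix()
    means = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    rates = evals / total if total > 0 else np.full(n_layers, 1.0 / n_layers)
    return PCAResult(
        eigenvalues=evals,
        loadings=evecs,
        contribution_rates=rates,
        means=means,
        oriented=False,
    )


def orient_pc1(pca: PCAResult) -> PCAResult:
    """Fix PC1's sign so greenness contributes positively to livability.

    PC1 is negated iff its NDVI loading is negative; if the NDVI loading
    is exactly zero the WET loading must be non-negative instead.
    """
    i_ndvi = LAYER_ORDER.index("ndvi")
    i_wet = LAYER_ORDER.index("wet")
    lead = pca.loadings[i_ndvi, 0]
    if lead == 0.0:
        lead = pca.loadings[i_wet, 0]
    loadings = pca.loadings.copy()
    if lead < 0:
        loadings[:, 0] = -loadings[:, 0]
    return replace(pca, loadings=loadings, oriented=True)


def project_pc1(stack: IndicatorStack, pca: PCAResult) -> RasterGrid:
    """Project each valid pixel's mean-centred 8-vector onto PC1."""
    if not pca.oriented:
        raise ValueError("orient the PCA (orient_pc1) before projecting")
    if pca.loadings.shape != (len(LAYER_ORDER), len(LAYER_ORDER)):
        raise ValueError(f"unexpected loadings shape {pca.loadings.shape}")
    valid = ~stack.mask
    x = stack.matrix() - pca.means
    scores = x @ pca.pc1
    out = np.full(stack.shape, np.nan)
    out[valid] = scores
    return stack.layers[0].with_values(out, stack.mask)


def rescale_rseli(pc1_grid: RasterGrid) -> RasterGrid:
    """Min-max rescale the PC1 scores into the final [0, 1] RSELI surface."""
    lo, hi = pc1_grid.min(), pc1_grid.max()
    if hi == lo:
        raise ValueError("PC1 surface is constant; RSELI is undefined")
    return pc1_grid.with_values((pc1_grid.values - lo) / (hi - lo))


def compose_rseli(
    indicators: dict[str, RasterGrid],
    year: int,
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
) -> tuple[RasterGrid, PCAResult, IndicatorStack, list[NormalizationRecord]]:
    """Full compositing chain: clip, normalize, stack, PCA, orient, project.

    Takes the raw indicator mapping from
    :func:`rseli.indicators.compute_indicators` and returns the RSELI
    surface with the fitted/oriented PCA, the normalized stack and the
    normalization audit records.
    """
    normalized: dict[str, RasterGrid] = {}
    records: list[NormalizationRecord] = []
    for name in LAYER_ORDER:
        if name not in indicators:
            raise ValueError(f"indicator mapping is missing '{name}'")
        layer, record = normalize_layer(indicators[name], name, lo_pct, hi_pct)
        normalized[name] = layer
        records.append(record)
    stack = build_stack(normalized, year)
    pca = orient_pc1(fit_pca(stack))
    rseli = rescale_rseli(project_pc1(stack, pca))
    return rseli, pca, stack, records


def pca_to_frame(pca: PCAResult) -> pd.DataFrame:
    """Loadings table: rows = indicators, columns = PC1..PC8, final row =
    contribution rate in percent."""
    cols = [f"PC{i + 1}" for i in range(len(LAYER_ORDER))]
    frame = pd.DataFrame(pca.loadings, index=[n.upper() for n in LAYER_ORDER], columns=cols)
    frame.loc["Contribution rate/%"] = pca.contribution_rates * 100.0
    return frame
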