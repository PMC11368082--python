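# Methods

## Scope and data model

The package computes a composite ecological-livability surface from eight
co-registered raster indicators and analyses it across years. It assumes
its inputs are already gridded to a common projected (metric) frame:
surface reflectance is atmospherically corrected (dimensionless, ~0–1),
the thermal band is at-sensor radiance, the DEM is in metres, AOD and
population density are consumed as given. No reprojection, resampling or
cloud masking is performed — misaligned grids are an error, and rasters
tagged with a geographic (degree) CRS are rejected rather than having
their pixel areas approximated. In the upstream products this pipeline
mirrors, the native resolutions differ (reflectance ~500 m, terrain 30 m,
population ~100 m); how they are best resampled to one grid is a
preprocessing decision left to the user, and the package only checks that
it has been made consistently.

Rasters are float64 arrays with NaN as the internal nodata value, written
to disk as float32 GeoTIFFs with a −9999 sentinel declared in the
`GDAL_NODATA` tag and georeferencing in the `ModelPixelScale` /
`ModelTiepoint` / `GeoKeyDirectory` tags. NaN propagation through
arithmetic guarantees the central masking invariant: a cell invalid in any
input is invalid in every derived product. Validity is intersected across
layers before the PCA, and all statistics (means, percentiles, min/max)
are computed over valid cells only.

## Indicators

* **NDVI, SI, IBI** are band ratios; any zero denominator (including the
  sub-ratios of IBI) makes the cell nodata rather than ±inf.
* **Wetness** is the tasseled-cap transform with the Landsat-TM
  coefficient set as default (0.0315, 0.2021, 0.3102, 0.1594, −0.6806,
  −0.6109). These weights are, strictly, sensor-specific; the coefficient
  table is a configurable dataclass so a sensor-matched set can be
  supplied, but the defaults are kept as the conventional choice for this
  index family.
* **NDBSI** is the plain average of IBI and SI.
* **FVC** rescales NDVI linearly between 0.05 (bare soil) and 0.7 (full
  cover), saturating at 0 and 1 outside. **Emissivity** uses different
  breakpoints on purpose (water at NDVI ≤ 0, natural vegetation at
  NDVI ≥ 0.7) — the two piecewise rules are implemented exactly as
  specified rather than harmonized, and NDVI = 0.7 is assigned to the
  natural branch so the ranges cannot overlap. Assigning the "building"
  polynomial to the whole 0 < NDVI < 0.7 range is a known simplification
  of this emissivity family: sparse natural vegetation is treated as
  built/mixed surface.
* **LST** is a single-channel retrieval: the at-sensor radiance is
  corrected for the atmosphere and emissivity,
  B(Ts) = (L − L_up − t(1−ε)L_down)/(t·ε), and inverted through the Planck
  function LST = K₂/ln(K₁/B + 1). Cells where the corrected radiance is
  non-positive are nodata. K₁, K₂, L_up, L_down and t are required config
  inputs (they are sensor- and scene-specific); the synthetic defaults use
  the Landsat-8 TIRS-1 calibration pair K₁ = 774.8853, K₂ = 1321.0789 and
  a mid-latitude-like atmosphere (L_up = 2.5, L_down = 4.0, t = 0.85).
  LST is reported in °C by default; Kelvin is available via a flag.
* **Slope** uses the Horn 3×3 weighted finite difference, the de-facto
  GIS standard, in degrees; edge cells fall back to one-sided/central
  differences. Cells adjacent to a nodata cell are nodata because the
  stencil is undefined there.
* **DEM, AOD, PD** are validated, masked pass-throughs.

## Normalization

"Select within the 5–95 % interval" is ambiguous between discarding and
clamping tail cells; the package **winsorizes** (clamps to the percentile
bounds) so no pixels are lost and area accounting stays exact over the
full valid mask. Percentiles use linear interpolation between closest
ranks — the dominant convention in numerical libraries; at scene scale the
difference between percentile definitions is negligible. Min-max
normalization then maps the clipped layer onto [0, 1] exactly
(minimum → 0, maximum → 1); a constant layer is a degenerate input and an
explicit error. Normalization is per year and per indicator — each year's
PCA is fitted independently — and every step emits an audit record
(bounds, min/max, cell count) exported as CSV.

## PCA compositing

The eight normalized layers are stacked in the fixed order NDVI, WET, DEM,
SLOPE, AOD, NDBSI, LST, PD, and the sample covariance matrix of the
valid-pixel vectors is eigendecomposed (`numpy.linalg.eigh`, deterministic).
**Covariance, not correlation**: the normalization step exists precisely to
put the layers on one scale, so standardizing again would discard its
purpose. Zero-variance layers are retained with zero loadings rather than
dropped, keeping the 8-layer contract stable; tiny negative eigenvalues
from rounding are clipped to zero. Contribution rates are eigenvalues over
their sum.

An eigenvector's sign is arbitrary, so PC1 is oriented by the rule "NDVI
loads positively" (greener ⇒ more livable), with the WET loading breaking
an exact-zero tie. The oriented PC1 scores are min-max rescaled to [0, 1]
to form the index — the standard convention for this index family, and the
only reading consistent with grading on absolute 0.2-wide bins. Rescaling
is invariant under positive affine transforms of the scores and preserves
pixel ranking.

## Classification and change

Grades are lower-inclusive 0.2 bins with the top bin closed at 1.0, so
every valid pixel receives a class (e.g. an index of 0.519 is Moderate).
Change detection differences the integer **class codes** (later − earlier,
range −4..+4), not the continuous index: on continuous values "unchanged"
would be a measure-zero event, so class differencing is the only reading
under which the three-way Improved/No Change/Degraded split is meaningful.
Areas are cell count × pixel area, reported in 10⁴ km²; proportions are
over the shared valid area and sum to 100 % by construction.

## Synthetic scenes

The generator emulates an arid mountain-and-plain region: a smooth latent
livability field (Gaussian white noise low-pass filtered at a 12-pixel
length scale, min-max rescaled to [0, 1]) drives all indicators.
Reflectance is a linear mixture of a vegetation and a soil endmember along
the latent gradient plus Gaussian noise (sd 0.02, clipped to [0, 1]);
surface temperature falls linearly from 318 K to 293 K as latent rises;
the thermal band is generated by the exact forward model (Planck emission
× t·ε + L_up + t(1−ε)L_down) using the emissivity implied by the scene's
own noisy NDVI, so the retrieval error on a noise-free scene measures pure
numerics. AOD (0.1–0.8) and population density (0–50 per cell) decrease
with latent plus noise, mirroring their negative loadings in arid urban
clusters. 2 % of cells are masked nodata, shared across bands. Scenes are
128×128 at 1 km pixels by default and bit-reproducible given (config,
seed).

Terrain: the DEM mixes an independent smooth relief with a component
anti-correlated with the latent field (`dem_latent_coupling`, default
0.5). A fully independent DEM was considered and rejected as the default:
in the regions this index family targets, elevation is typically the
single strongest PC1 loading — terrain is part of the livability gradient,
not pure nuisance — and a generator whose eight layers "coherently express"
the gradient must reflect that. With coupling 0.5 the noise-free PC1
contribution sits at ~80–85 % (the empirically reported regime is "above
75 %"), while the independent-relief component keeps terrain a partial
confounder. Setting the knob to 0 restores fully independent terrain for
harder recovery experiments.

What the generator does **not** emulate: sensor spectral response
functions, radiative-transfer realism, clouds, spatially correlated noise,
mixed land-cover classes beyond a two-endmember continuum, or
georeferencing error. Passing the recovery tests therefore shows the
pipeline's algebra and orientation logic are correct under a known ground
truth — not that the index is ecologically valid on real scenes.

## Numerical choices and degenerate inputs

* Percentile interpolation: linear; covariance ddof = 1 throughout (the
  projection-variance identity var(scores) = λ₁ holds at that ddof).
* Transform equality tolerance for alignment checks: 1e−9 absolute on the
  affine coefficients.
* Constant layers: error at normalization (undefined rescale); constant
  PC1 surface: error at index rescale; fewer than 9 valid pixels: error at
  PCA fit. Rank-deficient but non-constant stacks succeed with zero
  eigenvalues.
* Determinism: no randomness anywhere in the analysis path; the only RNG
  is the seeded generator. Two runs of the CLI pipeline on the same inputs
  produce byte-identical rasters and tables.

## Problem sizes

Validation runs use 48–128-pixel-square synthetic scenes (2.3k–16k valid
pixels), five seeds for the gradient-recovery checks, 20 random stacks for
the PCA oracle comparison, and an 81-step temperature ladder over
250–330 K for the thermal round trip; these sizes make every property
measurable with comfortable statistical margin while keeping the full
suite under a few seconds.

## Known limitations

* The tasseled-cap default is a TM coefficient set; applying it to other
  sensors' bands is an approximation inherited from common practice with
  this index family.
* Winsorize-vs-discard for the 5–95 % rule is a documented interpretation;
  a discarding variant would shrink the valid area and change area tables.
* Whether reported per-year index means refer to the rescaled PC1 is
  convention; this package always means min-max-rescaled PC1 by "RSELI".
* Cross-year comparability relies on per-year normalization being
  approximately stationary; a joint multi-year normalization variant is
  deliberately out of scope.
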