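"""Cumulative threat index: eight 0-10 factor scores summed to 0-80.

The index adapts the terrestrial Human Footprint recipe: each anthropogenic
or climatic pressure layer is standardized to a 0-10 score, the eight scores
are summed per cell (range 0-80), urban cells are masked out, and the sum is
classified into four fixed-width bands (Low < 20, Moderate 20-40, High
40-60, Very high > 60).  Three parameter bundles — ``reference``,
``highest`` (stricter thresholds, more threat) and ``lowest`` (looser
thresholds, less threat) — drive a sensitivity analysis comparing the
resulting class maps cell by cell.

Factor scoring rules (reference scenario):

* population density: ``min(10, 10/log10(sat+1) * log10(density+1))`` with
  saturation 1,000 persons/km^2 — the coefficient is derived from the
  saturation so the score reaches exactly 10 there;
* cropland cover and tree-cover loss: 10 where the cell fraction >= 0.20;
* roads: 10 within a 20-km buffer of primary/secondary roads;
* overexploitation: 10 in provinces where licensed extraction exceeds the
  adequate harvest volume (scenario margin shifts the bar by +/-10%);
* burned-area trend: 10 on significant increasing-trend cells plus a 5-km
  buffer;
* temperature / precipitation change: ``min(10, |future - current|/sat * 10)``
  saturating at 2 degC and 200 mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grid import GridSpec, PolygonSet, RasterLayer, apply_urban_mask, buffer_mask, rasterize, rasterize_lines

logger = logging.getLogger(__name__)

__all__ = [
    "ThreatScenario",
    "SCENARIOS",
    "ThreatIndexMap",
    "CLASS_NAMES",
    "score_population",
    "score_threshold_layer",
    "score_roads",
    "score_overexploitation",
    "score_burn_trend",
    "score_climate_delta",
    "mean_future",
    "sum_index",
    "classify_index",
    "sensitivity_compare",
    "compute_threat_index",
]

FACTOR_NAMES = (
    "population",
    "cropland",
    "roads",
    "overexploitation",
    "tree_loss",
    "burn_trend",
    "temperature_change",
    "precipitation_change",
)

CLASS_NAMES = {1: "Low", 2: "Moderate", 3: "High", 4: "VeryHigh"}


@dataclass(frozen=True)
class ThreatScenario:
    """Parameter bundle for one index variant.

    ``overexploit_margin`` shifts the adequate-harvest bar: a province scores
    10 iff licensed > adequate * (1 + margin), so -0.10 flags more provinces
    (highest threat) and +0.10 fewer (lowest threat).
    """

    name: str
    pop_saturation: float  # persons/km^2 at which the population score hits 10
    crop_cutoff: float  # cropland fraction scoring 10
    road_buffer_km: float
    overexploit_margin: float
    treeloss_cutoff: float
    burn_buffer_km: float
    temp_saturation_C: float
    precip_saturation_mm: float


SCENARIOS: dict[str, ThreatScenario] = {
    "reference": ThreatScenario("reference", 1000.0, 0.20, 20.0, 0.0, 0.20, 5.0, 2.0, 200.0),
    "highest": ThreatScenario("highest", 800.0, 0.15, 25.0, -0.10, 0.15, 10.0, 1.5, 150.0),
    "lowest": ThreatScenario("lowest", 1200.0, 0.25, 15.0, +0.10, 0.25, 0.0, 2.5, 250.0),
}


@dataclass
class ThreatIndexMap:
    scenario: ThreatScenario
    layer_scores: dict[str, RasterLayer]
    index: RasterLayer
    classes: RasterLayer  # codes 1..4 per CLASS_NAMES, NaN where masked


# ---------------------------------------------------------------------------
# factor scorers
# ---------------------------------------------------------------------------


def score_population(density: RasterLayer, saturation: float = 1000.0) -> RasterLayer:
    """Logarithmic population-pressure score, exactly 10 at the saturation."""
    vals = density.values
    if np.nanmin(vals) < 0:
        raise ValueError("population density must be non-negative")
    coef = 10.0 / np.log10(saturation + 1.0)
    score = np.minimum(10.0, coef * np.log10(vals + 1.0))
    return RasterLayer(density.grid, score, name="population")


def score_threshold_layer(fraction: RasterLayer, cutoff: float, name: str = "threshold") -> RasterLayer:
    """10 where the cell fraction meets the cutoff (inclusive), else 0."""
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie strictly between 0 and 1")
    vals = fraction.values
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("fraction layer must lie in [0, 1]")
    score = np.where(np.isfinite(vals), np.where(vals >= cutoff, 10.0, 0.0), np.nan)
    return RasterLayer(fraction.grid, score, name=name)


def score_roads(roads: Sequence, grid: GridSpec, buffer_km: float) -> RasterLayer:
    """10 within ``buffer_km`` of a primary/secondary road, else 0."""
    if len(roads) == 0:
        import warnings

        warnings.warn("empty road set; road score is zero everywhere", stacklevel=2)
        return RasterLayer(grid, np.zeros(grid.shape), name="roads")
    burned = rasterize_lines(list(roads), grid)
    buffered = buffer_mask(burned, buffer_km * 1000.0)
    return RasterLayer(grid, buffered.values * 10.0, name="roads")


def score_overexploitation(
    provinces: PolygonSet,
    grid: GridSpec,
    margin: float = 0.0,
    licensed_attr: str = "licensed_volume",
    adequate_attr: str = "adequate_volume",
) -> RasterLayer:
    """10 across provinces whose licensed extraction exceeds the adequate bar.

    The bar is ``adequate * (1 + margin)``; the comparison is strict.
    """
    flagged = []
    for fid, geom, attrs in provinces:
        if licensed_attr not in attrs or adequate_attr not in attrs:
            raise KeyError(f"province {fid!r} lacks harvest volumes")
        licensed = float(attrs[licensed_attr])
        adequate = float(attrs[adequate_attr])
        if licensed < 0 or adequate < 0:
            raise ValueError(f"province {fid!r}: volumes must be non-negative")
        flagged.append((fid, geom, {"score": 10.0 if licensed > adequate * (1.0 + margin) else 0.0}))
    scored = rasterize(PolygonSet(flagged), grid, attribute="score")
    vals = np.where(np.isfinite(scored.values), scored.values, 0.0)  # cells outside provinces: no evidence
    return RasterLayer(grid, vals, name="overexploitation")


def score_burn_trend(trend: RasterLayer, buffer_km: float = 5.0) -> RasterLayer:
    """10 on significant increasing burned-area trend cells plus a buffer."""
    finite = trend.values[np.isfinite(trend.values)]
    if not np.all(np.isin(finite, (0.0, 1.0))):
        raise ValueError("burn trend must be a binary {0,1} layer")
    buffered = buffer_mask(trend, buffer_km * 1000.0) if buffer_km > 0 else trend.copy()
    return RasterLayer(trend.grid, buffered.values * 10.0, name="burn_trend")


def score_climate_delta(current: RasterLayer, future_mean: RasterLayer, saturation: float) -> RasterLayer:
    """Linear |future - current| score saturating at ``saturation`` units."""
    if current.grid != future_mean.grid:
        raise ValueError("current and future layers must share a grid")
    if saturation <= 0:
        raise ValueError("saturation must be positive")
    amplitude = future_mean.values - current.values
    score = np.minimum(10.0, np.abs(amplitude) / saturation * 10.0)
    return RasterLayer(current.grid, score, name="climate_delta")


def mean_future(layers: list[RasterLayer]) -> RasterLayer:
    """Cellwise mean of the supplied future-climate model layers."""
    if not layers:
        raise ValueError("mean_future requires at least one layer")
    grid = layers[0].grid
    for lay in layers[1:]:
        if lay.grid != grid:
            raise ValueError("future layers must share a grid")
    return RasterLayer(grid, np.mean([lay.values for lay in layers], axis=0), name="future_mean")


# ---------------------------------------------------------------------------
# index assembly
# ---------------------------------------------------------------------------


def sum_index(layer_scores: dict[str, RasterLayer], urban: RasterLayer) -> RasterLayer:
    """Sum the eight factor scores (0-80) and mask urban cells.

    A missing score in one layer contributes 0 to the cell's sum (the index
    is a sum over factors with coverage); per-layer missing counts are
    logged so gaps are visible.
    """
    if len(layer_scores) != 8:
        raise ValueError(f"expected exactly 8 factor layers, got {len(layer_scores)}")
    grid = urban.grid
    total = np.zeros(grid.shape)
    for name, lay in layer_scores.items():
        if lay.grid != grid:
            raise ValueError(f"factor layer {name!r} is on a different grid")
        finite = np.isfinite(lay.values)
        vals = lay.values[finite]
        if vals.size and (vals.min() < 0 or vals.max() > 10):
            raise ValueError(f"factor layer {name!r} has scores outside [0, 10]")
        n_missing = int((~finite).sum())
        if n_missing:
            logger.warning("sum_index: factor %r missing in %d cell(s); treated as 0", name, n_missing)
        total += np.where(finite, lay.values, 0.0)
    index = RasterLayer(grid, total, name="threat_index")
    return apply_urban_mask(index, urban)


def classify_index(index: RasterLayer) -> RasterLayer:
    """Four threat classes: Low [0,20), Moderate [20,40), High [40,60],
    VeryHigh (60,80].  The boundary at 60 belongs to High."""
    vals = index.values
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 80):
        raise ValueError("index values must lie in [0, 80]")
    out = np.full(index.grid.shape, np.nan)
    fin = np.isfinite(vals)
    out[fin & (vals < 20)] = 1
    out[fin & (vals >= 20) & (vals < 40)] = 2
    out[fin & (vals >= 40) & (vals <= 60)] = 3
    out[fin & (vals > 60)] = 4
    return RasterLayer(index.grid, out, name="threat_classes")


def sensitivity_compare(reference: RasterLayer, alternate: RasterLayer) -> tuple[float, float, float]:
    """(changed%, increased%, decreased%) between two class maps.

    Percentages are over cells non-missing in both maps; changed =
    increased + decreased.
    """
    if reference.grid != alternate.grid:
        raise ValueError("class maps must share a grid")
    both = np.isfinite(reference.values) & np.isfinite(alternate.values)
    n = int(both.sum())
    if n == 0:
        raise ValueError("no cells defined in both maps")
    ref = reference.values[both]
    alt = alternate.values[both]
    increased = float((alt > ref).sum()) / n * 100.0
    decreased = float((alt < ref).sum()) / n * 100.0
    return increased + decreased, increased, decreased


def compute_threat_index(
    scenario: ThreatScenario,
    density: RasterLayer,
    cropland: RasterLayer,
    roads: Sequence,
    provinces: PolygonSet,
    tree_loss: RasterLayer,
    burn_trend: RasterLayer,
    temp_current: RasterLayer,
    temp_future: list[RasterLayer],
    precip_current: RasterLayer,
    precip_future: list[RasterLayer],
    urban: RasterLayer,
) -> ThreatIndexMap:
    """Score all eight factors under a scenario and assemble the class map."""
    grid = density.grid
    scores = {
        "population": score_population(density, scenario.pop_saturation),
        "cropland": score_threshold_layer(cropland, scenario.crop_cutoff, name="cropland"),
        "roads": score_roads(roads, grid, scenario.road_buffer_km),
        "overexploitation": score_overexploitation(provinces, grid, scenario.overexploit_margin),
        "tree_loss": score_threshold_layer(tree_loss, scenario.treeloss_cutoff, name="tree_loss"),
        "burn_trend": score_burn_trend(burn_trend, scenario.burn_buffer_km),
        "temperature_change": score_climate_delta(
            temp_current, mean_future(temp_future), scenario.temp_saturation_C
        ),
        "precipitation_change": score_climate_delta(
            precip_current, mean_future(precip_future), scenario.precip_saturation_mm
        ),
    }
    index = sum_index(scores, urban)
    classes = classify_index(index)
    return ThreatIndexMap(scenario=scenario, layer_scores=scores, index=index, classes=classes)
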