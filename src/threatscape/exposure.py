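"""Species richness, threat exposure and protected-area coverage overlays."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec, PolygonSet, RasterLayer, rasterize
from .sdm import BinarySuitabilityMap
from .threat import CLASS_NAMES

__all__ = ["ExposureSummary", "richness_map", "exposure_summary", "pa_class_profile"]


@dataclass
class ExposureSummary:
    """Per-species suitable area split by threat class, plus PA coverage.

    Suitable cells whose threat class is missing (e.g. urban-masked) are
    counted in ``total_suitable_km2`` and reported under the explicit
    ``unclassified`` bucket so the area partition stays checkable.
    """

    species: str
    total_suitable_km2: float
    area_by_class: dict[str, float]
    fraction_by_class: dict[str, float]
    protected_km2: float
    protected_fraction: float

    def __post_init__(self) -> None:
        tot = sum(self.area_by_class.values())
        if abs(tot - self.total_suitable_km2) > 1e-6 * max(self.total_suitable_km2, 1.0):
            raise ValueError("area_by_class must partition the total suitable area")
        if not (0.0 <= self.protected_fraction <= 1.0):
            raise ValueError("protected_fraction must lie in [0, 1]")

    def to_row(self) -> dict:
        row = {"species": self.species, "total_km2": self.total_suitable_km2}
        for name in list(CLASS_NAMES.values()) + ["unclassified"]:
            row[f"km2_{name.lower()}"] = self.area_by_class.get(name, 0.0)
        row["pct_protected"] = 100.0 * self.protected_fraction
        return row


def richness_map(binaries: list[BinarySuitabilityMap]) -> RasterLayer:
    """Cellwise number of species predicted present (sum of binary maps).

    Missing only where every input is missing; a species' missing cell
    contributes 0 elsewhere.
    """
    if not binaries:
        raise ValueError("richness_map requires at least one binary map")
    grid = binaries[0].map.grid
    stack = []
    for b in binaries:
        if b.map.grid != grid:
            raise ValueError("binary maps must share a grid")
        stack.append(b.map.values)
    arr = np.stack(stack)
    any_defined = np.any(np.isfinite(arr), axis=0)
    total = np.nansum(arr, axis=0)
    return RasterLayer(grid, np.where(any_defined, total, np.nan), name="richness")


def exposure_summary(
    binary: BinarySuitabilityMap,
    classes: RasterLayer,
    pas: PolygonSet,
    grid: GridSpec | None = None,
) -> ExposureSummary:
    """Suitable area (km^2) by threat class and protected-area coverage.

    Areas are cell counts times the grid cell area; PA membership is by
    cell-center containment.
    """
    grid = grid or binary.map.grid
    if classes.grid != grid:
        raise ValueError("class map must share the binary map's grid")
    suitable = binary.map.values == 1.0
    n_suit = int(suitable.sum())
    if n_suit == 0:
        raise ValueError(f"species {binary.species!r} has no suitable cells")
    cell_km2 = grid.cell_area_km2
    area_by_class: dict[str, float] = {}
    cls_vals = classes.values
    for code, cname in CLASS_NAMES.items():
        area_by_class[cname] = float((suitable & (cls_vals == code)).sum()) * cell_km2
    area_by_class["unclassified"] = float((suitable & ~np.isfinite(cls_vals)).sum()) * cell_km2
    total = n_suit * cell_km2
    fraction_by_class = {k: v / total for k, v in area_by_class.items()}
    pa_mask = rasterize(pas, grid).values == 1.0 if len(pas) else np.zeros(grid.shape, dtype=bool)
    protected = float((suitable & pa_mask).sum()) * cell_km2
    return ExposureSummary(
        species=binary.species,
        total_suitable_km2=total,
        area_by_class=area_by_class,
        fraction_by_class=fraction_by_class,
        protected_km2=protected,
        protected_fraction=protected / total,
    )


def pa_class_profile(classes: RasterLayer, pas: PolygonSet) -> dict[str, float]:
    """Distribution of threat classes over protected-area cells (sums to 1)."""
    pa_mask = rasterize(pas, classes.grid).values == 1.0
    defined = pa_mask & np.isfinite(classes.values)
    n = int(defined.sum())
    if n == 0:
        raise ValueError("no classified protected-area cells")
    out = {}
    for code, cname in CLASS_NAMES.items():
        out[cname] = float((defined & (classes.values == code)).sum()) / n
    return out


def summaries_table(summaries: list[ExposureSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])
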