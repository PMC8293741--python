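"""Predictor assembly, bioclim pre-screening and VIF-based selection.

Two screens reduce the candidate predictor stack before model fitting:

1. an importance pre-screen keeping the top-k temperature-related and top-k
   precipitation-related bioclimatic variables (non-bioclim predictors pass
   through untouched), and
2. iterative variance-inflation-factor elimination — repeatedly drop the
   predictor with the highest VIF until every remaining VIF is below the
   threshold (default 10).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import RasterLayer
from .occurrences import OccurrenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorTable",
    "VifReport",
    "prescreen_bioclim",
    "vif",
    "vif_select",
    "extract_at_points",
]

_BIO_RE = re.compile(r"^BIO(\d+)$", re.IGNORECASE)


def _name_order_key(name: str):
    """Canonical variable ordering: BIO1..BIO19 numerically, then others by name."""
    m = _BIO_RE.match(name)
    if m:
        return (0, int(m.group(1)), name)
    return (1, 0, name)


@dataclass
class PredictorTable:
    """Per-sample predictor values plus a variable-class map.

    ``data`` holds one row per sample cell and one column per predictor;
    ``var_class`` tags each column as temperature / precipitation / other
    for the bioclim pre-screen.
    """

    data: pd.DataFrame
    var_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("predictor table must not contain missing values")
        for col in self.data.columns:
            self.var_class.setdefault(col, "other")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, names: list[str]) -> "PredictorTable":
        return PredictorTable(self.data[names].copy(), {n: self.var_class[n] for n in names})


@dataclass
class VifReport:
    steps: list[tuple[str, float]]
    retained: list[str]
    final_vifs: dict[str, float]
    threshold: float

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.final_vifs.items() if v >= self.threshold}
        if bad:
            raise ValueError(f"final VIFs not below threshold: {bad}")


def prescreen_bioclim(
    importances: dict[str, float],
    var_class: dict[str, str],
    k_temp: int = 3,
    k_precip: int = 3,
) -> list[str]:
    """Keep the top-k temperature and precipitation variables by importance.

    Ties break by canonical variable-name order (BIO1..BIO19).  Variables of
    class ``other`` are untouched by the screen and always returned.
    """
    selected: list[str] = []
    for cls, k in (("temperature", k_temp), ("precipitation", k_precip)):
        members = [n for n in importances if var_class.get(n) == cls]
        if len(members) < k:
            warnings.warn(
                f"only {len(members)} {cls} variable(s) available (< {k}); keeping all",
                stacklevel=2,
            )
            k = len(members)
        ranked = sorted(members, key=lambda n: (-importances[n], _name_order_key(n)))
        selected.extend(ranked[:k])
    selected.extend(n for n in importances if var_class.get(n) not in ("temperature", "precipitation"))
    return sorted(set(selected), key=_name_order_key)


def vif(table: PredictorTable, target: str) -> float:
    """Variance inflation factor of ``target`` against the other columns.

    VIF = 1/(1-R^2) from the least-squares regression of the target on all
    remaining predictors with an intercept; +inf on perfect collinearity.
    """
    others = [c for c in table.columns if c != target]
    if not others:
        raise ValueError("vif requires at least two columns")
    y = table.data[target].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"target column {target!r} is constant; R^2 undefined")
    X = np.column_stack([np.ones(len(y))] + [table.data[c].to_numpy(dtype=float) for c in others])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def vif_select(table: PredictorTable, threshold: float = 10.0) -> VifReport:
    """Iteratively drop the max-VIF predictor until all VIFs < threshold.

    Ties break by canonical name order, making the outcome invariant to the
    column order of the input table.
    """
    current = list(table.columns)
    steps: list[tuple[str, float]] = []
    while len(current) >= 2:
        sub = table.subset(current)
        vifs = {c: vif(sub, c) for c in current}
        worst = max(sorted(vifs, key=_name_order_key), key=lambda c: vifs[c])
        if vifs[worst] < threshold:
            break
        steps.append((worst, vifs[worst]))
        current.remove(worst)
    if len(current) >= 2:
        final = {c: vif(table.subset(current), c) for c in current}
    else:
        final = {c: 1.0 for c in current}
    return VifReport(steps=steps, retained=current, final_vifs=final, threshold=threshold)


def extract_at_points(
    layers: list[RasterLayer],
    points: OccurrenceSet | list[tuple[int, int]],
    var_class: dict[str, str] | None = None,
) -> PredictorTable:
    """Build a predictor table by sampling each layer at point/cell locations.

    ``points`` is either an :class:`OccurrenceSet` (sampled at record
    coordinates) or a list of (row, col) cell indices.  Rows touching any
    missing layer value are dropped (count logged); dropping every row is an
    error.
    """
    grid = layers[0].grid
    for lay in layers[1:]:
        if lay.grid != grid:
            raise ValueError("all layers must share one grid")
    if isinstance(points, OccurrenceSet):
        xs = np.array([r.x for r in points.records])
        ys = np.array([r.y for r in points.records])
        rows, cols = grid.cell_of(xs, ys)
    else:
        rows = np.array([p[0] for p in points], dtype=int)
        cols = np.array([p[1] for p in points], dtype=int)
    data = {lay.name: lay.values[rows, cols] for lay in layers}
    df = pd.DataFrame(data)
    n0 = len(df)
    df = df.dropna().reset_index(drop=True)
    if len(df) < n0:
        logger.info("extract_at_points: dropped %d row(s) with missing values", n0 - len(df))
    if df.empty:
        raise ValueError("all rows fell in missing cells")
    return PredictorTable(df, dict(var_class or {}))
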