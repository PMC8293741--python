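"""Synthetic study system: environment, virtual species and threat inputs.

Everything the pipeline consumes can be generated here with known ground
truth: spatially autocorrelated predictor fields, a virtual species whose
occurrence probability follows a logistic Gaussian-niche response to chosen
predictors, and the eight threat-factor inputs (clustered population
density, random road polylines, fractional cropland / tree-loss fields, a
burned-area-trend mask, provinces with harvest volumes, climate-change
amplitude fields, and urban blobs).

The generator plays the role the real national datasets play in the study
design: its defaults (100 x 100 grid of 5-km cells, 150 presences, two true
niche variables, strong niche signal) are the conditions under which the
pipeline's recovery properties are asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import LineString, box

from .grid import GridSpec, PolygonSet, RasterLayer
from .occurrences import OccurrenceRecord, OccurrenceSet

__all__ = ["SyntheticConfig", "TruthBundle", "gen_env_layers", "gen_species", "gen_threat_factors"]


@dataclass
class SyntheticConfig:
    grid: GridSpec = field(default_factory=lambda: GridSpec(100, 100, 0.0, 500000.0, 5000.0))
    seed: int = 0
    n_env_layers: int = 6
    autocorr_range_cells: float = 8.0
    n_collinear_pairs: int = 0  # appended layers env{k}_colin = env{k} + small noise
    niche: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"env01": (0.8, 0.7), "env02": (-0.5, 0.7)}
    )
    target_prevalence: float = 0.15
    n_presences: int = 150
    sampling_bias: str = "none"  # or "road-biased"
    town_count: int = 8
    road_count: int = 5
    n_provinces: int = 6
    climate_delta_scale: tuple[float, float] = (2.0, 200.0)  # degC, mm

    def __post_init__(self) -> None:
        if self.n_presences < 1:
            raise ValueError("n_presences must be >= 1")
        for name, (_, breadth) in self.niche.items():
            if breadth <= 0:
                raise ValueError(f"niche breadth for {name!r} must be positive")


@dataclass
class TruthBundle:
    """Generating parameters, kept for recovery tests."""

    probability_map: RasterLayer | None = None
    niche_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    intercept: float = 0.0
    factor_truth: dict = field(default_factory=dict)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], range_cells: float) -> np.ndarray:
    """Standardized moving-average (Gaussian-kernel) random field."""
    noise = rng.standard_normal(shape)
    if range_cells > 0:
        fieldv = ndimage.gaussian_filter(noise, sigma=range_cells, mode="reflect")
    else:
        fieldv = noise
    return (fieldv - fieldv.mean()) / fieldv.std()


def gen_env_layers(cfg: SyntheticConfig) -> tuple[list[RasterLayer], TruthBundle]:
    """Autocorrelated, standardized predictor layers (plus collinear pairs)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    layers = []
    for i in range(1, cfg.n_env_layers + 1):
        vals = _smooth_field(rng, cfg.grid.shape, cfg.autocorr_range_cells)
        layers.append(RasterLayer(cfg.grid, vals, name=f"env{i:02d}"))
    for k in range(1, cfg.n_collinear_pairs + 1):
        base = layers[k - 1]
        vals = base.values + 0.05 * rng.standard_normal(cfg.grid.shape)
        layers.append(RasterLayer(cfg.grid, vals, name=f"{base.name}_colin"))
    return layers, TruthBundle(niche_params=dict(cfg.niche))


def _niche_logit(cfg: SyntheticConfig, layers: dict[str, RasterLayer]) -> np.ndarray:
    logit = np.zeros(cfg.grid.shape)
    for name, (opt, breadth) in cfg.niche.items():
        if name not in layers:
            raise KeyError(f"niche variable {name!r} not among environment layers")
        x = layers[name].values
        logit -= (x - opt) ** 2 / (2.0 * breadth**2)
    return logit


def gen_species(
    cfg: SyntheticConfig,
    env: list[RasterLayer],
    species: str = "SYNTH",
    bias_layer: RasterLayer | None = None,
) -> tuple[OccurrenceSet, TruthBundle]:
    """Virtual species: logistic Gaussian-niche probability + sampled presences.

    The intercept is calibrated by bisection so the mean occurrence
    probability equals ``target_prevalence``; presence cells are drawn
    without replacement with probability proportional to the true occurrence
    probability (optionally times a collection-bias weight), and each record
    is placed uniformly inside its cell.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    by_name = {lay.name: lay for lay in env}
    raw_logit = _niche_logit(cfg, by_name)

    def prevalence(intercept: float) -> float:
        return float((1.0 / (1.0 + np.exp(-(raw_logit + intercept)))).mean())

    lo, hi = -30.0, 30.0
    if not (prevalence(lo) <= cfg.target_prevalence <= prevalence(hi)):
        raise ValueError(f"target prevalence {cfg.target_prevalence} unreachable")
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if prevalence(mid) < cfg.target_prevalence:
            lo = mid
        else:
            hi = mid
    intercept = (lo + hi) / 2.0
    prob = 1.0 / (1.0 + np.exp(-(raw_logit + intercept)))

    weight = prob.ravel().copy()
    if cfg.sampling_bias == "road-biased":
        if bias_layer is None:
            raise ValueError("road-biased sampling requires a bias layer")
        weight *= np.clip(bias_layer.values.ravel(), 0.0, None)
    if cfg.n_presences > np.count_nonzero(weight):
        raise ValueError("not enough cells with positive sampling weight")
    chosen = rng.choice(weight.size, size=cfg.n_presences, replace=False, p=weight / weight.sum())
    grid = cfg.grid
    records = []
    for flat in np.sort(chosen):
        row, col = int(flat // grid.n_cols), int(flat % grid.n_cols)
        cx, cy = grid.center_of(row, col)
        dx, dy = (rng.random(2) - 0.5) * grid.cell_size
        records.append(OccurrenceRecord(species=species, x=float(cx + dx), y=float(cy + dy), source_id=f"synth{flat}"))
    occ = OccurrenceSet(species, records, grid)
    truth = TruthBundle(
        probability_map=RasterLayer(grid, prob, name=f"{species}:truth"),
        niche_params=dict(cfg.niche),
        intercept=intercept,
    )
    return occ, truth


def _province_polygons(grid: GridSpec, labels: np.ndarray, n_provinces: int) -> list:
    xe, ye = grid.x_edges(), grid.y_edges()
    polys = []
    for p in range(n_provinces):
        rows, cols = np.nonzero(labels == p)
        boxes = [box(xe[c], ye[r + 1], xe[c + 1], ye[r]) for r, c in zip(rows, cols)]
        polys.append(shapely.union_all(boxes))
    return polys


def gen_threat_factors(cfg: SyntheticConfig, grid: GridSpec | None = None) -> dict:
    """All eight threat-factor inputs plus urban mask, with known truth.

    Returns a dict with keys: density, cropland, tree_loss, burn_trend,
    temp_current, temp_future, precip_current, precip_future, urban, roads,
    provinces, pas, harvest (DataFrame), truth.
    """
    grid = grid or cfg.grid
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303]))
    rr, cc = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]

    # population: exponential-decay kernels around random town centers
    density = np.zeros(grid.shape)
    towns = []
    for _ in range(cfg.town_count):
        tr, tc = rng.integers(0, grid.n_rows), rng.integers(0, grid.n_cols)
        peak = rng.uniform(300.0, 1500.0)
        scale = rng.uniform(2.0, 5.0)  # cells
        d = np.hypot(rr - tr, cc - tc)
        density += peak * np.exp(-d / scale)
        towns.append((int(tr), int(tc), float(peak)))
    density_layer = RasterLayer(grid, density, name="population_density")

    # fractional cover layers in [0, 1]
    def frac_layer(tag: int, name: str) -> RasterLayer:
        f = _smooth_field(np.random.default_rng(np.random.SeedSequence([cfg.seed, 303, tag])), grid.shape, 4.0)
        f = (f - f.min()) / (f.max() - f.min())
        return RasterLayer(grid, f, name=name)

    cropland = frac_layer(1, "cropland_fraction")
    tree_loss = frac_layer(2, "tree_loss_fraction")

    # burned-area trend: blobs where a smooth field is in its upper tail
    burn_field = _smooth_field(rng, grid.shape, 5.0)
    burn_trend = RasterLayer(grid, (burn_field > np.quantile(burn_field, 0.85)).astype(float), name="burn_trend")

    # roads: straight polylines between random points on opposite grid edges
    x0, y0 = grid.origin_x, grid.origin_y
    w, h = grid.n_cols * grid.cell_size, grid.n_rows * grid.cell_size
    roads = []
    for _ in range(cfg.road_count):
        if rng.random() < 0.5:
            p1 = (x0, y0 - rng.uniform(0, h))
            p2 = (x0 + w, y0 - rng.uniform(0, h))
        else:
            p1 = (x0 + rng.uniform(0, w), y0)
            p2 = (x0 + rng.uniform(0, w), y0 - h)
        roads.append(LineString([p1, p2]))

    # provinces: nearest-seed partition of the grid, with harvest volumes
    seeds_rc = np.column_stack(
        [rng.integers(0, grid.n_rows, cfg.n_provinces), rng.integers(0, grid.n_cols, cfg.n_provinces)]
    )
    d2 = (rr[..., None] - seeds_rc[:, 0]) ** 2 + (cc[..., None] - seeds_rc[:, 1]) ** 2
    labels = np.argmin(d2, axis=-1)
    polys = _province_polygons(grid, labels, cfg.n_provinces)
    harvest_rows = []
    feats = []
    for p, poly in enumerate(polys):
        adequate = float(rng.uniform(80.0, 120.0))
        licensed = float(adequate * rng.uniform(0.6, 1.4))
        name = f"province_{p}"
        feats.append((name, poly, {"licensed_volume": licensed, "adequate_volume": adequate}))
        harvest_rows.append({"province": name, "licensed_volume": licensed, "adequate_volume": adequate})
    provinces = PolygonSet(feats)
    harvest = pd.DataFrame(harvest_rows)

    # climate: current fields plus per-model future layers with smooth deltas
    dT, dP = cfg.climate_delta_scale
    temp_current = RasterLayer(grid, 20.0 + 3.0 * _smooth_field(rng, grid.shape, 10.0), name="temp_current")
    precip_current = RasterLayer(grid, 1000.0 + 250.0 * _smooth_field(rng, grid.shape, 10.0), name="precip_current")
    # climate models share one broad change pattern (scaled so the multi-model
    # mean amplitude exceeds the saturation somewhere) plus small disagreements
    base_dt = _smooth_field(rng, grid.shape, 8.0)
    base_dt = base_dt / np.abs(base_dt).max() * dT * 1.2
    base_dp = _smooth_field(rng, grid.shape, 8.0)
    base_dp = base_dp / np.abs(base_dp).max() * dP * 1.2
    temp_future, precip_future = [], []
    for m in range(3):
        jitter_t = 0.1 * dT * _smooth_field(rng, grid.shape, 8.0)
        temp_future.append(RasterLayer(grid, temp_current.values + base_dt + jitter_t, name=f"temp_future_m{m}"))
        jitter_p = 0.1 * dP * _smooth_field(rng, grid.shape, 8.0)
        precip_future.append(RasterLayer(grid, precip_current.values + base_dp + jitter_p, name=f"precip_future_m{m}"))

    # protected areas: a few random rectangles away from grid edges
    pa_feats = []
    for k in range(4):
        pr = rng.integers(5, grid.n_rows - 25)
        pc = rng.integers(5, grid.n_cols - 25)
        hgt = int(rng.integers(8, 20))
        wid = int(rng.integers(8, 20))
        xe, ye = grid.x_edges(), grid.y_edges()
        pa_feats.append(
            (f"pa_{k}", box(xe[pc], ye[pr + hgt], xe[pc + wid], ye[pr]), {"name": f"PA {k}"})
        )
    pas = PolygonSet(pa_feats)

    # urban: one-cell-radius blobs at the densest town centers
    urban = np.zeros(grid.shape)
    for tr, tc, peak in towns:
        if peak > 600.0:
            d = np.hypot(rr - tr, cc - tc)
            urban[d <= 1.0] = 1.0
    urban_layer = RasterLayer(grid, urban, name="urban")

    return {
        "density": density_layer,
        "cropland": cropland,
        "tree_loss": tree_loss,
        "burn_trend": burn_trend,
        "roads": roads,
        "provinces": provinces,
        "pas": pas,
        "harvest": harvest,
        "temp_current": temp_current,
        "temp_future": temp_future,
        "precip_current": precip_current,
        "precip_future": precip_future,
        "urban": urban_layer,
        "truth": {"towns": towns, "labels": labels, "climate_delta_scale": cfg.climate_delta_scale},
    }
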