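"""End-to-end orchestration: fixtures -> prep -> sdm -> threat -> exposure.

A single YAML config drives the run; every stage writes its outputs under
the configured output directory and records a content hash, so unchanged
reruns are cache hits.  The :class:`RunManifest` (written atomically at run
end) captures the config hash, master seed, per-stage timings and output
checksums for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

from . import __version__
from .exposure import exposure_summary, pa_class_profile, richness_map, summaries_table
from .grid import (
    GridSpec,
    PolygonSet,
    RasterLayer,
    read_ascii_grid,
    read_geojson,
    write_ascii_grid,
    write_geojson,
)
from .occurrences import OccurrenceSet, deduplicate, filter_uncertainty, read_occurrences_csv, spatial_thin, write_occurrences_csv
from .sdm import BinarySuitabilityMap, EnsembleSDM, default_learners, random_forest_adapter
from .threat import SCENARIOS, compute_threat_index, sensitivity_compare
from .synthetic import SyntheticConfig, gen_env_layers, gen_species, gen_threat_factors

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "load_grid_yaml"]

STAGES = ("fixtures", "prep", "sdm", "threat", "exposure")


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    versions: str
    stage_timings: dict[str, float] = field(default_factory=dict)
    stage_status: dict[str, str] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))
        os.replace(tmp, path)


def load_grid_yaml(path: str | Path) -> GridSpec:
    cfg = yaml.safe_load(Path(path).read_text())
    return _grid_from_cfg(cfg["grid"] if "grid" in cfg else cfg)


def _grid_from_cfg(g: dict) -> GridSpec:
    return GridSpec(
        n_rows=int(g["n_rows"]),
        n_cols=int(g["n_cols"]),
        origin_x=float(g.get("origin_x", 0.0)),
        origin_y=float(g.get("origin_y", 0.0)),
        cell_size=float(g.get("cell_size", 5000.0)),
        crs_id=str(g.get("crs_id", "local-equal-area")),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_lines_geojson(lines, path: Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"id": i}, "geometry": geom_mapping(ln)}
            for i, ln in enumerate(lines)
        ],
    }
    path.write_text(json.dumps(fc))


def _read_lines_geojson(path: Path) -> list:
    fc = json.loads(path.read_text())
    return [geom_shape(f["geometry"]) for f in fc["features"]]


def _stage_done(outdir: Path, stage: str, key: str) -> bool:
    done = outdir / f".{stage}.done.json"
    if not done.exists():
        return False
    try:
        info = json.loads(done.read_text())
    except json.JSONDecodeError:
        return False
    return info.get("key") == key and all(Path(p).exists() for p in info.get("outputs", []))


def _mark_done(outdir: Path, stage: str, key: str, outputs: list[Path]) -> None:
    (outdir / f".{stage}.done.json").write_text(
        json.dumps({"key": key, "outputs": [str(p) for p in outputs]})
    )


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Run the configured stages in order and return the manifest.

    The config either carries a ``synth`` section (all inputs generated) or
    an ``inputs`` section with file paths.  Stage outputs are cached by a
    key derived from the config hash: rerunning an unchanged config skips
    completed stages.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    _validate_config(cfg)
    outdir = Path(cfg.get("outdir", "threatscape_out"))
    if not outdir.is_absolute():
        outdir = config_path.parent / outdir
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    config_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest = RunManifest(config_hash=config_hash, master_seed=seed, versions=f"threatscape {__version__}")

    stages = cfg.get("stages", ["prep", "sdm", "threat", "exposure"])
    if "synth" in cfg and "fixtures" not in stages:
        stages = ["fixtures"] + list(stages)

    stage = "<none>"
    try:
        for stage in stages:
            key = f"{config_hash}:{stage}"
            t0 = time.perf_counter()
            if _stage_done(outdir, stage, key):
                manifest.stage_status[stage] = "cached"
                manifest.stage_timings[stage] = 0.0
                continue
            outputs = _STAGE_FNS[stage](cfg, outdir, seed)
            _mark_done(outdir, stage, key, outputs)
            manifest.stage_status[stage] = "completed"
            manifest.stage_timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        manifest.stage_status[stage] = f"failed: {exc}"
        manifest.write(outdir / "manifest.json")
        raise
    for name in ("occurrences",):
        p = cfg.get("inputs", {}).get(name)
        if p and Path(p).exists():
            manifest.input_checksums[str(p)] = _sha256(Path(p))
    for p in sorted(outdir.glob("**/*")):
        if p.is_file() and not p.name.startswith(".") and p.name != "manifest.json":
            manifest.input_checksums[str(p.relative_to(outdir))] = _sha256(p)
    manifest.write(outdir / "manifest.json")
    return manifest


def _validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    if "synth" not in cfg and "inputs" not in cfg:
        raise ValueError("config needs a 'synth' or an 'inputs' section")
    known = {"seed", "outdir", "stages", "synth", "inputs", "grid", "sdm", "threat", "exposure"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    for stage in cfg.get("stages", []):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; valid stages: {STAGES}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _synth_cfg(cfg: dict, seed: int) -> SyntheticConfig:
    s = dict(cfg.get("synth") or {})
    if "grid" in cfg:
        s["grid"] = _grid_from_cfg(cfg["grid"])
    if "niche" in s:
        s["niche"] = {k: tuple(v) for k, v in s["niche"].items()}
    if "climate_delta_scale" in s:
        s["climate_delta_scale"] = tuple(s["climate_delta_scale"])
    s.setdefault("seed", seed)
    return SyntheticConfig(**s)


def _stage_fixtures(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    scfg = _synth_cfg(cfg, seed)
    fdir = outdir / "fixtures"
    fdir.mkdir(exist_ok=True)
    env, _ = gen_env_layers(scfg)
    occ, truth = gen_species(scfg, env)
    factors = gen_threat_factors(scfg)
    outputs = []
    for lay in env:
        p = fdir / f"{lay.name}.asc"
        write_ascii_grid(lay, p)
        outputs.append(p)
    p = fdir / "occurrences.csv"
    write_occurrences_csv([occ], p)
    outputs.append(p)
    for name in ("density", "cropland", "tree_loss", "burn_trend", "temp_current", "precip_current", "urban"):
        p = fdir / f"{name}.asc"
        write_ascii_grid(factors[name], p)
        outputs.append(p)
    for name in ("temp_future", "precip_future"):
        for lay in factors[name]:
            p = fdir / f"{lay.name}.asc"
            write_ascii_grid(lay, p)
            outputs.append(p)
    write_geojson(factors["provinces"], fdir / "provinces.geojson")
    write_geojson(factors["pas"], fdir / "pas.geojson")
    _write_lines_geojson(factors["roads"], fdir / "roads.geojson")
    factors["harvest"].to_csv(fdir / "harvest.csv", index=False)
    p = fdir / "truth.json"
    p.write_text(
        json.dumps(
            {
                "niche": {k: list(v) for k, v in truth.niche_params.items()},
                "intercept": truth.intercept,
                "prevalence_target": scfg.target_prevalence,
            }
        )
    )
    tp = fdir / "truth_probability.asc"
    write_ascii_grid(truth.probability_map, tp)
    outputs += [fdir / "provinces.geojson", fdir / "pas.geojson", fdir / "roads.geojson", fdir / "harvest.csv", p, tp]
    return outputs


def _resolve_inputs(cfg: dict, outdir: Path) -> dict:
    """Paths to stage inputs: explicit in config, else the fixtures dir."""
    if "inputs" in cfg:
        return dict(cfg["inputs"])
    fdir = outdir / "fixtures"
    return {
        "occurrences": fdir / "occurrences.csv",
        "species": [ "SYNTH" ],
        "predictors": sorted(str(p) for p in fdir.glob("env*.asc")),
        "density": fdir / "density.asc",
        "cropland": fdir / "cropland.asc",
        "tree_loss": fdir / "tree_loss.asc",
        "burn_trend": fdir / "burn_trend.asc",
        "temp_current": fdir / "temp_current.asc",
        "temp_future": sorted(str(p) for p in fdir.glob("temp_future_*.asc")),
        "precip_current": fdir / "precip_current.asc",
        "precip_future": sorted(str(p) for p in fdir.glob("precip_future_*.asc")),
        "urban": fdir / "urban.asc",
        "roads": fdir / "roads.geojson",
        "provinces": fdir / "provinces.geojson",
        "pas": fdir / "pas.geojson",
        "grid": {"from_raster": str(fdir / "density.asc")},
    }


def _grid_of(inputs: dict, cfg: dict) -> GridSpec:
    if "grid" in cfg:
        return _grid_from_cfg(cfg["grid"])
    g = inputs.get("grid")
    if isinstance(g, dict) and "from_raster" in g:
        return read_ascii_grid(g["from_raster"]).grid
    return _grid_from_cfg(g)


def _stage_prep(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    inputs = _resolve_inputs(cfg, outdir)
    grid = _grid_of(inputs, cfg)
    sets = []
    for sp in inputs["species"]:
        occ = read_occurrences_csv(inputs["occurrences"], sp, grid)
        recs = filter_uncertainty(deduplicate(occ.records))
        thinned = spatial_thin(OccurrenceSet(sp, recs, grid))
        logger.info("prep %s: %d -> %d records", sp, len(occ), len(thinned))
        sets.append(thinned)
    p = outdir / "occurrences_thinned.csv"
    write_occurrences_csv(sets, p)
    return [p]


def _learners_from_cfg(sdm_cfg: dict):
    names = sdm_cfg.get("learners", ["GLM", "GBM"])
    fast = bool(sdm_cfg.get("fast", False))
    base = {l.name: l for l in default_learners(fast=fast)}
    base["RF"] = random_forest_adapter(30 if fast else 100)
    return [base[n] for n in names]


def _stage_sdm(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    inputs = _resolve_inputs(cfg, outdir)
    grid = _grid_of(inputs, cfg)
    sdm_cfg = dict(cfg.get("sdm") or {})
    layers = [read_ascii_grid(p) for p in inputs["predictors"]]
    outputs = []
    for sp in inputs["species"]:
        occ = read_occurrences_csv(outdir / "occurrences_thinned.csv", sp, grid)
        model = EnsembleSDM(
            occ,
            layers,
            learners=_learners_from_cfg(sdm_cfg),
            n_pa_sets=int(sdm_cfg.get("n_pa_sets", 3)),
            auc_gate=float(sdm_cfg.get("auc_gate", 0.7)),
            min_presences=int(sdm_cfg.get("min_presences", 15)),
            n_perm=int(sdm_cfg.get("n_perm", 10)),
        )
        res = model.fit(n_replicates=int(sdm_cfg.get("n_replicates", 100)), seed=seed)
        binary = res.binarize()
        sdir = outdir / "sdm" / sp
        sdir.mkdir(parents=True, exist_ok=True)
        write_ascii_grid(res.mean_map, sdir / "suitability.asc")
        write_ascii_grid(binary.map, sdir / "binary.asc")
        res.runs_table().to_csv(sdir / "runs.csv", index=False)
        res.importance_table().to_csv(sdir / "importance.csv", index=False)
        (sdir / "metrics.json").write_text(
            json.dumps(
                {
                    "species": sp,
                    "ensemble_auc": res.auc_,
                    "ensemble_tss": res.tss_,
                    "binary_threshold": binary.threshold,
                    "n_member_runs": len(res.ensemble.member_runs),
                    "n_runs": len(res.runs),
                }
            )
        )
        (sdir / "summary.txt").write_text(res.summary() + "\n")
        outputs += [sdir / "suitability.asc", sdir / "binary.asc", sdir / "runs.csv",
                    sdir / "importance.csv", sdir / "metrics.json", sdir / "summary.txt"]
    return outputs


def _stage_threat(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    inputs = _resolve_inputs(cfg, outdir)
    tcfg = dict(cfg.get("threat") or {})
    scenario_names = tcfg.get("scenarios", ["reference", "highest", "lowest"])
    density = read_ascii_grid(inputs["density"])
    cropland = read_ascii_grid(inputs["cropland"])
    tree_loss = read_ascii_grid(inputs["tree_loss"])
    burn = read_ascii_grid(inputs["burn_trend"])
    temp_c = read_ascii_grid(inputs["temp_current"])
    temp_f = [read_ascii_grid(p) for p in inputs["temp_future"]]
    prec_c = read_ascii_grid(inputs["precip_current"])
    prec_f = [read_ascii_grid(p) for p in inputs["precip_future"]]
    urban = read_ascii_grid(inputs["urban"])
    roads = _read_lines_geojson(Path(inputs["roads"]))
    provinces = read_geojson(inputs["provinces"])
    tdir = outdir / "threat"
    tdir.mkdir(exist_ok=True)
    outputs = []
    maps = {}
    for name in scenario_names:
        tim = compute_threat_index(
            SCENARIOS[name], density, cropland, roads, provinces, tree_loss, burn,
            temp_c, temp_f, prec_c, prec_f, urban,
        )
        maps[name] = tim
        write_ascii_grid(tim.index, tdir / f"index_{name}.asc")
        write_ascii_grid(tim.classes, tdir / f"classes_{name}.asc")
        outputs += [tdir / f"index_{name}.asc", tdir / f"classes_{name}.asc"]
    if "reference" in maps:
        report = {}
        for name, tim in maps.items():
            if name == "reference":
                continue
            changed, inc, dec = sensitivity_compare(maps["reference"].classes, tim.classes)
            report[name] = {"changed_pct": changed, "increased_pct": inc, "decreased_pct": dec}
        p = tdir / "sensitivity.json"
        p.write_text(json.dumps(report, indent=2))
        outputs.append(p)
    return outputs


def _stage_exposure(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    inputs = _resolve_inputs(cfg, outdir)
    pas = read_geojson(inputs["pas"])
    classes = read_ascii_grid(outdir / "threat" / "classes_reference.asc")
    binaries = []
    for sp in inputs["species"]:
        b = read_ascii_grid(outdir / "sdm" / sp / "binary.asc")
        binaries.append(BinarySuitabilityMap(species=sp, threshold=float("nan"), map=b))
    edir = outdir / "exposure"
    edir.mkdir(exist_ok=True)
    rich = richness_map(binaries)
    write_ascii_grid(rich, edir / "richness.asc")
    summaries = [exposure_summary(b, classes, pas) for b in binaries]
    summaries_table(summaries).to_csv(edir / "summaries.csv", index=False)
    profile = pa_class_profile(classes, pas)
    (edir / "pa_class_profile.json").write_text(json.dumps(profile, indent=2))
    report = {
        "species": [s.species for s in summaries],
        "protected_fraction": {s.species: s.protected_fraction for s in summaries},
        "fraction_by_class": {s.species: s.fraction_by_class for s in summaries},
    }
    (edir / "report.json").write_text(json.dumps(report, indent=2))
    return [edir / "richness.asc", edir / "summaries.csv", edir / "pa_class_profile.json", edir / "report.json"]


_STAGE_FNS = {
    "fixtures": _stage_fixtures,
    "prep": _stage_prep,
    "sdm": _stage_sdm,
    "threat": _stage_threat,
    "exposure": _stage_exposure,
}
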