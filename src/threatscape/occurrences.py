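"""Occurrence-record cleaning and spatial thinning.

Raw herbarium/GBIF-style presence records go through three steps before
modelling: collector+number de-duplication, a strict 5-km positional
uncertainty gate, and a one-record-per-grid-cell spatial filter that keeps
the record closest to its cell center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec

__all__ = [
    "OccurrenceRecord",
    "OccurrenceSet",
    "deduplicate",
    "filter_uncertainty",
    "spatial_thin",
    "read_occurrences_csv",
    "write_occurrences_csv",
]

OCC_COLUMNS = ["species", "x", "y", "collector", "collection_number", "uncertainty_m", "source_id"]


@dataclass(frozen=True)
class OccurrenceRecord:
    species: str
    x: float
    y: float
    collector: str | None = None
    collection_number: str | None = None
    uncertainty_m: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("coordinates must be finite")
        if self.uncertainty_m is not None and self.uncertainty_m < 0:
            raise ValueError("uncertainty_m must be non-negative")


@dataclass
class OccurrenceSet:
    """Presence records of one species on the analysis grid."""

    species: str
    records: list[OccurrenceRecord]
    grid: GridSpec

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.species != self.species:
                raise ValueError(f"record species {rec.species!r} != set species {self.species!r}")

    def __len__(self) -> int:
        return len(self.records)

    def cells(self) -> list[tuple[int, int]]:
        """Distinct occupied grid cells, in first-occurrence order."""
        seen: dict[tuple[int, int], None] = {}
        for rec in self.records:
            row, col = self.grid.cell_of(rec.x, rec.y)
            seen.setdefault((int(row), int(col)), None)
        return list(seen)


def deduplicate(records: list[OccurrenceRecord]) -> list[OccurrenceRecord]:
    """Drop later records sharing both collector and collection number.

    Records missing either field carry no duplicate evidence and are never
    merged.  First occurrence in input order survives.
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for rec in records:
        if rec.collector is not None and rec.collection_number is not None:
            key = (rec.collector, rec.collection_number)
            if key in seen:
                continue
            seen.add(key)
        out.append(rec)
    return out


def filter_uncertainty(records: list[OccurrenceRecord], max_uncertainty_m: float = 5000.0) -> list[OccurrenceRecord]:
    """Keep records with positional uncertainty strictly below the gate.

    Records with no stated uncertainty are retained; their count is reported
    in a warning so the analyst can judge the risk.
    """
    out = []
    n_unknown = 0
    for rec in records:
        if rec.uncertainty_m is None:
            n_unknown += 1
            out.append(rec)
        elif rec.uncertainty_m < max_uncertainty_m:
            out.append(rec)
    if n_unknown:
        warnings.warn(
            f"{n_unknown} record(s) lack uncertainty metadata and were retained",
            stacklevel=2,
        )
    return out


def spatial_thin(occ: OccurrenceSet) -> OccurrenceSet:
    """Retain one record per grid cell: nearest the cell center, ties by order.

    Records falling outside the grid extent are excluded with a warning.
    """
    grid = occ.grid
    best: dict[tuple[int, int], tuple[float, int]] = {}
    n_outside = 0
    for i, rec in enumerate(occ.records):
        row, col = grid.cell_of(rec.x, rec.y)
        row, col = int(row), int(col)
        if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
            n_outside += 1
            continue
        cx, cy = grid.center_of(row, col)
        d2 = (rec.x - cx) ** 2 + (rec.y - cy) ** 2
        cur = best.get((row, col))
        if cur is None or d2 < cur[0]:
            best[(row, col)] = (float(d2), i)
    if n_outside:
        warnings.warn(f"{n_outside} record(s) outside grid extent were excluded", stacklevel=2)
    keep = sorted(i for _, i in best.values())
    return OccurrenceSet(occ.species, [occ.records[i] for i in keep], grid)


def read_occurrences_csv(path: str | Path, species: str, grid: GridSpec) -> OccurrenceSet:
    df = pd.read_csv(path)
    recs = []
    for _, row in df[df["species"] == species].iterrows():
        recs.append(
            OccurrenceRecord(
                species=row["species"],
                x=float(row["x"]),
                y=float(row["y"]),
                collector=None if pd.isna(row.get("collector")) else str(row["collector"]),
                collection_number=None if pd.isna(row.get("collection_number")) else str(row["collection_number"]),
                uncertainty_m=None if pd.isna(row.get("uncertainty_m")) else float(row["uncertainty_m"]),
                source_id=str(row.get("source_id", "")),
            )
        )
    return OccurrenceSet(species, recs, grid)


def write_occurrences_csv(sets: list[OccurrenceSet], path: str | Path) -> None:
    rows = [
        {
            "species": r.species,
            "x": r.x,
            "y": r.y,
            "collector": r.collector,
            "collection_number": r.collection_number,
            "uncertainty_m": r.uncertainty_m,
            "source_id": r.source_id,
        }
        for s in sets
        for r in s.records
    ]
    pd.DataFrame(rows, columns=OCC_COLUMNS).to_csv(path, index=False)
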