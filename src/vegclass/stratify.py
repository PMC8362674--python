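"""Geographic grid stratified resampling of classified relevés.

Oversampled localities are thinned by overlaying an arc-minute grid
(anchored at 0°E, 0°N) and keeping at most ``per_cell`` randomly chosen
relevés per (grid cell, vegetation unit) stratum.  The default cell of
1.25' longitude x 0.75' latitude is roughly 1.4 x 1.4 km at 52° N.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .releve_io import Releve, ReleveTable

__all__ = ["GridSpec", "grid_cell", "stratified_sample", "export_geojson"]


@dataclass(frozen=True)
class GridSpec:
    """Grid cell size; *unit* is "arcmin" (default) or "degree"."""

    width: float = 1.25
    height: float = 0.75
    unit: str = "arcmin"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("grid cell dimensions must be positive")
        if self.unit not in ("arcmin", "degree"):
            raise ValueError(f"unknown grid unit {self.unit!r}")

    @property
    def width_deg(self) -> float:
        return self.width / 60.0 if self.unit == "arcmin" else self.width

    @property
    def height_deg(self) -> float:
        return self.height / 60.0 if self.unit == "arcmin" else self.height


def grid_cell(lon: float, lat: float, grid: GridSpec) -> tuple[int, int]:
    """Integer cell indices (i, j) = (floor(lon/w), floor(lat/h))."""
    if lon is None or lat is None:
        raise ValueError("missing coordinates")
    return (
        math.floor(lon / grid.width_deg),
        math.floor(lat / grid.height_deg),
    )


def stratified_sample(
    table: ReleveTable,
    labels: Mapping[str, str],
    grid: GridSpec | None = None,
    per_cell: int = 3,
    seed: int | np.random.Generator = 0,
) -> ReleveTable:
    """Keep at most *per_cell* plots per (grid cell, unit) stratum.

    Selection is uniform without replacement under *seed*; output plot order
    is deterministic (sorted plot id).  Strata are visited in sorted order
    so the same seed always yields the same sample.
    """
    grid = grid or GridSpec()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    strata: dict[tuple, list[str]] = {}
    for plot_id, unit in labels.items():
        rel = table[plot_id]
        if not rel.has_coords():
            raise ValueError(f"plot {plot_id!r} has no coordinates")
        key = (*grid_cell(rel.lon, rel.lat, grid), unit)
        strata.setdefault(key, []).append(plot_id)

    kept: list[str] = []
    for key in sorted(strata):
        plot_ids = sorted(strata[key])
        if len(plot_ids) <= per_cell:
            kept.extend(plot_ids)
        else:
            idx = rng.choice(len(plot_ids), size=per_cell, replace=False)
            kept.extend(plot_ids[i] for i in idx)
    return table.subset(sorted(kept))


def export_geojson(
    table: ReleveTable,
    labels: Mapping[str, str],
    out_dir: str | Path,
    prefix: str = "units",
) -> list[Path]:
    """Write one GeoJSON point collection per unit (WGS84 lon/lat)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_unit: dict[str, list[Releve]] = {}
    for plot_id, unit in labels.items():
        by_unit.setdefault(unit, []).append(table[plot_id])
    paths = []
    for unit in sorted(by_unit):
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [rel.lon, rel.lat]},
                "properties": {"plot_id": rel.plot_id, "unit": unit},
            }
            for rel in sorted(by_unit[unit], key=lambda r: r.plot_id)
            if rel.has_coords()
        ]
        slug = "".join(c if c.isalnum() else "_" for c in unit.lower())
        path = out_dir / f"{prefix}_{slug}.geojson"
        path.write_text(
            json.dumps(
                {"type": "FeatureCollection", "features": features}, indent=1
            )
        )
        paths.append(path)
    return paths
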