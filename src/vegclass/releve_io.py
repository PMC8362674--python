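"""Relevé data model and I/O.

A relevé is a standardized vegetation plot record: species with
cover-abundance values (by vertical layer) plus header metadata
(coordinates, plot area, date).  Covers are held internally as fractions in
[0, 1]; cover-abundance codes (Braun-Blanquet dialects) are converted to
class midpoints on input via a :class:`CoverScale`.

When a species occurs in several layers, or several taxa are merged into one
aggregate, covers are combined under the independence formula
``1 - prod(1 - c_i)`` — the combined cover assuming random overlap of the
individual covers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "CoverScale",
    "MergeMap",
    "Releve",
    "ReleveTable",
    "ReleveError",
    "canonical_name",
    "combine_covers",
    "convert_cover",
    "default_scale",
    "filter_releves",
    "load_scales",
    "merge_taxa",
    "read_releves",
    "write_releves",
]

log = logging.getLogger(__name__)

DEFAULT_LAYER = "herb"


class ReleveError(ValueError):
    """Raised for malformed relevé inputs (bad covers, duplicates, ...)."""


def canonical_name(name: str) -> str:
    """Normalize a taxon name: collapse internal whitespace, strip ends."""
    return " ".join(str(name).split())


def name_key(name: str) -> str:
    """Case-insensitive matching key for a taxon or group name."""
    return canonical_name(name).casefold()


def combine_covers(covers: Iterable[float]) -> float:
    """Combine covers (fractions) under independence: ``1 - prod(1 - c)``."""
    covers = list(covers)
    if len(covers) == 1:  # avoid 1-(1-c) float round-trip
        return covers[0]
    out = 1.0
    for c in covers:
        out *= 1.0 - c
    return 1.0 - out


@dataclass(frozen=True)
class CoverScale:
    """An ordered cover-abundance code -> percent-midpoint mapping.

    Codes absent from the mapping are parsed as plain percentages, so the
    ``percent`` scale is simply an empty mapping.
    """

    name: str
    midpoints: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev = 0.0
        for code, mid in self.midpoints.items():
            if not 0.0 < mid <= 100.0:
                raise ReleveError(
                    f"scale {self.name!r}: midpoint of {code!r} outside (0, 100]"
                )
            if mid <= prev:
                raise ReleveError(
                    f"scale {self.name!r}: midpoints must be strictly increasing"
                )
            prev = mid


def load_scales(path: str | Path | None = None) -> dict[str, CoverScale]:
    """Load cover scales from YAML (packaged scales when *path* is None)."""
    if path is None:
        text = (resources.files("vegclass.data") / "cover_scales.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    scales = {}
    for entry in raw["scales"]:
        mids = {str(k): float(v) for k, v in (entry.get("midpoints") or {}).items()}
        scales[entry["name"]] = CoverScale(entry["name"], mids)
    return scales


def default_scale(name: str = "braun_blanquet") -> CoverScale:
    return load_scales()[name]


def convert_cover(code: str | float, scale: CoverScale) -> float:
    """Convert a cover code or percentage string to a fraction in (0, 1].

    Codes of the scale map to their class midpoint / 100; anything else must
    parse as a percentage in (0, 100].  A recorded species cannot have zero
    cover, so ``0`` is an error.
    """
    text = str(code).strip()
    if text in scale.midpoints:
        return scale.midpoints[text] / 100.0
    try:
        value = float(text)
    except ValueError:
        raise ReleveError(
            f"unknown cover code {text!r} for scale {scale.name!r}"
        ) from None
    if not 0.0 < value <= 100.0:
        raise ReleveError(f"cover percentage {value} outside (0, 100]")
    return value / 100.0


@dataclass
class Releve:
    """One vegetation plot: (taxon, layer) -> cover fraction plus header."""

    plot_id: str
    records: dict[tuple[str, str], float] = field(default_factory=dict)
    lon: float | None = None
    lat: float | None = None
    area: float | None = None
    date: str | None = None

    def __post_init__(self) -> None:
        for (taxon, layer), cover in self.records.items():
            if not 0.0 <= cover <= 1.0:
                raise ReleveError(
                    f"plot {self.plot_id!r}: cover of {taxon!r} ({layer}) "
                    f"outside [0, 1]"
                )

    @property
    def taxa(self) -> set[str]:
        return {taxon for taxon, _ in self.records}

    def cover(self, taxon: str) -> float:
        """Layer-combined cover fraction of *taxon* (0 if absent)."""
        key = name_key(taxon)
        covers = [c for (t, _), c in self.records.items() if name_key(t) == key]
        return combine_covers(covers) if covers else 0.0

    def species_covers(self) -> dict[str, float]:
        """Layer-combined cover per taxon."""
        per: dict[str, list[float]] = {}
        for (taxon, _), cover in self.records.items():
            per.setdefault(taxon, []).append(cover)
        return {t: combine_covers(cs) for t, cs in per.items()}

    def has_coords(self) -> bool:
        return self.lon is not None and self.lat is not None


class ReleveTable:
    """An ordered collection of relevés with unique plot ids."""

    def __init__(self, releves: Iterable[Releve] = ()) -> None:
        self._plots: dict[str, Releve] = {}
        for rel in releves:
            if rel.plot_id in self._plots:
                raise ReleveError(f"duplicate plot id {rel.plot_id!r}")
            self._plots[rel.plot_id] = rel

    def __len__(self) -> int:
        return len(self._plots)

    def __iter__(self) -> Iterator[Releve]:
        return iter(self._plots.values())

    def __contains__(self, plot_id: str) -> bool:
        return plot_id in self._plots

    def __getitem__(self, plot_id: str) -> Releve:
        return self._plots[plot_id]

    @property
    def plot_ids(self) -> list[str]:
        return list(self._plots)

    @property
    def taxa(self) -> set[str]:
        out: set[str] = set()
        for rel in self:
            out |= rel.taxa
        return out

    def subset(self, plot_ids: Sequence[str]) -> "ReleveTable":
        return ReleveTable(self._plots[p] for p in plot_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReleveTable):
            return NotImplemented
        return self._plots == other._plots


def _read_frame(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_releves(
    species_path: str | Path,
    header_path: str | Path | None = None,
    scale: CoverScale | None = None,
) -> ReleveTable:
    """Read a long-format species table (plus optional plot headers).

    The species file needs columns ``plot_id, taxon, layer, cover``; the
    header file ``plot_id`` plus any of ``lon, lat, area_m2, date``.  Plots
    present in the species file but missing from the header file carry empty
    header fields.
    """
    scale = scale or default_scale()
    species = _read_frame(species_path)
    for col in ("plot_id", "taxon", "cover"):
        if col not in species.columns:
            raise ReleveError(f"species file missing column {col!r}")

    headers: dict[str, dict] = {}
    if header_path is not None:
        hdr = _read_frame(header_path)
        if "plot_id" not in hdr.columns:
            raise ReleveError("header file missing column 'plot_id'")
        for row in hdr.itertuples(index=False):
            d = row._asdict()
            headers[str(d["plot_id"])] = {
                "lon": float(d["lon"]) if d.get("lon") else None,
                "lat": float(d["lat"]) if d.get("lat") else None,
                "area": float(d["area_m2"]) if d.get("area_m2") else None,
                "date": d.get("date") or None,
            }

    releves: dict[str, Releve] = {}
    for row in species.itertuples(index=False):
        d = row._asdict()
        plot_id = str(d["plot_id"])
        taxon = canonical_name(d["taxon"])
        layer = canonical_name(d.get("layer") or "") or DEFAULT_LAYER
        try:
            cover = convert_cover(d["cover"], scale)
        except ReleveError as exc:
            raise ReleveError(f"plot {plot_id!r}, taxon {taxon!r}: {exc}") from None
        if plot_id not in releves:
            releves[plot_id] = Releve(plot_id, {}, **headers.get(plot_id, {}))
        rel = releves[plot_id]
        if (taxon, layer) in rel.records:
            raise ReleveError(
                f"duplicate record for plot {plot_id!r}, taxon {taxon!r}, "
                f"layer {layer!r}"
            )
        rel.records[(taxon, layer)] = cover
    # header-only plots (no species rows) are kept as empty relevés
    for plot_id, hdr_fields in headers.items():
        if plot_id not in releves:
            releves[plot_id] = Releve(plot_id, {}, **hdr_fields)
    return ReleveTable(releves.values())


def write_releves(
    table: ReleveTable,
    species_path: str | Path,
    header_path: str | Path | None = None,
) -> None:
    """Write a table back to the long-format dialect (covers as percent)."""
    rows = [
        {
            "plot_id": rel.plot_id,
            "taxon": taxon,
            "layer": layer,
            "cover": format(cover * 100.0, ".12g"),
        }
        for rel in table
        for (taxon, layer), cover in rel.records.items()
    ]
    sep = "\t" if str(species_path).endswith((".tsv", ".tab", ".txt")) else ","
    pd.DataFrame(rows, columns=["plot_id", "taxon", "layer", "cover"]).to_csv(
        species_path, sep=sep, index=False
    )
    if header_path is not None:
        hdr_rows = [
            {
                "plot_id": rel.plot_id,
                "lon": "" if rel.lon is None else format(rel.lon, ".12g"),
                "lat": "" if rel.lat is None else format(rel.lat, ".12g"),
                "area_m2": "" if rel.area is None else format(rel.area, ".12g"),
                "date": rel.date or "",
            }
            for rel in table
        ]
        sep = "\t" if str(header_path).endswith((".tsv", ".tab", ".txt")) else ","
        pd.DataFrame(
            hdr_rows, columns=["plot_id", "lon", "lat", "area_m2", "date"]
        ).to_csv(header_path, sep=sep, index=False)


@dataclass(frozen=True)
class MergeMap:
    """Mapping of taxonomically critical taxa onto aggregates.

    The mapping must be idempotent: an aggregate that itself appears as a
    source must map to itself.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        canon = {canonical_name(k): canonical_name(v) for k, v in self.mapping.items()}
        keys = {name_key(k): v for k, v in canon.items()}
        for target in canon.values():
            mapped = keys.get(name_key(target))
            if mapped is not None and name_key(mapped) != name_key(target):
                raise ReleveError(
                    f"merge map not idempotent: {target!r} -> {mapped!r}"
                )
        object.__setattr__(self, "mapping", canon)
        object.__setattr__(self, "_keys", keys)

    def resolve(self, taxon: str) -> str:
        return self._keys.get(name_key(taxon), canonical_name(taxon))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MergeMap":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(raw["merge"] if "merge" in raw else raw)


def merge_taxa(table: ReleveTable, merge: MergeMap) -> ReleveTable:
    """Rename taxa onto aggregates, combining collapsing covers."""
    out = []
    for rel in table:
        per: dict[tuple[str, str], list[float]] = {}
        for (taxon, layer), cover in rel.records.items():
            per.setdefault((merge.resolve(taxon), layer), []).append(cover)
        records = {key: combine_covers(cs) for key, cs in per.items()}
        out.append(replace(rel, records=records))
    return ReleveTable(out)


def filter_releves(
    table: ReleveTable,
    min_area: float | None = 1.0,
    max_area: float | None = 100.0,
    require_coords: bool = True,
    cultivated: Iterable[str] = (),
) -> ReleveTable:
    """Apply the plot-level filters used before classification.

    Plots without coordinates (when required) or with area outside
    ``[min_area, max_area]`` (bounds inclusive; plots with unknown area are
    excluded when bounds are enforced) are removed; records of cultivated
    species are dropped from the surviving plots, which are retained even if
    emptied.  Removal counts are logged.
    """
    if min_area is not None and max_area is not None and min_area > max_area:
        raise ReleveError("min_area > max_area")
    cult_keys = {name_key(t) for t in cultivated}
    kept, dropped_coords, dropped_area, dropped_records = [], 0, 0, 0
    for rel in table:
        if require_coords and not rel.has_coords():
            dropped_coords += 1
            continue
        if min_area is not None or max_area is not None:
            if rel.area is None:
                dropped_area += 1
                continue
            if (min_area is not None and rel.area < min_area) or (
                max_area is not None and rel.area > max_area
            ):
                dropped_area += 1
                continue
        if cult_keys:
            records = {
                (taxon, layer): cover
                for (taxon, layer), cover in rel.records.items()
                if name_key(taxon) not in cult_keys
            }
            dropped_records += len(rel.records) - len(records)
            rel = replace(rel, records=records)
        kept.append(rel)
    log.info(
        "filter_releves: kept %d of %d plots (%d without coordinates, "
        "%d by area); removed %d cultivated-species records",
        len(kept), len(table), dropped_coords, dropped_area, dropped_records,
    )
    return ReleveTable(kept)
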