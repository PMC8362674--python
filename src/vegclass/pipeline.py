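"""End-to-end workflow: read -> filter -> classify -> stratify -> synoptic
tables -> ordination -> exports.

Every stage logs count conservation (plots in = plots kept + excluded), all
outputs are plain CSV/TSV/JSON/GeoJSON, and a manifest with SHA-256
checksums plus the full configuration (seed included) makes two runs with
the same config byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import releve_io
from .cocktail_engine import SyntaxonHierarchy, classify_table
from .fidelity import RoleThresholds, build_synoptic, species_roles
from .ordination import (
    community_matrix,
    cwm_table,
    dca,
    fit_supplementary,
    load_eiv,
    transform_cover,
)
from .releve_io import MergeMap, ReleveTable, filter_releves, read_releves
from .stratify import GridSpec, export_geojson, stratified_sample

__all__ = ["PipelineConfig", "PipelineResult", "run", "run_table"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    species_path: str
    header_path: str | None = None
    out_dir: str = "pipeline_out"
    cover_scale: str = "braun_blanquet"
    merge_map_path: str | None = None
    min_area: float | None = 1.0
    max_area: float | None = 100.0
    require_coords: bool = True
    cultivated: list[str] = field(default_factory=list)
    definitions_path: str | None = None  # packaged reconstruction when None
    grid_width: float = 1.25
    grid_height: float = 0.75
    grid_unit: str = "arcmin"
    per_cell: int = 3
    dca_axes: int = 4
    dca_segments: int = 26
    dca_min_plots: int = 10
    eiv_path: str | None = None  # packaged synthetic table when None
    n_permutations: int = 199
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    out_dir: Path
    counts: dict[str, Any]
    artifacts: dict[str, Path]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline from files on disk."""
    try:
        scale = releve_io.load_scales()[config.cover_scale]
        table = read_releves(config.species_path, config.header_path, scale)
    except Exception as exc:
        raise PipelineError(f"stage 'read' failed: {exc}") from exc
    return run_table(table, config)


def run_table(table: ReleveTable, config: PipelineConfig) -> PipelineResult:
    """Run the pipeline on an in-memory relevé table."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    counts: dict[str, Any] = {"input_plots": len(table)}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    @stage("merge")
    def merged() -> ReleveTable:
        if config.merge_map_path is None:
            return table
        return releve_io.merge_taxa(table, MergeMap.from_yaml(config.merge_map_path))

    @stage("filter")
    def filtered() -> ReleveTable:
        return filter_releves(
            merged,
            min_area=config.min_area,
            max_area=config.max_area,
            require_coords=config.require_coords,
            cultivated=config.cultivated,
        )

    counts["filtered_plots"] = len(filtered)
    counts["excluded_plots"] = counts["input_plots"] - len(filtered)

    @stage("classify")
    def classified():
        hierarchy = SyntaxonHierarchy.from_yaml(config.definitions_path)
        results, summary = classify_table(filtered, hierarchy)
        return hierarchy, results, summary

    hierarchy, results, summary = classified
    counts["classification"] = summary
    res_frame = pd.DataFrame(
        [
            {
                "plot_id": r.plot_id,
                "class": r.klass or "",
                "alliance": r.alliance or "",
                "association": r.association or "",
                "conflict": ";".join(r.conflict),
            }
            for r in results
        ]
    )
    artifacts["results"] = out / "results.tsv"
    res_frame.to_csv(artifacts["results"], sep="\t", index=False)

    # deepest assigned unit per plot; unassigned plots leave the workflow here
    labels = {r.plot_id: r.deepest for r in results if r.deepest is not None}
    counts["assigned_plots"] = len(labels)

    @stage("stratify")
    def stratified() -> ReleveTable:
        grid = GridSpec(config.grid_width, config.grid_height, config.grid_unit)
        return stratified_sample(
            filtered, labels, grid, per_cell=config.per_cell, seed=config.seed
        )

    counts["stratified_plots"] = len(stratified)
    strat_labels = {p: labels[p] for p in stratified.plot_ids}
    unit_counts: dict[str, int] = {}
    for unit in strat_labels.values():
        unit_counts[unit] = unit_counts.get(unit, 0) + 1
    counts["stratified_per_unit"] = dict(sorted(unit_counts.items()))

    @stage("synoptic")
    def synoptic():
        if not strat_labels:
            raise ValueError("no classified relevés; labels are required")
        ranks = {
            name: node.rank for name, node in hierarchy.nodes.items()
        }
        syn = build_synoptic(stratified, strat_labels)
        return species_roles(syn, stratified, strat_labels, RoleThresholds(), ranks)

    artifacts["synoptic"] = out / "synoptic.csv"
    synoptic.to_frame().to_csv(artifacts["synoptic"], index=False)

    @stage("ordination")
    def ordination_outputs():
        assoc_plots = [
            r.plot_id for r in results
            if r.association is not None and r.plot_id in stratified
        ]
        if len(assoc_plots) < config.dca_min_plots:
            return None
        sub = stratified.subset(assoc_plots)
        mat = transform_cover(community_matrix(sub), p=0.5)
        result = dca(mat, n_axes=config.dca_axes, n_segments=config.dca_segments)
        cwm = cwm_table(sub, load_eiv(config.eiv_path))
        fit = fit_supplementary(
            result, cwm, n_permutations=config.n_permutations, seed=config.seed
        )
        return result, fit

    if ordination_outputs is not None:
        dca_result, fit = ordination_outputs
        artifacts["dca_sites"] = out / "dca_sites.csv"
        dca_result.site_scores.to_csv(artifacts["dca_sites"])
        artifacts["dca_species"] = out / "dca_species.csv"
        dca_result.species_scores.to_csv(artifacts["dca_species"])
        artifacts["dca_eigenvalues"] = out / "dca_eigenvalues.csv"
        pd.Series(
            dca_result.eigenvalues,
            index=[f"DCA{i+1}" for i in range(dca_result.n_axes)],
            name="eigenvalue",
        ).to_csv(artifacts["dca_eigenvalues"])
        artifacts["supplementary"] = out / "supplementary_fit.csv"
        fit.to_frame().to_csv(artifacts["supplementary"])
        counts["dca_plots"] = len(dca_result.site_scores)
        counts["dca_eigenvalues"] = [float(v) for v in dca_result.eigenvalues]

    @stage("export")
    def geo_paths():
        return export_geojson(stratified, strat_labels, out / "geo")

    for path in geo_paths:
        artifacts[f"geojson:{path.stem}"] = path

    artifacts["counts"] = out / "counts.json"
    artifacts["counts"].write_text(json.dumps(counts, indent=1, sort_keys=True))

    report = out / "report.md"
    by_rank = summary["by_rank"]
    lines = [
        "# Pipeline run report",
        "",
        "## Configuration",
        "```yaml",
        # out_dir is where this report lives; leaving it out keeps runs of
        # the same config byte-comparable across output directories
        yaml.safe_dump(
            {k: v for k, v in asdict(config).items() if k != "out_dir"},
            sort_keys=True,
        ).strip(),
        "```",
        "",
        "## Stage counts",
        f"- plots read: {counts['input_plots']}",
        f"- plots after filters: {counts['filtered_plots']} "
        f"(excluded {counts['excluded_plots']})",
        f"- assigned to the class (any rank): {counts['assigned_plots']}",
        f"- association level: {by_rank['association']}, "
        f"alliance only: {by_rank['alliance_only']}, "
        f"class only: {by_rank['class_only']}, "
        f"unassigned: {by_rank['unassigned']}",
        f"- after geographic stratification: {counts['stratified_plots']}",
        "",
        "## Relevés per unit (after stratification)",
    ]
    lines += [f"- {unit}: {n}" for unit, n in sorted(unit_counts.items())]
    if "dca_plots" in counts:
        ev = ", ".join(f"{v:.4f}" for v in counts["dca_eigenvalues"])
        lines += ["", f"## DCA ({counts['dca_plots']} association-level relevés)",
                  f"- eigenvalues: {ev}"]
    report.write_text("\n".join(lines) + "\n")
    artifacts["report"] = report

    manifest = {
        str(path.relative_to(out)): _checksum(path)
        for path in sorted(artifacts.values())
    }
    (out / "manifest.json").write_text(
        json.dumps({"seed": config.seed, "files": manifest}, indent=1, sort_keys=True)
    )
    artifacts["manifest"] = out / "manifest.json"
    return PipelineResult(out_dir=out, counts=counts, artifacts=artifacts)
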