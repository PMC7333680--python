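"""Batch pipeline: folder of reconstructions → density maps and exports.

One run reads every reconstruction in a folder (unreadable files are
skipped, logged, and the batch continues), optionally aligns each cell to
a consensus geometry (translation of its soma onto the consensus soma)
and applies the consensus compartment whitelist, lays ONE shared sampling
grid over the bounding box of all aligned cells, computes per-neuron
density fields in parallel, combines them into the max-normalized field,
and exports profiles, heatmaps and (optionally) isosurface meshes.

Per-neuron fields are computed independently per cell and combined in
sorted file order, so numeric outputs are byte-identical regardless of
the worker count (the partition-independence contract).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fixtures as fx
from .density import combine, make_grid, neuron_density, save_field
from .geometry import (
    align_to_consensus,
    bounding_box,
    consensus_compartments,
    filter_compartments,
    total_length,
)
from .io import read_any
from .isosurface import iso_band, write_mesh
from .morphology import Morphology, Scene
from .projection import export_profile, project_axis, project_plane
from .render import ColorMapSpec, render_heatmap, render_profiles

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_density", "run_fixtures"]

_MORPH_EXTS = {".swc", ".xml", ".asc"}


@dataclass
class RunConfig:
    """Everything a batch run needs; serializable and echoed to the output."""

    input_folder: str
    output_folder: str
    consensus: str | None = None
    cuboid_size: tuple[float, float, float] = (50.0, 50.0, 50.0)
    exclude_compartments: tuple[str, ...] = ()
    norm_mode: str = "total_length"
    min_density_pct: float = 0.0
    iso_average_pct: float | None = None
    iso_deviation_pct: float = 10.0
    color0: tuple[int, int, int] = (0, 0, 255)
    color1: tuple[int, int, int] = (255, 0, 0)
    image_format: str = "png"
    scalebar: bool = True
    blur_output: bool = False
    workers: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not Path(self.input_folder).is_dir():
            raise ValueError(f"input folder {self.input_folder!r} does not exist")
        if any(s <= 0 for s in self.cuboid_size):
            raise ValueError("cuboid_size components must be positive")
        if self.norm_mode not in ("total_length", "voxel_volume"):
            raise ValueError(f"unknown norm_mode {self.norm_mode!r}")
        if not 0 <= self.min_density_pct <= 100:
            raise ValueError("min_density_pct must be in [0, 100]")
        if self.workers < 1:
            raise ValueError("workers must be ≥ 1")
        if self.image_format.lower() not in ("png", "jpg", "jpeg", "tiff", "gif"):
            raise ValueError(f"unsupported image format {self.image_format!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        cfg = cls(**data)
        cfg.cuboid_size = tuple(cfg.cuboid_size)
        cfg.exclude_compartments = tuple(cfg.exclude_compartments)
        cfg.color0 = tuple(cfg.color0)
        cfg.color1 = tuple(cfg.color1)
        return cfg


@dataclass
class RunReport:
    """What a batch run read, skipped and produced."""

    files_read: list[str] = field(default_factory=list)
    files_skipped: list[str] = field(default_factory=list)
    total_lengths_um: dict[str, float] = field(default_factory=dict)
    grid_counts: tuple[int, int, int] = (0, 0, 0)
    grid_lower: tuple[float, float, float] = (0.0, 0.0, 0.0)
    max_density_voxel: tuple[int, int, int] = (0, 0, 0)
    combined_max: float = 0.0
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _load_cells(config: RunConfig, report: RunReport) -> list[Morphology]:
    paths = sorted(
        p
        for p in Path(config.input_folder).iterdir()
        if p.is_file() and p.suffix.lower() in _MORPH_EXTS
    )
    consensus_path = Path(config.consensus).resolve() if config.consensus else None
    cells: list[Morphology] = []
    for p in paths:
        if consensus_path and p.resolve() == consensus_path:
            continue
        try:
            scene = read_any(p)
        except Exception as exc:  # batch continues past unreadable files
            logger.warning("skipping %s: %s", p, exc)
            report.files_skipped.append(str(p))
            continue
        if not scene.morphologies:
            logger.warning("skipping %s: contours only", p)
            report.files_skipped.append(str(p))
            continue
        report.files_read.append(str(p))
        for i, m in enumerate(scene.morphologies):
            if len(scene.morphologies) > 1:
                m.name = f"{p.stem}.{i + 1}"
            else:
                m.name = p.stem
            cells.append(m)
    return cells


def run_density(config: RunConfig) -> RunReport:
    """Execute a full batch run; returns the report (also written as JSON)."""
    config.validate()
    t_start = time.monotonic()
    out = Path(config.output_folder)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    cells = _load_cells(config, report)
    if not cells:
        raise ValueError(f"no readable morphologies in {config.input_folder!r}")

    consensus: Scene | None = None
    if config.consensus:
        consensus = read_any(config.consensus)
        cells = [align_to_consensus(m, consensus) for m in cells]
        allowed = consensus_compartments(consensus)
        if allowed:
            dropped = sorted(
                {str(c) for m in cells for c in m.compartments} - allowed
            )
            if dropped:
                logger.info(
                    "consensus whitelist %s drops compartments: %s",
                    sorted(allowed),
                    dropped,
                )
            cells = [
                filter_compartments(m, set(str(c) for c in m.compartments) - allowed)
                for m in cells
            ]

    if config.exclude_compartments:
        cells = [filter_compartments(m, config.exclude_compartments) for m in cells]
    cells = [m for m in cells if len(m) > 0]
    if not cells:
        raise ValueError("no vertices left after compartment filtering")

    for m in cells:
        report.total_lengths_um[m.name] = total_length(m)

    box = bounding_box(Scene(cells, []))
    grid = make_grid(box, np.asarray(config.cuboid_size))
    report.grid_counts = grid.counts
    report.grid_lower = tuple(float(v) for v in grid.lower)

    # per-neuron fields: independent per cell, combined in fixed order, so
    # the result does not depend on the worker count
    if config.workers > 1:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            fields = list(
                pool.map(lambda m: neuron_density(m, grid, config.norm_mode), cells)
            )
    else:
        fields = [neuron_density(m, grid, config.norm_mode) for m in cells]

    combined = combine(fields)
    report.combined_max = float(combined.values.max())
    report.max_density_voxel = tuple(
        int(i) for i in np.unravel_index(np.argmax(combined.values), combined.values.shape)
    )

    def record(path: Path) -> None:
        # relative paths keep the report byte-stable across output locations
        report.outputs.append(str(path.relative_to(out)))

    fields_dir = out / "fields"
    fields_dir.mkdir(exist_ok=True)
    for m, f in zip(cells, fields):
        npy, meta = save_field(f, fields_dir / m.name)
        record(npy); record(meta)
    npy, meta = save_field(combined, out / "combined")
    record(npy); record(meta)

    display = combined
    if config.blur_output:
        from .density import blur

        display = blur(combined)
        npy, meta = save_field(display, out / "combined_blurred")
        record(npy); record(meta)

    for axis in "xyz":
        prof = project_axis(combined, axis)
        p = out / f"profile_{axis}.csv"
        export_profile(prof, p)
        record(p)

    spec = ColorMapSpec(
        color0=config.color0,
        color1=config.color1,
        min_density_pct=config.min_density_pct,
    )
    overlays = Scene(cells, list(consensus.contours) if consensus else [])
    ext = config.image_format.lower()
    for plane in ("xy", "xz", "yz"):
        img = project_plane(display, plane)
        p = out / f"heatmap_{plane}.{ext}"
        render_heatmap(img, spec, overlays=overlays, path=p, scalebar=config.scalebar)
        record(p)
    profs = [project_axis(combined, a) for a in "xyz"]
    p = out / f"profiles_combined.{ext}"
    render_profiles(profs, combined=True, path=p)
    record(p)

    if config.iso_average_pct is not None:
        meshes = iso_band(combined, config.iso_average_pct, config.iso_deviation_pct)
        for mesh in meshes:
            p = out / f"iso_{mesh.isovalue:.4f}.obj"
            write_mesh(mesh, p)
            record(p)

    (out / "config.json").write_text(config.to_json() + "\n")
    (out / "report.json").write_text(report.to_json() + "\n")
    # hardware-dependent numbers stay out of the report body
    (out / "timings.json").write_text(
        json.dumps({"wall_seconds": time.monotonic() - t_start}) + "\n"
    )
    return report


def run_fixtures(spec_name: str, out_folder: str | Path, seed: int = 0) -> list[Path]:
    """Write a named fixture corpus (see :data:`fixtures.CORPUS_SPECS`)."""
    return fx.write_corpus(spec_name, out_folder, seed=seed)
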