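"""Isosurface extraction from density fields.

Scalar samples live at voxel centers; the mesh is the standard
marching-cubes triangulation of that cell-centered lattice with linear
edge interpolation (the Lewiner 256-case tables as implemented by
scikit-image, which resolve the ambiguous configurations consistently).
Vertex coordinates are in μm in the grid frame; consequently a mesh can
never extend beyond the outer half-voxel shell of the lattice.

The band interface mirrors the average ± deviation parameterization:
both percentages refer to the normalized density (field maximum = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure

from .density import DensityField

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "marching_cubes",
    "iso_band",
    "write_mesh",
    "read_obj",
    "edge_use_counts",
]

_WELD_DECIMALS = 9  # weld tolerance 1e-9 μm
_MIN_AREA = 1e-12


@dataclass
class TriangleMesh:
    """An indexed triangle mesh in μm."""

    vertices: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    triangles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    isovalue: float = 0.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if len(self.triangles) and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle indices out of range")

    @property
    def is_empty(self) -> bool:
        return len(self.triangles) == 0

    def triangle_areas(self) -> np.ndarray:
        a = self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 1]]
        c = self.vertices[self.triangles[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def surface_area(self) -> float:
        return float(self.triangle_areas().sum())


def _weld(vertices: np.ndarray, triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices within 1e-9 μm and drop degenerate triangles."""
    if len(vertices) == 0:
        return vertices, triangles
    key = np.round(vertices, _WELD_DECIMALS)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    new_vertices = vertices[np.sort(first)]
    # remap unique-order indices onto sorted-first order
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    tri = rank[inverse][triangles]
    # drop triangles with repeated vertices or ~zero area
    distinct = (
        (tri[:, 0] != tri[:, 1]) & (tri[:, 1] != tri[:, 2]) & (tri[:, 0] != tri[:, 2])
    )
    tri = tri[distinct]
    if len(tri):
        a = new_vertices[tri[:, 0]]
        b = new_vertices[tri[:, 1]]
        c = new_vertices[tri[:, 2]]
        areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
        tri = tri[areas > _MIN_AREA]
    return new_vertices, tri


def marching_cubes(f: DensityField, isovalue: float) -> TriangleMesh:
    """Extract the isosurface of a normalized field at *isovalue* ∈ (0, 1).

    Returns an empty mesh (with a warning) when the field never crosses
    the isovalue or the grid is too thin to triangulate.
    """
    if not 0.0 < isovalue < 1.0:
        raise ValueError("isovalue must lie strictly between 0 and 1")
    values = f.values
    if (
        min(values.shape) < 2
        or values.max() <= isovalue
        or values.min() >= isovalue
    ):
        logger.warning(
            "marching_cubes: field does not cross isovalue %.4g; empty mesh", isovalue
        )
        return TriangleMesh(isovalue=isovalue)
    spacing = tuple(float(s) for s in f.grid.cuboid_size)
    verts, faces, _normals, _vals = measure.marching_cubes(
        values, level=isovalue, spacing=spacing, gradient_direction="descent"
    )
    # index frame → μm grid frame: sample (i,j,k) sits at L + (i+½, j+½, k+½)∘l
    verts = verts + (f.grid.lower + 0.5 * f.grid.cuboid_size)
    verts, faces = _weld(verts, np.asarray(faces, dtype=np.int64))
    return TriangleMesh(verts, faces, isovalue=isovalue)


def iso_band(
    f: DensityField, average_pct: float, deviation_pct: float
) -> tuple[TriangleMesh, ...]:
    """Meshes at (average − deviation) % and (average + deviation) %.

    Percentages refer to the normalized density; band endpoints are
    clamped into (0, 1). A zero deviation collapses the band to the single
    average-isovalue mesh; an empty band after clamping yields no meshes.
    """
    if not 0.0 <= average_pct <= 100.0:
        raise ValueError("average_pct must be in [0, 100]")
    if deviation_pct < 0.0:
        raise ValueError("deviation_pct must be non-negative")
    eps = 1e-9
    lo = max((average_pct - deviation_pct) / 100.0, eps)
    hi = min((average_pct + deviation_pct) / 100.0, 1.0 - eps)
    if lo > hi:
        logger.warning("iso_band: empty band after clamping")
        return ()
    if deviation_pct == 0.0 or lo == hi:
        return (marching_cubes(f, lo),)
    return (marching_cubes(f, lo), marching_cubes(f, hi))


def edge_use_counts(mesh: TriangleMesh) -> dict[tuple[int, int], int]:
    """How many triangles use each undirected edge (2 ⇔ watertight)."""
    counts: dict[tuple[int, int], int] = {}
    for tri in mesh.triangles:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (int(min(a, b)), int(max(a, b)))
            counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Wavefront OBJ export


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write as Wavefront OBJ (``v``/``f`` records, 1-based indices)."""
    path = Path(path)
    if mesh.is_empty:
        logger.warning("%s: writing empty mesh", path)
    lines = [f"# neurodensity isosurface, isovalue {float(mesh.isovalue)!r}"]
    for v in mesh.vertices:
        x, y, z = (float(c) for c in v)
        lines.append(f"v {x!r} {y!r} {z!r}")
    for t in mesh.triangles:
        lines.append(f"f {int(t[0]) + 1} {int(t[1]) + 1} {int(t[2]) + 1}")
    path.write_text("\n".join(lines) + "\n")


def read_obj(path: str | Path) -> TriangleMesh:
    """Read the v/f subset of a Wavefront OBJ file."""
    verts, faces = [], []
    iso = 0.0
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "#" and "isovalue" in parts:
            try:
                iso = float(parts[-1])
            except ValueError:
                pass
        elif parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            faces.append([int(tok.split("/")[0]) - 1 for tok in parts[1:4]])
    return TriangleMesh(
        np.array(verts, dtype=np.float64).reshape(-1, 3),
        np.array(faces, dtype=np.int64).reshape(-1, 3),
        isovalue=iso,
    )
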