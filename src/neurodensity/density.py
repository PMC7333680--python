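"""Sampling-cuboid length densities — the computational core.

A reconstruction's cable is binned onto an axis-aligned lattice of
"sampling cuboids" (voxels) of user-chosen edge lengths l = (l_x, l_y, l_z)
μm. The lattice covers the bounding box of all loaded cells: the voxel
count per axis is N_j = ⌈E_j / l_j⌉ where E_j is the box extent, so the
grid may overshoot the tight box by up to one voxel per axis.

Per neuron, the raw value of a voxel B is the exact cable length of the
morphology inside B (parametric slab clipping, no sampling). The per-neuron
density |B_i| divides raw length either by the neuron's total cable length
(default; the field then sums to 1 for a fully contained cell) or by the
voxel volume (units μm/μm³ = μm⁻²). Multiple neurons are combined by the
voxelwise sum S(B) = Σ_i |B_i| rescaled by its grid-wide maximum
m = max_B S(B), so the combined field always peaks at exactly 1 and lives
in [0, 1].

Voxels are half-open along internal boundary planes; a segment lying
exactly in such a plane is credited to the higher-index voxel (a
measure-zero, deterministic tie-break). Edge sums run in file order in
double precision, so results do not depend on any internal partitioning.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import AABB
from .morphology import Morphology

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "DensityField",
    "make_grid",
    "clip_length",
    "raw_length_grid",
    "neuron_density",
    "combine",
    "threshold_mask",
    "gaussian_kernel",
    "blur",
    "save_field",
    "load_field",
]

FIELD_FORMAT = "neurodensity-field"
FIELD_VERSION = 1


@dataclass(frozen=True)
class GridSpec:
    """The sampling lattice: lower corner, cuboid edge lengths, counts."""

    lower: np.ndarray       # (3,) μm
    cuboid_size: np.ndarray  # (3,) μm, > 0
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=np.float64))
        object.__setattr__(
            self, "cuboid_size", np.asarray(self.cuboid_size, dtype=np.float64)
        )
        object.__setattr__(self, "counts", tuple(int(n) for n in self.counts))
        if self.lower.shape != (3,) or self.cuboid_size.shape != (3,):
            raise ValueError("grid lower/cuboid_size must be 3-vectors")
        if np.any(self.cuboid_size <= 0):
            raise ValueError("cuboid edge lengths must be positive")
        if any(n < 1 for n in self.counts):
            raise ValueError("voxel counts must be ≥ 1")

    @property
    def upper(self) -> np.ndarray:
        """Outer corner of the lattice (may overshoot the source box)."""
        return self.lower + np.asarray(self.counts) * self.cuboid_size

    @property
    def outer_box(self) -> AABB:
        return AABB(self.lower, self.upper)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.cuboid_size))

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (μm)."""
        n = self.counts[axis]
        return self.lower[axis] + (np.arange(n) + 0.5) * self.cuboid_size[axis]

    def voxel_centers(self) -> np.ndarray:
        """(N1*N2*N3, 3) array of voxel centers in C (row-major) order."""
        cx, cy, cz = (self.axis_centers(a) for a in range(3))
        gx, gy, gz = np.meshgrid(cx, cy, cz, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass
class DensityField:
    """A scalar value per sampling cuboid.

    ``stage`` tracks provenance: ``per_neuron`` (one cell, normalized by
    its total length or by voxel volume), ``summed`` (plain voxelwise sum)
    or ``normalized`` (max-rescaled combined field in [0, 1]).
    """

    grid: GridSpec
    values: np.ndarray
    stage: str = "per_neuron"       # per_neuron | summed | normalized
    norm_mode: str = "total_length"  # total_length | voxel_volume

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")
        if self.stage not in ("per_neuron", "summed", "normalized"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.norm_mode not in ("total_length", "voxel_volume"):
            raise ValueError(f"unknown norm_mode {self.norm_mode!r}")


def make_grid(box: AABB, cuboid_size) -> GridSpec:
    """Lay a sampling lattice over *box*: N_j = ⌈E_j / l_j⌉ (≥ 1)."""
    size = np.asarray(cuboid_size, dtype=np.float64)
    if size.ndim == 0:
        size = np.full(3, float(size))
    if size.shape != (3,):
        raise ValueError("cuboid_size must be a scalar or 3-vector")
    if np.any(size <= 0):
        raise ValueError("cuboid_size components must be positive")
    extent = box.extent
    counts = tuple(max(1, math.ceil(e / l)) for e, l in zip(extent, size))
    return GridSpec(box.lower.copy(), size, counts)


def clip_length(p1, p2, box: AABB) -> float:
    """Length (μm) of the segment p1→p2 inside *box* (closed), exactly.

    Parametric slab clipping: the segment is x(t) = p1 + t·(p2 − p1),
    t ∈ [0, 1]; each axis contributes an admissible t-interval and the
    clipped length is the intersection's measure times the segment length.
    Zero-length segments contribute 0.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    d = p2 - p1
    seg_len = float(np.linalg.norm(d))
    if seg_len == 0.0:
        return 0.0
    t0, t1 = 0.0, 1.0
    for j in range(3):
        if d[j] == 0.0:
            if p1[j] < box.lower[j] or p1[j] > box.upper[j]:
                return 0.0
        else:
            ta = (box.lower[j] - p1[j]) / d[j]
            tb = (box.upper[j] - p1[j]) / d[j]
            if ta > tb:
                ta, tb = tb, ta
            t0 = max(t0, ta)
            t1 = min(t1, tb)
    return max(0.0, t1 - t0) * seg_len


def _deposit_edge(values: np.ndarray, p1: np.ndarray, p2: np.ndarray, grid: GridSpec) -> None:
    """Distribute one segment's in-grid length over the voxels it crosses.

    The segment is first clipped to the grid's outer box, then cut at every
    internal lattice plane it crosses; each sub-interval lies in exactly
    one voxel, identified by its midpoint (which realizes the
    higher-index-voxel tie-break for boundary-plane segments).
    """
    L = grid.lower
    l = grid.cuboid_size
    N = grid.counts
    d = p2 - p1
    seg_len = float(np.linalg.norm(d))
    if seg_len == 0.0:
        return
    U = grid.upper
    t0, t1 = 0.0, 1.0
    for j in range(3):
        if d[j] == 0.0:
            if p1[j] < L[j] or p1[j] > U[j]:
                return
        else:
            ta = (L[j] - p1[j]) / d[j]
            tb = (U[j] - p1[j]) / d[j]
            if ta > tb:
                ta, tb = tb, ta
            t0 = max(t0, ta)
            t1 = min(t1, tb)
    if t1 <= t0:
        return
    cuts = [t0, t1]
    for j in range(3):
        if d[j] == 0.0:
            continue
        a = p1[j] + t0 * d[j]
        b = p1[j] + t1 * d[j]
        lo, hi = (a, b) if a <= b else (b, a)
        k_lo = int(math.floor((lo - L[j]) / l[j]))
        k_hi = int(math.ceil((hi - L[j]) / l[j]))
        for k in range(max(k_lo, 0) + 1, min(k_hi, N[j]) + 1):
            t = (L[j] + k * l[j] - p1[j]) / d[j]
            if t0 < t < t1:
                cuts.append(t)
    cuts.sort()
    for ta, tb in zip(cuts[:-1], cuts[1:]):
        dt = tb - ta
        if dt <= 0.0:
            continue
        mid = p1 + (0.5 * (ta + tb)) * d
        idx = np.floor((mid - L) / l).astype(np.int64)
        idx = np.clip(idx, 0, np.asarray(N) - 1)
        values[idx[0], idx[1], idx[2]] += dt * seg_len


def raw_length_grid(m: Morphology, grid: GridSpec) -> np.ndarray:
    """Exact cable length (μm) per voxel; sums to the in-grid total length."""
    values = np.zeros(grid.shape, dtype=np.float64)
    child_pos, parent_pos, _ = m.edge_arrays()
    for p1, p2 in zip(parent_pos, child_pos):
        _deposit_edge(values, p1, p2, grid)
    return values


def neuron_density(
    m: Morphology, grid: GridSpec, norm_mode: str = "total_length"
) -> DensityField:
    """Per-neuron density field.

    ``total_length`` mode divides each voxel's raw cable length by the
    neuron's total cable length, so a fully contained cell's field sums to
    one; ``voxel_volume`` divides by l_x·l_y·l_z (μm⁻²).
    """
    raw = raw_length_grid(m, grid)
    if norm_mode == "total_length":
        from .geometry import total_length

        tl = total_length(m)
        if tl == 0.0:
            logger.warning(
                "%s: zero total cable length; per-neuron field is all zeros",
                m.name or "<unnamed>",
            )
            values = raw  # all zeros already
        else:
            values = raw / tl
    elif norm_mode == "voxel_volume":
        values = raw / grid.voxel_volume
    else:
        raise ValueError(f"unknown norm_mode {norm_mode!r}")
    return DensityField(grid, values, stage="per_neuron", norm_mode=norm_mode)


def combine(fields: list[DensityField]) -> DensityField:
    """Voxelwise sum of per-neuron fields, rescaled to peak at exactly 1.

    S(B) = Σ_i |B_i| over the n input neurons; the result is S/m with
    m = max_B S(B) (all zeros if m = 0).
    """
    if not fields:
        raise ValueError("combine needs at least one field")
    first = fields[0]
    for f in fields[1:]:
        if f.values.shape != first.values.shape or not np.array_equal(
            np.asarray(f.grid.counts), np.asarray(first.grid.counts)
        ):
            raise ValueError("fields must share one grid")
        if f.norm_mode != first.norm_mode:
            raise ValueError("fields must share one norm_mode")
        if not (
            np.allclose(f.grid.lower, first.grid.lower)
            and np.allclose(f.grid.cuboid_size, first.grid.cuboid_size)
        ):
            raise ValueError("fields must share one grid")
    total = np.zeros_like(first.values)
    for f in fields:
        total += f.values
    m = float(total.max()) if total.size else 0.0
    # x/x is exact in IEEE double, so the peak voxel is 1.0 exactly
    out = total / m if m > 0.0 else total
    return DensityField(first.grid, out, stage="normalized", norm_mode=first.norm_mode)


def threshold_mask(f: DensityField, min_density_pct: float) -> np.ndarray:
    """Boolean mask of voxels strictly above *min_density_pct* percent.

    At 0 % the mask keeps every voxel with a positive value.
    """
    if not 0.0 <= min_density_pct <= 100.0:
        raise ValueError("min_density_pct must be in [0, 100]")
    return f.values > (min_density_pct / 100.0)


def gaussian_kernel(sigma: float = 1.0, size: int = 5) -> np.ndarray:
    """Separable 3D Gaussian stencil (σ in voxels), renormalized to sum 1."""
    if size % 2 == 0 or size < 1:
        raise ValueError("kernel size must be odd and positive")
    x = np.arange(size) - size // 2
    g = np.exp(-0.5 * (x / sigma) ** 2)
    k = g[:, None, None] * g[None, :, None] * g[None, None, :]
    return k / k.sum()


def blur(f: DensityField, kernel: np.ndarray | None = None) -> DensityField:
    """Convolve the field with a 3D stencil (reflective boundaries).

    Default stencil: separable Gaussian, σ = 1 voxel, 5³ support, sum 1.
    The maximum of a normalized field may drop below 1; it is NOT
    re-normalized (logged).
    """
    if kernel is None:
        kernel = gaussian_kernel()
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.ndim != 3 or any(s % 2 == 0 for s in kernel.shape):
        raise ValueError("kernel must be 3D with odd side lengths")
    if not np.all(np.isfinite(kernel)):
        raise ValueError("kernel must be finite")
    out = ndimage.convolve(f.values, kernel, mode="reflect")
    out = np.maximum(out, 0.0)  # guard tiny negative round-off
    if f.stage == "normalized" and out.size and out.max() < 1.0:
        logger.info("blur: field maximum dropped to %.6g (not re-normalized)", out.max())
    return DensityField(f.grid, out, stage=f.stage, norm_mode=f.norm_mode)


# ---------------------------------------------------------------------------
# Field container I/O: a .npy array plus a versioned JSON sidecar, so fields
# are diffable in tests and portable between runs.


def save_field(f: DensityField, basepath: str | Path) -> tuple[Path, Path]:
    """Write ``<basepath>.npy`` and ``<basepath>.json``; returns both paths."""
    base = Path(basepath)
    npy = base.with_suffix(".npy")
    meta = base.with_suffix(".json")
    np.save(npy, f.values)
    sidecar = {
        "format": FIELD_FORMAT,
        "version": FIELD_VERSION,
        "lower": [float(v) for v in f.grid.lower],
        "cuboid_size": [float(v) for v in f.grid.cuboid_size],
        "counts": list(f.grid.counts),
        "stage": f.stage,
        "norm_mode": f.norm_mode,
    }
    meta.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return npy, meta


def load_field(basepath: str | Path) -> DensityField:
    """Inverse of :func:`save_field`."""
    base = Path(basepath)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    if sidecar.get("format") != FIELD_FORMAT:
        raise ValueError(f"{base}: not a {FIELD_FORMAT} sidecar")
    grid = GridSpec(
        np.array(sidecar["lower"]),
        np.array(sidecar["cuboid_size"]),
        tuple(sidecar["counts"]),
    )
    values = np.load(base.with_suffix(".npy"))
    return DensityField(grid, values, stage=sidecar["stage"], norm_mode=sidecar["norm_mode"])
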