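"""Static rendering: two-color density heatmaps, profile line charts.

The density colormap interpolates linearly between a color for zero
density and a color for unit density (defaults blue → red); voxels below
the minimum-density threshold become fully transparent. The plane
convention matches the projection module, with y drawn increasing upward
(pia up in the layered fixtures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless backend; rendering is file output only
import matplotlib.pyplot as plt
import numpy as np
from PIL import Image

from .morphology import Scene
from .projection import PlaneImage, Profile, _PLANES

logger = logging.getLogger(__name__)

__all__ = [
    "ColorMapSpec",
    "map_color",
    "heatmap_rgba",
    "render_heatmap",
    "render_profiles",
]


@dataclass(frozen=True)
class ColorMapSpec:
    """Two-color density coding: color0 at density 0, color1 at density 1."""

    color0: tuple[int, int, int] = (0, 0, 255)   # blue
    color1: tuple[int, int, int] = (255, 0, 0)   # red
    transparency: float = 0.0                    # 0 = opaque
    min_density_pct: float = 0.0

    def __post_init__(self) -> None:
        for c in (*self.color0, *self.color1):
            if not 0 <= c <= 255:
                raise ValueError("color components must be in [0, 255]")
        if not 0.0 <= self.transparency <= 1.0:
            raise ValueError("transparency must be in [0, 1]")
        if not 0.0 <= self.min_density_pct <= 100.0:
            raise ValueError("min_density_pct must be in [0, 100]")


def map_color(value: float, spec: ColorMapSpec = ColorMapSpec()) -> tuple[float, float, float, float]:
    """Linear two-color blend of a density value in [0, 1] → (R, G, B, A).

    RGB channels are floats in [0, 255] (unquantized); alpha is in [0, 1]
    and is zero for values below the minimum-density threshold.
    Out-of-range values are clamped with a warning.
    """
    if not 0.0 <= value <= 1.0:
        logger.warning("map_color: value %.4g outside [0, 1], clamped", value)
        value = min(max(value, 0.0), 1.0)
    c0 = np.asarray(spec.color0, dtype=np.float64)
    c1 = np.asarray(spec.color1, dtype=np.float64)
    rgb = c0 + value * (c1 - c0)
    alpha = 0.0 if value < spec.min_density_pct / 100.0 else 1.0 - spec.transparency
    return (float(rgb[0]), float(rgb[1]), float(rgb[2]), float(alpha))


def heatmap_rgba(img: PlaneImage, spec: ColorMapSpec = ColorMapSpec()) -> np.ndarray:
    """Pixel-exact RGBA (uint8) array of a plane raster, one pixel per bin.

    The raster is renormalized to [0, 1] if its maximum exceeds 1 (logged).
    Row 0 of the output is the TOP of the image (largest second-axis
    coordinate), so y increases upward.
    """
    raster = img.raster
    vmax = raster.max() if raster.size else 0.0
    if vmax > 1.0:
        logger.info("heatmap: raster max %.4g > 1, renormalizing for display", vmax)
        raster = raster / vmax
    c0 = np.asarray(spec.color0, dtype=np.float64)
    c1 = np.asarray(spec.color1, dtype=np.float64)
    vals = raster.T[::-1]  # (v, u) with v decreasing downward
    rgb = c0[None, None, :] + vals[..., None] * (c1 - c0)[None, None, :]
    alpha = np.where(
        vals < spec.min_density_pct / 100.0, 0.0, 1.0 - spec.transparency
    )
    out = np.empty(vals.shape + (4,), dtype=np.uint8)
    out[..., :3] = np.rint(rgb).astype(np.uint8)
    out[..., 3] = np.rint(alpha * 255).astype(np.uint8)
    return out


def _overlay_segments_2d(scene: Scene, plane: str) -> list[np.ndarray]:
    """Morphology edges and contour polylines projected into plane coords."""
    a, b = _PLANES[plane]
    polylines: list[np.ndarray] = []
    for m in scene.morphologies:
        child_pos, parent_pos, _ = m.edge_arrays()
        for p, c in zip(parent_pos, child_pos):
            polylines.append(np.array([[p[a], p[b]], [c[a], c[b]]]))
    for contour in scene.contours:
        pts = contour.points[:, [a, b]]
        if contour.closed:
            pts = np.vstack([pts, pts[:1]])
        polylines.append(pts)
    return polylines


def render_heatmap(
    img: PlaneImage,
    spec: ColorMapSpec = ColorMapSpec(),
    overlays: Scene | None = None,
    path: str | Path = "heatmap.png",
    scalebar: bool = True,
    upscale: int = 1,
) -> None:
    """Write a plane-density heatmap to PNG/JPEG/TIFF/GIF.

    Without overlays or a scale bar the output is pixel-exact: one image
    pixel block per density bin (nearest-neighbour *upscale*). With
    decorations, the heatmap is drawn through matplotlib in physical μm
    coordinates with overlay polylines and a scale bar.
    """
    path = Path(path)
    rgba = heatmap_rgba(img, spec)
    if overlays is None and not scalebar:
        if upscale > 1:
            rgba = np.kron(rgba, np.ones((upscale, upscale, 1), dtype=np.uint8))
        _save_rgba(rgba, path)
        return
    nu, nv = img.raster.shape
    extent = (
        float(img.origin[0]),
        float(img.origin[0] + nu * img.pixel_size[0]),
        float(img.origin[1]),
        float(img.origin[1] + nv * img.pixel_size[1]),
    )
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(rgba, extent=extent, origin="upper", interpolation="nearest", aspect="equal")
    if overlays is not None:
        for line in _overlay_segments_2d(overlays, img.plane):
            ax.plot(line[:, 0], line[:, 1], color="black", linewidth=0.8)
    if scalebar:
        span = extent[1] - extent[0]
        bar = 10.0 ** np.floor(np.log10(max(span / 3.0, 1e-12)))
        x0 = extent[0] + 0.05 * span
        y0 = extent[2] + 0.05 * (extent[3] - extent[2])
        ax.plot([x0, x0 + bar], [y0, y0], color="black", linewidth=3)
        ax.annotate(
            f"{bar:g} μm", (x0, y0), textcoords="offset points", xytext=(0, 4)
        )
    ax.set_xlabel(f"{img.axes_labels[0]} (μm)")
    ax.set_ylabel(f"{img.axes_labels[1]} (μm)")
    _savefig(fig, path)


def _save_rgba(rgba: np.ndarray, path: Path) -> None:
    image = Image.fromarray(rgba, mode="RGBA")
    fmt = path.suffix.lower()
    if fmt in (".jpg", ".jpeg"):
        image = image.convert("RGB")  # JPEG has no alpha
    elif fmt == ".gif":
        image = image.convert("P")
    image.save(path)


def _savefig(fig, path: Path) -> None:
    fmt = path.suffix.lower()
    if fmt == ".gif":  # matplotlib cannot write GIF directly
        from io import BytesIO

        buf = BytesIO()
        fig.savefig(buf, format="png", dpi=100)
        plt.close(fig)
        buf.seek(0)
        Image.open(buf).convert("P").save(path)
    else:
        fig.savefig(path, dpi=100)
        plt.close(fig)


def render_profiles(
    profiles: list[Profile],
    combined: bool = False,
    path: str | Path = "profile.png",
) -> list[Path]:
    """Line charts of 1D density profiles.

    ``combined=True`` draws all profiles into one chart with a legend;
    otherwise one file per profile, suffixed ``_<axis>``. Returns the
    written paths.
    """
    if not profiles:
        raise ValueError("render_profiles needs at least one profile")
    path = Path(path)
    written: list[Path] = []
    if combined:
        fig, ax = plt.subplots(figsize=(6, 4))
        for p in profiles:
            ax.plot(p.bin_centers, p.values, label=p.axis_label)
        ax.set_xlabel("position (μm)")
        ax.set_ylabel("density")
        ax.legend()
        _savefig(fig, path)
        written.append(path)
    else:
        for p in profiles:
            out = path.with_name(f"{path.stem}_{p.axis_label}{path.suffix}")
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.plot(p.bin_centers, p.values)
            ax.set_xlabel(f"{p.axis_label} (μm)")
            ax.set_ylabel("density")
            _savefig(fig, out)
            written.append(out)
    return written
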