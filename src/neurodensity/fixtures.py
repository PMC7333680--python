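"""Deterministic toy morphologies and scenes with closed-form geometry.

These generators stand in for traced cortical data: straight cables,
Y-shaped trees, seeded random arbors and a layered "consensus" scene with
L1–L6 and barrel contours. Every fixture's total cable length, bounding
box and (for the Y-tree) per-slab length masses are available in closed
form, so downstream modules can be tested against analytic oracles rather
than recorded outputs. Corpora are written as SWC plus the Neurolucida
XML/ASC dialects with a JSON metadata sidecar; identical parameters and
seed always reproduce byte-identical files.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .density import DensityField, GridSpec
from .io import write_swc
from .morphology import Contour, Morphology, Scene

__all__ = [
    "make_cable",
    "make_y_tree",
    "y_tree_slab_masses",
    "make_random_tree",
    "make_layered_consensus",
    "make_sphere_field",
    "write_xml_scene",
    "write_asc_scene",
    "write_corpus",
    "CORPUS_SPECS",
]

PRNG_IDENTITY = "numpy.random.Generator(PCG64)"


def make_cable(
    length: float,
    n_points: int,
    compartment: str = "dendrite",
    soma_root: bool = True,
) -> Morphology:
    """A straight cable along +y with uniform point spacing.

    The first point sits at the origin and is labeled soma when
    *soma_root* is set (it contributes position but no extra cable: the
    cable length is exactly *length*).
    """
    if n_points < 2:
        raise ValueError("n_points must be ≥ 2")
    if length <= 0:
        raise ValueError("length must be positive")
    ys = np.linspace(0.0, length, n_points)
    comps = [compartment] * n_points
    if soma_root:
        comps[0] = "soma"
    return Morphology(
        ids=np.arange(1, n_points + 1),
        positions=np.column_stack([np.zeros(n_points), ys, np.zeros(n_points)]),
        radii=np.full(n_points, 0.5),
        compartments=comps,
        parent_ids=np.r_[-1, np.arange(1, n_points)],
        name=f"cable{length:g}",
    )


def make_y_tree(
    trunk: float, branch: float, angle: float, compartment: str = "dendrite"
) -> Morphology:
    """Trunk along +y, then two branches symmetric about the y axis.

    *angle* (degrees) is the opening angle between the two branches, so
    each branch deviates angle/2 from the trunk direction. Total cable
    length is trunk + 2·branch; the y extent is trunk + branch·cos(angle/2).
    """
    if trunk <= 0 or branch <= 0:
        raise ValueError("trunk and branch lengths must be positive")
    if not 0.0 < angle < 180.0:
        raise ValueError("angle must lie in (0, 180) degrees")
    half = math.radians(angle) / 2.0
    top = np.array([0.0, trunk, 0.0])
    tip_l = top + branch * np.array([-math.sin(half), math.cos(half), 0.0])
    tip_r = top + branch * np.array([math.sin(half), math.cos(half), 0.0])
    return Morphology(
        ids=[1, 2, 3, 4],
        positions=np.array([[0.0, 0.0, 0.0], top, tip_l, tip_r]),
        radii=[1.0, 0.5, 0.5, 0.5],
        compartments=["soma", compartment, compartment, compartment],
        parent_ids=[-1, 1, 2, 2],
        name=f"ytree{trunk:g}_{branch:g}_{angle:g}",
    )


def y_tree_slab_masses(
    trunk: float, branch: float, angle: float, bin_edges: np.ndarray
) -> np.ndarray:
    """Closed-form cable mass of the Y-tree per y-slab.

    The trunk deposits 1 μm of cable per μm of y over [0, trunk]; the two
    branches together deposit 2/cos(angle/2) per μm over
    [trunk, trunk + branch·cos(angle/2)].
    """
    edges = np.asarray(bin_edges, dtype=np.float64)
    c = math.cos(math.radians(angle) / 2.0)
    y_top = trunk + branch * c

    def overlap(a, b, lo, hi):
        return max(0.0, min(b, hi) - max(a, lo))

    masses = np.zeros(len(edges) - 1)
    for k in range(len(masses)):
        a, b = edges[k], edges[k + 1]
        masses[k] = overlap(a, b, 0.0, trunk) + overlap(a, b, trunk, y_top) * 2.0 / c
    return masses


def make_random_tree(
    seed: int,
    depth: int = 4,
    mean_branch_len: float = 40.0,
    branch_prob: float = 0.7,
) -> Morphology:
    """A reproducible random arbor: soma plus axon and dendrite subtrees.

    Growth is recursive: from each node, one or (with probability
    *branch_prob*) two daughter segments of length uniform in
    [0.5, 1.5]·mean_branch_len extend in a perturbed direction, down to
    *depth* generations. depth = 0 yields the soma alone. Randomness comes
    from a seeded PCG64 generator, so regeneration is exact.
    """
    rng = np.random.default_rng(seed)
    positions = [np.zeros(3)]
    comps = ["soma"]
    parents = [-1]

    def grow(parent_idx: int, direction: np.ndarray, gen: int, comp: str) -> None:
        if gen <= 0:
            return
        n_children = 2 if rng.random() < branch_prob else 1
        for _ in range(n_children):
            d = direction + rng.normal(scale=0.4, size=3)
            d /= np.linalg.norm(d)
            length = rng.uniform(0.5, 1.5) * mean_branch_len
            positions.append(positions[parent_idx] + length * d)
            comps.append(comp)
            parents.append(parent_idx)
            grow(len(positions) - 1, d, gen - 1, comp)

    grow(0, np.array([0.0, 1.0, 0.0]), depth, "dendrite")
    grow(0, np.array([0.0, -1.0, 0.0]), depth, "axon")
    n = len(positions)
    return Morphology(
        ids=np.arange(1, n + 1),
        positions=np.array(positions),
        radii=np.full(n, 0.5),
        compartments=comps,
        parent_ids=[-1 if p == -1 else p + 1 for p in parents],
        name=f"rtree{seed}",
    )


def make_layered_consensus(
    layer_y_bounds,
    barrel_width: float,
    reference_point=(0.0, 0.0, 0.0),
    allowed_compartments=("soma", "axon", "dendrite", "apical"),
) -> Scene:
    """A consensus scene: one reference soma plus layer and barrel contours.

    *layer_y_bounds* (increasing, μm) delimit the cortical layers; k + 1
    bounds yield k rectangular contours named "L1".."Lk" in the z = 0
    plane, plus one "Barrel" contour of the given width spanning all
    layers. The scene carries one single-point stub morphology per allowed
    compartment — how a consensus file declares its compartment whitelist —
    and the first morphology's soma sits exactly at *reference_point*.
    """
    bounds = np.asarray(layer_y_bounds, dtype=np.float64)
    if len(bounds) < 2 or np.any(np.diff(bounds) <= 0):
        raise ValueError("layer_y_bounds must be ≥ 2 increasing values")
    if barrel_width <= 0:
        raise ValueError("barrel_width must be positive")
    ref = np.asarray(reference_point, dtype=np.float64)
    morphs = [
        Morphology(
            ids=[1],
            positions=ref.reshape(1, 3),
            radii=[5.0],
            compartments=["soma"],
            parent_ids=[-1],
            name="consensus_reference",
        )
    ]
    for i, comp in enumerate(c for c in allowed_compartments if c != "soma"):
        morphs.append(
            Morphology(
                ids=[1],
                positions=(ref + np.array([0.0, 1.0 + i, 0.0])).reshape(1, 3),
                radii=[0.5],
                compartments=[comp],
                parent_ids=[-1],
                name=f"consensus_allow_{comp}",
            )
        )
    half = barrel_width / 2.0
    contours = []
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        contours.append(
            Contour(
                name=f"L{i + 1}",
                points=np.array(
                    [[-half, lo, 0.0], [half, lo, 0.0], [half, hi, 0.0], [-half, hi, 0.0]]
                ),
                closed=True,
            )
        )
    contours.append(
        Contour(
            name="Barrel",
            points=np.array(
                [
                    [-half, bounds[0], 0.0],
                    [half, bounds[0], 0.0],
                    [half, bounds[-1], 0.0],
                    [-half, bounds[-1], 0.0],
                ]
            ),
            closed=True,
        )
    )
    return Scene(morphs, contours, source_format=None)


def make_sphere_field(
    shape=(20, 20, 20), cuboid_size=(1.0, 1.0, 1.0), radius: float | None = None
) -> DensityField:
    """A radially decaying normalized field: g(v) = max(0, 1 − ‖v − c‖/R).

    The center c is placed on a voxel center so the field maximum is
    exactly 1; the isovalue-q surface of the continuous field is the
    sphere of radius (1 − q)·R around c.
    """
    shape = tuple(int(s) for s in shape)
    grid = GridSpec(np.zeros(3), np.asarray(cuboid_size, dtype=np.float64), shape)
    if radius is None:
        radius = 0.4 * float(min(np.asarray(shape) * grid.cuboid_size))
    center_idx = np.array([s // 2 for s in shape])
    center = grid.lower + (center_idx + 0.5) * grid.cuboid_size
    dist = np.linalg.norm(grid.voxel_centers() - center, axis=1).reshape(shape)
    values = np.clip(1.0 - dist / radius, 0.0, None)
    f = DensityField(grid, values, stage="normalized", norm_mode="total_length")
    f.sphere_center = center  # analytic metadata for tests
    f.sphere_radius = radius
    return f


# ---------------------------------------------------------------------------
# Writers for the Neurolucida dialects (fixture emission only)


def _children_lists(m: Morphology) -> tuple[list[int], list[list[int]]]:
    idx = {int(v): i for i, v in enumerate(m.ids)}
    children: list[list[int]] = [[] for _ in range(len(m))]
    roots: list[int] = []
    for i, pid in enumerate(m.parent_ids):
        if pid == -1:
            roots.append(i)
        else:
            children[idx[int(pid)]].append(i)
    return roots, children


def _tree_type(m: Morphology, root: int, children) -> str:
    # use the first non-soma compartment below the root, else the root's
    stack = [root]
    while stack:
        i = stack.pop(0)
        if str(m.compartments[i]) != "soma":
            return str(m.compartments[i])
        stack.extend(children[i])
    return str(m.compartments[root])


def write_xml_scene(scene: Scene, path: str | Path) -> None:
    """Emit a scene in the tree/branch/point/contour XML dialect.

    One ``<tree>`` element per connected component; the tree's ``type``
    attribute carries a single compartment label (per-point labels are not
    representable in this dialect), and ``d`` attributes store diameters.
    """
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', '<mbf version="4.0">']

    def pt(i: int, m: Morphology, indent: str) -> str:
        x, y, z = (float(v) for v in m.positions[i])
        d = float(2 * m.radii[i])
        return f'{indent}<point x="{x!r}" y="{y!r}" z="{z!r}" d="{d!r}"/>'

    def emit(i: int, m: Morphology, children, indent: str) -> None:
        lines.append(pt(i, m, indent))
        ch = children[i]
        while len(ch) == 1:
            i = ch[0]
            lines.append(pt(i, m, indent))
            ch = children[i]
        for c in ch:
            lines.append(f"{indent}<branch>")
            emit(c, m, children, indent + "  ")
            lines.append(f"{indent}</branch>")

    for m in scene.morphologies:
        roots, children = _children_lists(m)
        for root in roots:
            ttype = _tree_type(m, root, children)
            lines.append(f'  <tree type="{ttype}" leaf="normal">')
            emit(root, m, children, "    ")
            lines.append("  </tree>")
    for c in scene.contours:
        closed = "true" if c.closed else "false"
        lines.append(f'  <contour name="{c.name}" closed="{closed}">')
        for p in c.points:
            x, y, z = (float(v) for v in p)
            lines.append(f'    <point x="{x!r}" y="{y!r}" z="{z!r}" d="1.0"/>')
        lines.append("  </contour>")
    lines.append("</mbf>")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_ASC_TREE_NAMES = {"dendrite": "Dendrite", "axon": "Axon", "apical": "Apical", "soma": "CellBody"}


def write_asc_scene(scene: Scene, path: str | Path) -> None:
    """Emit a scene in the parenthesized ASC dialect (fixture subset)."""
    lines = ["; neurodensity fixture (Neurolucida ASC subset)"]

    def pt(i: int, m: Morphology, indent: str) -> str:
        x, y, z = (float(v) for v in m.positions[i])
        return f"{indent}( {x!r} {y!r} {z!r} {float(2 * m.radii[i])!r} )"

    def emit(i: int, m: Morphology, children, indent: str) -> None:
        lines.append(pt(i, m, indent))
        ch = children[i]
        while len(ch) == 1:
            i = ch[0]
            lines.append(pt(i, m, indent))
            ch = children[i]
        if ch:
            lines.append(f"{indent}(")
            for k, c in enumerate(ch):
                if k:
                    lines.append(f"{indent}|")
                emit(c, m, children, indent + "  ")
            lines.append(f"{indent})")

    for m in scene.morphologies:
        roots, children = _children_lists(m)
        for root in roots:
            ttype = _tree_type(m, root, children)
            lines.append(f"({_ASC_TREE_NAMES.get(ttype, 'Dendrite')}")
            emit(root, m, children, "  ")
            lines.append(")")
    for c in scene.contours:
        lines.append(f'("{c.name}"')
        if c.closed:
            lines.append("  (Closed)")
        for p in c.points:
            x, y, z = (float(v) for v in p)
            lines.append(f"  ( {x!r} {y!r} {z!r} 1.0 )")
        lines.append(")")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Named corpora

CORPUS_SPECS = ("smoke", "formats", "random")


def write_corpus(spec_name: str, out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write a named fixture corpus; returns the files written.

    ``smoke``   — cable + Y-tree cells (SWC) and a layered consensus (XML).
    ``formats`` — one single-compartment cable emitted as SWC, XML and ASC.
    ``random``  — three seeded random arbors (SWC) plus the consensus.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    meta: dict = {"spec": spec_name, "seed": seed, "prng": PRNG_IDENTITY, "fixtures": {}}

    def add_swc(m: Morphology, name: str, extra: dict) -> None:
        p = out / f"{name}.swc"
        write_swc(m, p)
        files.append(p)
        meta["fixtures"][name] = extra

    if spec_name == "smoke":
        cable = make_cable(100.0, 11)
        add_swc(cable, "cable", {"total_length_um": 100.0, "bbox": [[0, 0, 0], [0, 100, 0]]})
        ytree = make_y_tree(50.0, 50.0, 90.0)
        add_swc(
            ytree,
            "ytree",
            {
                "total_length_um": 150.0,
                "y_extent_um": 50.0 + 50.0 * math.cos(math.radians(45.0)),
            },
        )
        consensus = make_layered_consensus([0, 100, 200, 300, 400, 500, 600], 300.0)
        p = out / "consensus.xml"
        write_xml_scene(consensus, p)
        files.append(p)
        meta["fixtures"]["consensus"] = {"reference_point": [0.0, 0.0, 0.0], "layers": 6}
    elif spec_name == "formats":
        cable = make_cable(100.0, 11, soma_root=False)
        for writer, ext in ((write_swc, "swc"), (None, "xml"), (None, "asc")):
            p = out / f"cable_dend.{ext}"
            if ext == "swc":
                write_swc(cable, p)
            elif ext == "xml":
                write_xml_scene(Scene([cable], []), p)
            else:
                write_asc_scene(Scene([cable], []), p)
            files.append(p)
        meta["fixtures"]["cable_dend"] = {"total_length_um": 100.0}
    elif spec_name == "random":
        for i in range(3):
            m = make_random_tree(seed + i)
            add_swc(m, f"rtree{i}", {"seed": seed + i, "n_vertices": len(m)})
        consensus = make_layered_consensus([0, 100, 200, 300, 400, 500, 600], 300.0)
        p = out / "consensus.xml"
        write_xml_scene(consensus, p)
        files.append(p)
    else:
        raise ValueError(
            f"unknown corpus spec {spec_name!r}; available: {', '.join(CORPUS_SPECS)}"
        )

    mp = out / "metadata.json"
    mp.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    files.append(mp)
    return files
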