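"""Shared in-memory model for neuronal reconstructions.

A reconstruction is a line graph: vertices carry a 3D position (μm), a
radius (μm, half the traced diameter) and a compartment label; each
non-root vertex stores the id of its parent, so the edge set is exactly
the set of (child, parent) links and the graph is a forest.

Compartment labels are canonicalized to the lowercase vocabulary
``{soma, axon, dendrite, apical, custom-N}`` so that filtering works
identically across input formats.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "MorphVertex",
    "Morphology",
    "Contour",
    "Scene",
    "canonical_compartment",
    "compartment_from_swc_code",
    "swc_code_for_compartment",
]

#: SWC integer type code → canonical compartment name.
SWC_CODE_TO_COMPARTMENT = {1: "soma", 2: "axon", 3: "dendrite", 4: "apical"}
COMPARTMENT_TO_SWC_CODE = {v: k for k, v in SWC_CODE_TO_COMPARTMENT.items()}

_CUSTOM_RE = re.compile(r"^custom-(\d+)$")

_NAME_ALIASES = {
    "soma": "soma",
    "cellbody": "soma",
    "cell body": "soma",
    "axon": "axon",
    "dendrite": "dendrite",
    "basal": "dendrite",
    "basal dendrite": "dendrite",
    "apical": "apical",
    "apical dendrite": "apical",
}


def canonical_compartment(name: str) -> str:
    """Map a free-form compartment name onto the canonical vocabulary."""
    key = name.strip().lower()
    if key in _NAME_ALIASES:
        return _NAME_ALIASES[key]
    if _CUSTOM_RE.match(key):
        return key
    return key  # unknown names pass through lowercased


def compartment_from_swc_code(code: int) -> str:
    """SWC type code → compartment label (0 and ≥5 become ``custom-N``)."""
    return SWC_CODE_TO_COMPARTMENT.get(code, f"custom-{code}")


def swc_code_for_compartment(comp: str, extra: dict[str, int] | None = None) -> int:
    """Compartment label → SWC type code.

    ``custom-N`` maps back to ``N``; other unknown names draw stable codes
    ≥ 5 from *extra* (which is updated in place).
    """
    comp = canonical_compartment(comp)
    if comp in COMPARTMENT_TO_SWC_CODE:
        return COMPARTMENT_TO_SWC_CODE[comp]
    m = _CUSTOM_RE.match(comp)
    if m:
        return int(m.group(1))
    if extra is None:
        raise ValueError(f"no SWC code for compartment {comp!r}")
    if comp not in extra:
        used = set(COMPARTMENT_TO_SWC_CODE.values()) | set(extra.values())
        code = 5
        while code in used:
            code += 1
        extra[comp] = code
    return extra[comp]


@dataclass(frozen=True)
class MorphVertex:
    """One traced point: id ≥ 1, position/radius in μm, parent id (−1 = root)."""

    id: int
    position: np.ndarray
    radius: float
    compartment: str
    parent_id: int


class Morphology:
    """A neuronal reconstruction stored struct-of-arrays.

    Parameters
    ----------
    ids : (n,) int array, each ≥ 1, unique.
    positions : (n, 3) float array, μm.
    radii : (n,) float array, μm, non-negative.
    compartments : sequence of n canonical compartment labels.
    parent_ids : (n,) int array; −1 for roots, otherwise an id that occurs
        *earlier* in the array (file order), which guarantees a forest.
    """

    def __init__(
        self,
        ids: Sequence[int],
        positions: np.ndarray,
        radii: Sequence[float],
        compartments: Sequence[str],
        parent_ids: Sequence[int],
        name: str = "",
        colors: dict[str, tuple[int, int, int]] | None = None,
    ):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.positions = np.asarray(positions, dtype=np.float64).reshape(-1, 3)
        self.radii = np.asarray(radii, dtype=np.float64)
        self.compartments = np.asarray(
            [canonical_compartment(c) for c in compartments], dtype=object
        )
        self.parent_ids = np.asarray(parent_ids, dtype=np.int64)
        self.name = name
        self.colors = dict(colors) if colors else {}
        self._validate()

    def _validate(self) -> None:
        n = len(self.ids)
        if not (
            len(self.positions) == len(self.radii)
            == len(self.compartments) == len(self.parent_ids) == n
        ):
            raise ValueError("morphology field lengths disagree")
        if n == 0:
            return
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite vertex position")
        if np.any(self.radii < 0):
            raise ValueError("negative radius")
        if np.any(self.ids < 1):
            raise ValueError("vertex ids must be ≥ 1")
        if len(np.unique(self.ids)) != n:
            raise ValueError("duplicate vertex ids")
        seen: set[int] = set()
        for vid, pid in zip(self.ids, self.parent_ids):
            if pid != -1 and pid not in seen:
                raise ValueError(f"vertex {vid}: parent {pid} not defined earlier")
            seen.add(int(vid))

    # -- views ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_vertices(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[MorphVertex]:
        for i in range(len(self.ids)):
            yield MorphVertex(
                int(self.ids[i]),
                self.positions[i],
                float(self.radii[i]),
                str(self.compartments[i]),
                int(self.parent_ids[i]),
            )

    @property
    def edges(self) -> list[tuple[int, int]]:
        """(child-id, parent-id) pairs, one per non-root vertex."""
        return [
            (int(c), int(p))
            for c, p in zip(self.ids, self.parent_ids)
            if p != -1
        ]

    def _index_of(self) -> dict[int, int]:
        return {int(v): i for i, v in enumerate(self.ids)}

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Edge endpoints as arrays.

        Returns ``(child_pos, parent_pos, child_index)`` with shapes
        (m, 3), (m, 3), (m,) where m is the number of edges.
        """
        idx = self._index_of()
        child = np.flatnonzero(self.parent_ids != -1)
        parent = np.array([idx[int(p)] for p in self.parent_ids[child]], dtype=np.int64)
        return self.positions[child], self.positions[parent], child

    @property
    def edge_compartments(self) -> np.ndarray:
        """Per-edge compartment label, taken from the CHILD vertex.

        Edges that straddle two compartments (e.g. soma→dendrite) are
        attributed to the child's compartment — the convention SWC itself
        uses for typed points.
        """
        return self.compartments[self.parent_ids != -1]

    def translate(self, delta: np.ndarray) -> "Morphology":
        """Return a copy rigidly shifted by *delta* (μm)."""
        return Morphology(
            self.ids.copy(),
            self.positions + np.asarray(delta, dtype=np.float64),
            self.radii.copy(),
            list(self.compartments),
            self.parent_ids.copy(),
            name=self.name,
            colors=self.colors,
        )

    @classmethod
    def from_vertices(
        cls, vertices: Iterable[MorphVertex], name: str = "", colors=None
    ) -> "Morphology":
        vs = list(vertices)
        return cls(
            [v.id for v in vs],
            np.array([v.position for v in vs], dtype=np.float64).reshape(-1, 3),
            [v.radius for v in vs],
            [v.compartment for v in vs],
            [v.parent_id for v in vs],
            name=name,
            colors=colors,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Morphology {self.name!r}: {len(self)} vertices, "
            f"{len(self.edges)} edges>"
        )


@dataclass
class Contour:
    """A named landmark polyline (layer border, barrel outline, ...)."""

    name: str
    points: np.ndarray  # (k, 3) μm
    closed: bool = True
    color: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValueError(f"contour {self.name!r} needs ≥ 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"contour {self.name!r} has non-finite points")


@dataclass
class Scene:
    """Morphologies plus landmark contours read from one source file."""

    morphologies: list[Morphology] = field(default_factory=list)
    contours: list[Contour] = field(default_factory=list)
    source_format: str | None = None  # swc | nlx_xml | nlx_asc

    def __post_init__(self) -> None:
        if not self.morphologies and not self.contours:
            raise ValueError("scene must contain at least one morphology or contour")
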