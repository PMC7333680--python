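"""Morphology-level geometry: cable lengths, bounding boxes, compartment
filtering, soma centroids, and consensus alignment.

Alignment is a pure translation that moves a cell's soma centroid onto the
reference soma of a consensus scene; nothing is rotated or scaled, so all
pairwise distances and cable lengths are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .morphology import Morphology, Scene, canonical_compartment

logger = logging.getLogger(__name__)

__all__ = [
    "AABB",
    "total_length",
    "bounding_box",
    "filter_compartments",
    "soma_centroid",
    "align_to_consensus",
    "consensus_compartments",
    "EmptySelectionError",
]


class EmptySelectionError(ValueError):
    """A filter left nothing to operate on."""


@dataclass(frozen=True)
class AABB:
    """Axis-aligned bounding box, lower/upper corners in μm."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=np.float64))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=np.float64))
        if self.lower.shape != (3,) or self.upper.shape != (3,):
            raise ValueError("AABB corners must be 3-vectors")
        if np.any(self.lower > self.upper):
            raise ValueError("AABB lower corner exceeds upper corner")

    @property
    def extent(self) -> np.ndarray:
        return self.upper - self.lower


def _include_set(include) -> set[str] | None:
    if include is None:
        return None
    s = {canonical_compartment(c) for c in include}
    if not s:
        raise ValueError("include set must be non-empty")
    return s


def total_length(m: Morphology, include: Iterable[str] | None = None) -> float:
    """Total cable length in μm: sum of Euclidean edge lengths.

    With *include*, only edges whose BOTH endpoints carry an included
    compartment label contribute. An empty selection yields 0.
    """
    if len(m) == 0:
        return 0.0
    child_pos, parent_pos, child_idx = m.edge_arrays()
    if len(child_idx) == 0:
        return 0.0
    if include is not None:
        inc = _include_set(include)
        idx_map = m._index_of()
        keep = []
        for i, ci in enumerate(child_idx):
            pi = idx_map[int(m.parent_ids[ci])]
            keep.append(
                str(m.compartments[ci]) in inc and str(m.compartments[pi]) in inc
            )
        keep = np.asarray(keep, dtype=bool)
        child_pos, parent_pos = child_pos[keep], parent_pos[keep]
    if len(child_pos) == 0:
        return 0.0
    return float(np.linalg.norm(child_pos - parent_pos, axis=1).sum())


def bounding_box(
    scene: Scene | Morphology,
    include: Iterable[str] | None = None,
    with_contours: bool = False,
) -> AABB:
    """Componentwise min/max over all (included) vertices of the scene.

    Contours are excluded unless *with_contours* is set.
    """
    morphologies = (
        [scene] if isinstance(scene, Morphology) else list(scene.morphologies)
    )
    inc = _include_set(include) if include is not None else None
    chunks = []
    for m in morphologies:
        pos = m.positions
        if inc is not None:
            mask = np.array([str(c) in inc for c in m.compartments], dtype=bool)
            pos = pos[mask]
        if len(pos):
            chunks.append(pos)
    if with_contours and isinstance(scene, Scene):
        chunks.extend(c.points for c in scene.contours)
    if not chunks:
        raise EmptySelectionError("no vertices selected for bounding box")
    allpos = np.vstack(chunks)
    return AABB(allpos.min(axis=0), allpos.max(axis=0))


def filter_compartments(m: Morphology, exclude: Iterable[str]) -> Morphology:
    """Drop vertices whose compartment is in *exclude* (and incident edges).

    Children of removed vertices become roots, so the result may be a
    forest with more components than the input.
    """
    exc = {canonical_compartment(c) for c in exclude}
    if not exc:
        return m
    keep = np.array([str(c) not in exc for c in m.compartments], dtype=bool)
    kept_ids = set(int(v) for v in m.ids[keep])
    parents = [
        int(p) if int(p) in kept_ids else -1 for p in m.parent_ids[keep]
    ]
    return Morphology(
        m.ids[keep],
        m.positions[keep],
        m.radii[keep],
        list(m.compartments[keep]),
        parents,
        name=m.name,
        colors=m.colors,
    )


def soma_centroid(m: Morphology) -> np.ndarray:
    """Arithmetic mean of the soma vertices' positions (μm).

    Falls back (with a warning) to the first root vertex when the cell has
    no soma points at all.
    """
    if len(m) == 0:
        raise ValueError("empty morphology has no soma centroid")
    mask = np.array([c == "soma" for c in m.compartments], dtype=bool)
    if mask.any():
        return m.positions[mask].mean(axis=0)
    roots = np.flatnonzero(m.parent_ids == -1)
    logger.warning(
        "%s: no soma vertices; using root vertex as reference", m.name or "<unnamed>"
    )
    return m.positions[roots[0]].copy()


def consensus_reference_point(consensus: Scene) -> np.ndarray:
    """The consensus scene's reference point: its first morphology's soma."""
    if not consensus.morphologies:
        raise ValueError("consensus scene has no reference morphology")
    return soma_centroid(consensus.morphologies[0])


def align_to_consensus(m: Morphology, consensus: Scene) -> Morphology:
    """Translate *m* so its soma centroid lands on the consensus reference.

    Pure translation — radii, topology and pairwise distances unchanged.
    """
    delta = consensus_reference_point(consensus) - soma_centroid(m)
    return m.translate(delta)


def consensus_compartments(consensus: Scene) -> set[str]:
    """Compartment whitelist declared by a consensus scene.

    The compartments present in the consensus reference morphologies define
    which compartments take part in density computation.
    """
    comps: set[str] = set()
    for m in consensus.morphologies:
        comps.update(str(c) for c in m.compartments)
    return comps
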