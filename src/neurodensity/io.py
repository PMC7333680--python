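"""Readers for SWC, Neurolucida XML and Neurolucida ASC reconstructions.

All readers produce the shared :class:`~neurodensity.morphology.Morphology`
/ :class:`~neurodensity.morphology.Scene` model. Coordinates are μm in the
file's own right-handed frame (no axis flipping); Neurolucida ``d``
attributes are diameters and are halved into radii on import.

Only trees, branches, points and contours of the Neurolucida dialects are
interpreted; markers, spines and image references are skipped with a
logged count. XML files with a missing or corrupt declaration are repaired
before parsing (declaration prepended, multiple roots wrapped), mirroring
the auto-correction behaviour users expect from tracing-suite exports.
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .morphology import (
    Contour,
    Morphology,
    Scene,
    canonical_compartment,
    compartment_from_swc_code,
    swc_code_for_compartment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_swc",
    "write_swc",
    "read_neurolucida_xml",
    "read_asc",
    "detect_format",
    "read_any",
    "MorphologyParseError",
    "UnsupportedFormatError",
]


class MorphologyParseError(ValueError):
    """A reconstruction file could not be parsed."""


class UnsupportedFormatError(ValueError):
    """The file is not in a supported reconstruction format."""


def _read_text(path: str | Path) -> str:
    data = Path(path).read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


# ---------------------------------------------------------------------------
# SWC


def read_swc(path: str | Path) -> Morphology:
    """Read a 7-column SWC file into a :class:`Morphology`.

    Columns are ``id type x y z radius parent``; ``#`` lines are comments.
    Type codes map 1→soma, 2→axon, 3→dendrite, 4→apical, anything else
    →``custom-N``.
    """
    path = Path(path)
    ids, pos, radii, comps, parents = [], [], [], [], []
    for lineno, raw in enumerate(_read_text(path).splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise MorphologyParseError(
                f"{path}:{lineno}: expected 7 fields, got {len(fields)}"
            )
        try:
            vid = int(fields[0])
            code = int(fields[1])
            x, y, z, r = (float(v) for v in fields[2:6])
            pid = int(fields[6])
        except ValueError as exc:
            raise MorphologyParseError(f"{path}:{lineno}: {exc}") from exc
        ids.append(vid)
        pos.append((x, y, z))
        radii.append(r)
        comps.append(compartment_from_swc_code(code))
        parents.append(pid)
    if not ids:
        raise MorphologyParseError(f"{path}: no data records (empty input)")
    try:
        return Morphology(ids, np.array(pos), radii, comps, parents, name=path.stem)
    except ValueError as exc:
        raise MorphologyParseError(f"{path}: {exc}") from exc


def write_swc(m: Morphology, path: str | Path) -> None:
    """Write *m* as standard SWC, ids renumbered 1..n in file order.

    File order already satisfies parents-before-children, so the renumbering
    is a relabeling only. Floats are written with ``repr`` so a re-read
    reproduces the exact double values (write∘read is a fixed point).
    """
    path = Path(path)
    old_to_new = {int(v): i + 1 for i, v in enumerate(m.ids)}
    extra_codes: dict[str, int] = {}
    lines = ["# SWC written by neurodensity", "# id type x y z radius parent"]
    for i in range(len(m)):
        code = swc_code_for_compartment(str(m.compartments[i]), extra_codes)
        pid = int(m.parent_ids[i])
        new_pid = -1 if pid == -1 else old_to_new[pid]
        x, y, z = (float(v) for v in m.positions[i])
        lines.append(
            f"{i + 1} {code} {x!r} {y!r} {z!r} {float(m.radii[i])!r} {new_pid}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Neurolucida XML

_XML_DECL_RE = re.compile(r"^\s*<\?xml[^>]*\?>")


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1].lower()


def _repair_xml(text: str) -> str:
    """Best-effort repair of a missing/corrupt XML header or multiple roots."""
    body = text
    # drop everything before the first element
    lt = body.find("<")
    if lt > 0:
        body = body[lt:]
    if _XML_DECL_RE.match(body):
        body = _XML_DECL_RE.sub("", body, count=1)
    # wrap in a synthetic root; harmless if a single root already exists
    return '<?xml version="1.0" encoding="UTF-8"?>\n<mbf>' + body + "</mbf>"


def _parse_color(value: str | None) -> tuple[int, int, int] | None:
    if not value:
        return None
    v = value.strip().lstrip("#")
    if len(v) == 6:
        try:
            return tuple(int(v[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]
        except ValueError:
            return None
    return None


def _xml_points(elem) -> list[tuple[float, float, float, float]]:
    pts = []
    for child in elem:
        if _strip_ns(child.tag) == "point":
            pts.append(
                (
                    float(child.get("x", "0")),
                    float(child.get("y", "0")),
                    float(child.get("z", "0")),
                    float(child.get("d", "0")),
                )
            )
    return pts


def _walk_tree(elem, verts, parent_idx, comp):
    """Depth-first over point/branch children, appending to *verts*.

    Branch nesting becomes parent links: a branch's first point attaches to
    the last point seen in the enclosing scope.
    """
    last = parent_idx
    for child in elem:
        tag = _strip_ns(child.tag)
        if tag == "point":
            verts.append(
                (
                    float(child.get("x", "0")),
                    float(child.get("y", "0")),
                    float(child.get("z", "0")),
                    float(child.get("d", "0")) / 2.0,
                    comp,
                    last,
                )
            )
            last = len(verts) - 1
        elif tag == "branch":
            _walk_tree(child, verts, last, comp)


def read_neurolucida_xml(path: str | Path) -> Scene:
    """Read the tree/contour subset of a Neurolucida XML export.

    Each ``<tree>`` becomes one :class:`Morphology`; ``<contour>`` elements
    become :class:`Contour` objects. Unknown elements (markers, spines,
    images) are counted and skipped. If the document fails to parse as-is,
    a repaired copy (declaration prepended, roots wrapped) is tried before
    giving up.
    """
    path = Path(path)
    text = _read_text(path)
    try:
        root = ET.fromstring(text)
    except ET.ParseError:
        logger.warning("%s: malformed XML, attempting auto-correction", path)
        try:
            root = ET.fromstring(_repair_xml(text))
        except ET.ParseError as exc:
            raise MorphologyParseError(f"{path}: unrecoverable XML: {exc}") from exc

    morphologies: list[Morphology] = []
    contours: list[Contour] = []
    skipped = 0
    elements = [root] if _strip_ns(root.tag) in ("tree", "contour") else list(root.iter())
    tree_no = 0
    for elem in elements:
        tag = _strip_ns(elem.tag)
        if tag == "tree":
            tree_no += 1
            comp = canonical_compartment(elem.get("type", elem.get("leaf", "dendrite")))
            color = _parse_color(elem.get("color"))
            verts: list[tuple] = []
            _walk_tree(elem, verts, -1, comp)
            if not verts:
                logger.warning("%s: tree #%d has no points, skipped", path, tree_no)
                continue
            n = len(verts)
            morphologies.append(
                Morphology(
                    ids=list(range(1, n + 1)),
                    positions=np.array([v[:3] for v in verts]),
                    radii=[v[3] for v in verts],
                    compartments=[v[4] for v in verts],
                    parent_ids=[-1 if v[5] == -1 else v[5] + 1 for v in verts],
                    name=f"{path.stem}.tree{tree_no}",
                    colors={comp: color} if color else None,
                )
            )
        elif tag == "contour":
            pts = _xml_points(elem)
            if len(pts) < 2:
                logger.warning("%s: contour with < 2 points skipped", path)
                continue
            contours.append(
                Contour(
                    name=elem.get("name", "contour"),
                    points=np.array([p[:3] for p in pts]),
                    closed=elem.get("closed", "true").lower() in ("true", "1", "yes"),
                    color=_parse_color(elem.get("color")),
                )
            )
        elif tag in ("marker", "spine", "image", "images"):
            skipped += 1
    if skipped:
        logger.info("%s: skipped %d unsupported element(s)", path, skipped)
    if not morphologies and not contours:
        raise MorphologyParseError(f"{path}: no trees or contours found")
    return Scene(morphologies, contours, source_format="nlx_xml")


# ---------------------------------------------------------------------------
# Neurolucida ASC (s-expression dialect)

_TREE_KEYWORDS = {
    "dendrite": "dendrite",
    "axon": "axon",
    "apical": "apical",
    "cellbody": "soma",
    "soma": "soma",
}


def _tokenize_asc(text: str):
    """Yield (token, offset) over the parenthesized ASC dialect.

    Tokens: ``(``, ``)``, ``|``, quoted strings, bare atoms. ``;`` starts a
    comment to end of line.
    """
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c in " \t\r\n":
            i += 1
        elif c == ";":
            j = text.find("\n", i)
            i = n if j == -1 else j + 1
        elif c in "()|":
            yield c, i
            i += 1
        elif c == '"':
            j = text.find('"', i + 1)
            if j == -1:
                raise MorphologyParseError(f"unterminated string at offset {i}")
            yield text[i : j + 1], i
            i = j + 1
        else:
            j = i
            while j < n and text[j] not in ' \t\r\n()|";':
                j += 1
            yield text[i:j], i
            i = j


def _parse_sexprs(text: str):
    """Parse the token stream into nested lists of atoms."""
    stack: list[list] = [[]]
    depth_pos: list[int] = []
    for tok, pos in _tokenize_asc(text):
        if tok == "(":
            stack.append([])
            depth_pos.append(pos)
        elif tok == ")":
            if len(stack) < 2:
                raise MorphologyParseError(
                    f"unbalanced ')' at offset {pos}"
                )
            done = stack.pop()
            depth_pos.pop()
            stack[-1].append(done)
        else:
            stack[-1].append(tok)
    if len(stack) != 1:
        raise MorphologyParseError(
            f"unbalanced '(' at offset {depth_pos[-1]}"
        )
    return stack[0]

def _is_number(tok) -> bool:
    if not isinstance(tok, str):
        return False
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _is_point(node) -> bool:
    return (
        isinstance(node, list)
        and 3 <= len(node) <= 4
        and all(_is_number(t) for t in node)
    )


def _point_xyzd(node) -> tuple[float, float, float, float]:
    vals = [float(t) for t in node]
    if len(vals) == 3:
        vals.append(0.0)
    return tuple(vals)  # type: ignore[return-value]


def _asc_tree_walk(items, verts, parent_idx, comp):
    """Recursive descent over a tree block body.

    Point tuples extend the current neurite; a sub-list containing points
    or further sub-lists is a branch group whose ``|``-separated segments
    all attach to the current tip.
    """
    last = parent_idx
    for node in items:
        if _is_point(node):
            x, y, z, d = _point_xyzd(node)
            verts.append((x, y, z, d / 2.0, comp, last))
            last = len(verts) - 1
        elif isinstance(node, list):
            # split on '|' into sibling branches
            segments: list[list] = [[]]
            for sub in node:
                if sub == "|":
                    segments.append([])
                else:
                    segments[-1].append(sub)
            for seg in segments:
                if seg:
                    _asc_tree_walk(seg, verts, last, comp)
        # bare atoms (directives) are skipped by the caller's policy


def read_asc(path: str | Path) -> Scene:
    """Read the contour/tree subset of a Neurolucida ASC file."""
    path = Path(path)
    try:
        blocks = _parse_sexprs(_read_text(path))
    except MorphologyParseError as exc:
        raise MorphologyParseError(f"{path}: {exc}") from exc

    morphologies: list[Morphology] = []
    contours: list[Contour] = []
    tree_no = 0
    for block in blocks:
        if not isinstance(block, list) or not block:
            continue
        head = block[0]
        if isinstance(head, str) and head.startswith('"'):
            # named contour block
            name = head.strip('"')
            closed = True
            pts = []
            for node in block[1:]:
                if _is_point(node):
                    pts.append(_point_xyzd(node)[:3])
                elif isinstance(node, list) and node and node[0] == "Closed":
                    closed = True
            if len(pts) >= 2:
                contours.append(Contour(name=name, points=np.array(pts), closed=closed))
            else:
                logger.warning("%s: contour %r with < 2 points skipped", path, name)
        elif isinstance(head, str) and head.lower() in _TREE_KEYWORDS:
            tree_no += 1
            comp = _TREE_KEYWORDS[head.lower()]
            verts: list[tuple] = []
            _asc_tree_walk(block[1:], verts, -1, comp)
            if not verts:
                logger.warning("%s: empty %s block skipped", path, head)
                continue
            n = len(verts)
            morphologies.append(
                Morphology(
                    ids=list(range(1, n + 1)),
                    positions=np.array([v[:3] for v in verts]),
                    radii=[v[3] for v in verts],
                    compartments=[v[4] for v in verts],
                    parent_ids=[-1 if v[5] == -1 else v[5] + 1 for v in verts],
                    name=f"{path.stem}.tree{tree_no}",
                )
            )
        else:
            logger.warning("%s: unknown directive %r skipped", path, head)
    if not morphologies and not contours:
        raise MorphologyParseError(f"{path}: no trees or contours found")
    return Scene(morphologies, contours, source_format="nlx_asc")


# ---------------------------------------------------------------------------
# Format detection

_EXT_TO_FORMAT = {".swc": "swc", ".xml": "nlx_xml", ".asc": "nlx_asc"}


def _looks_like_swc(text: str) -> bool:
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            return False
        try:
            int(fields[0]); float(fields[2]); int(fields[6])
        except ValueError:
            return False
        return True
    return False


def detect_format(path: str | Path) -> str:
    """Classify *path* as ``swc`` | ``nlx_xml`` | ``nlx_asc``.

    Extension wins; extensionless or unknown extensions fall back to
    content sniffing. ``.dat`` (the Neurolucida binary container) is
    rejected explicitly as unsupported.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".dat":
        raise UnsupportedFormatError(f"{path}: DAT format is not supported")
    if ext in _EXT_TO_FORMAT:
        return _EXT_TO_FORMAT[ext]
    text = _read_text(path)
    stripped = text.lstrip()
    if stripped.startswith("<"):
        return "nlx_xml"
    if stripped.startswith("(") or stripped.startswith(";"):
        return "nlx_asc"
    if _looks_like_swc(text):
        return "swc"
    raise UnsupportedFormatError(f"{path}: cannot determine reconstruction format")


def read_any(path: str | Path) -> Scene:
    """Read any supported reconstruction file into a :class:`Scene`."""
    fmt = detect_format(path)
    if fmt == "swc":
        return Scene([read_swc(path)], [], source_format="swc")
    if fmt == "nlx_xml":
        return read_neurolucida_xml(path)
    return read_asc(path)
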