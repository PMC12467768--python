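"""Reading and writing tangram figures and encoding matrices.

Figure JSON format::

    {"figure_id": "fig1", "pieces": [{"vertices": [[x, y], ...]}, x7]}

Coordinates are arbitrary planar units; orientation does not matter because
the encoding is similarity-invariant.  Piece identities are not stored: they
are reassigned on read from shape (triangle vs quadrilateral), area ranking
and a right-angle test, with A/B within the identical pairs fixed by
lexicographic centroid order.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .geometry import (
    CANONICAL_ORDER,
    CAEMatrix,
    InvalidPieceError,
    Piece,
    PieceType,
    TangramFigure,
    _signed_area,
)

__all__ = [
    "assign_piece_identities",
    "read_figure",
    "write_figure",
    "read_cae_csv",
    "write_cae_csv",
    "FigureFormatError",
]


class FigureFormatError(ValueError):
    """File does not describe a 7-piece tangram figure."""


def _is_right_angled(vertices: np.ndarray, rtol: float = 1e-3) -> bool:
    """True when every corner of the quadrilateral is (near) 90 degrees."""
    n = len(vertices)
    for i in range(n):
        a = vertices[(i - 1) % n] - vertices[i]
        b = vertices[(i + 1) % n] - vertices[i]
        cosang = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        if cosang > rtol:
            return False
    return True


def assign_piece_identities(
    polygons: list[np.ndarray], strict_ratios: bool = False, area_rtol: float = 1e-2
) -> list[Piece]:
    """Label 7 raw polygons with canonical piece identities.

    Triangles are ranked by area into large/medium/small; quadrilaterals are
    split into square vs parallelogram by a right-angle test.  A/B twins are
    ordered by lexicographic centroid (x, then y).
    """
    if len(polygons) != 7:
        raise FigureFormatError(f"expected 7 polygons, got {len(polygons)}")
    tris, quads = [], []
    for poly in polygons:
        v = np.asarray(poly, dtype=float)
        if _signed_area(v) < 0:
            v = v[::-1].copy()
        if v.shape[0] == 3:
            tris.append(v)
        elif v.shape[0] == 4:
            quads.append(v)
        else:
            raise FigureFormatError(
                f"polygon with {v.shape[0]} vertices is not a tangram piece"
            )
    if len(tris) != 5 or len(quads) != 2:
        raise FigureFormatError(
            f"expected 5 triangles and 2 quadrilaterals, got {len(tris)}/{len(quads)}"
        )
    tris.sort(key=lambda v: -abs(_signed_area(v)))
    larges, medium, smalls = tris[:2], tris[2], tris[3:]
    right = [_is_right_angled(q) for q in quads]
    if right[0] == right[1]:
        raise FigureFormatError(
            "cannot distinguish square from parallelogram (right-angle test tied)"
        )
    square = quads[0] if right[0] else quads[1]
    para = quads[1] if right[0] else quads[0]

    def _centroid_key(v: np.ndarray) -> tuple[float, float]:
        c = v.mean(axis=0)
        return (float(c[0]), float(c[1]))

    larges.sort(key=_centroid_key)
    smalls.sort(key=_centroid_key)
    pieces = [
        Piece(PieceType.LARGE_A, larges[0]),
        Piece(PieceType.LARGE_B, larges[1]),
        Piece(PieceType.MEDIUM, medium),
        Piece(PieceType.SMALL_A, smalls[0]),
        Piece(PieceType.SMALL_B, smalls[1]),
        Piece(PieceType.SQUARE, square),
        Piece(PieceType.PARALLELOGRAM, para),
    ]
    areas = {p.piece_id: p.area for p in pieces}
    small_mean = (areas[PieceType.SMALL_A] + areas[PieceType.SMALL_B]) / 2
    ratios = {
        PieceType.LARGE_A: 4,
        PieceType.LARGE_B: 4,
        PieceType.MEDIUM: 2,
        PieceType.SQUARE: 2,
        PieceType.PARALLELOGRAM: 2,
    }
    for pid, rel in ratios.items():
        expected = rel * small_mean
        if abs(areas[pid] - expected) > area_rtol * expected:
            msg = (
                f"{pid.value} area {areas[pid]:.4g} violates canonical tangram "
                f"ratios (expected {expected:.4g})"
            )
            if strict_ratios:
                raise FigureFormatError(msg)
            warnings.warn(msg, stacklevel=2)
    return pieces


def read_figure(path: str | Path, format: str | None = None) -> TangramFigure:
    """Read a figure from JSON or SVG; identities assigned from geometry."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        return _read_json(path)
    if fmt == "svg":
        return _read_svg(path)
    raise FigureFormatError(f"unsupported figure format: {fmt!r}")


def _read_json(path: Path) -> TangramFigure:
    with open(path) as fh:
        payload = json.load(fh)
    try:
        raw = [np.asarray(p["vertices"], dtype=float) for p in payload["pieces"]]
        figure_id = payload.get("figure_id", path.stem)
    except (KeyError, TypeError) as exc:
        raise FigureFormatError(f"{path}: malformed figure JSON: {exc}") from exc
    return TangramFigure(figure_id=figure_id, pieces=assign_piece_identities(raw))


def _svg_path_to_vertices(d: str) -> np.ndarray:
    """Parse an SVG path of straight segments (M/L/H/V/Z, absolute or relative)."""
    import re

    tokens = re.findall(r"[MmLlHhVvZz]|-?\d*\.?\d+(?:[eE][-+]?\d+)?", d)
    pts: list[list[float]] = []
    cur = [0.0, 0.0]
    cmd = None
    i = 0
    while i < len(tokens):
        t = tokens[i]
        if t.isalpha():
            cmd = t
            i += 1
            if cmd in "Zz":
                break
            continue
        if cmd in ("M", "L"):
            cur = [float(t), float(tokens[i + 1])]
            i += 2
        elif cmd in ("m", "l"):
            cur = [cur[0] + float(t), cur[1] + float(tokens[i + 1])]
            i += 2
        elif cmd == "H":
            cur = [float(t), cur[1]]
            i += 1
        elif cmd == "h":
            cur = [cur[0] + float(t), cur[1]]
            i += 1
        elif cmd == "V":
            cur = [cur[0], float(t)]
            i += 1
        elif cmd == "v":
            cur = [cur[0], cur[1] + float(t)]
            i += 1
        else:
            raise FigureFormatError(f"unsupported SVG path command {cmd!r}")
        pts.append(list(cur))
    v = np.asarray(pts, dtype=float)
    if len(v) > 1 and np.allclose(v[0], v[-1]):
        v = v[:-1]
    return v


def _read_svg(path: Path) -> TangramFigure:
    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = {"svg": root.nsmap.get(None, "http://www.w3.org/2000/svg")}
    raw: list[np.ndarray] = []
    for el in root.iter():
        tag = etree.QName(el).localname
        if tag == "polygon":
            nums = [float(x) for x in el.get("points").replace(",", " ").split()]
            raw.append(np.asarray(nums, dtype=float).reshape(-1, 2))
        elif tag == "path":
            raw.append(_svg_path_to_vertices(el.get("d")))
    if len(raw) != 7:
        raise FigureFormatError(f"{path}: expected 7 polygons in SVG, found {len(raw)}")
    return TangramFigure(figure_id=path.stem, pieces=assign_piece_identities(raw))


def write_figure(fig: TangramFigure, path: str | Path) -> None:
    """Write a figure to JSON (pieces in canonical order)."""
    payload = {
        "figure_id": fig.figure_id,
        "pieces": [{"vertices": p.vertices.tolist()} for p in fig.pieces],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


_HEADER = [t.value for t in CANONICAL_ORDER]


def write_cae_csv(matrix: CAEMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.weights, index=_HEADER, columns=_HEADER)
    df.to_csv(path)


def read_cae_csv(path: str | Path) -> CAEMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.columns) != _HEADER:
        raise FigureFormatError(f"{path}: unexpected CAE CSV header {list(df.columns)}")
    return CAEMatrix(weights=df.to_numpy(dtype=int), figure_id=Path(path).stem)
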