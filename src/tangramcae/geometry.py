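"""Tangram figures and their cognitive-associative encoding.

A tangram is built from seven fixed pieces (two large, one medium and two
small right isosceles triangles, a square and a parallelogram) that may touch
along their boundaries but never overlap in their interiors.  The
cognitive-associative encoding (CAE) summarizes one figure as a symmetric
7 x 7 integer matrix: the entry for a piece pair is one of six boundary
relation codes,

    0  no overlap (no boundary contact)
    1  complete line overlap   (two edges coincide entirely)
    2  partial line overlap    (collinear edges share a sub-segment)
    3  line containment        (one edge lies strictly inside the other)
    4  point-line contact      (a vertex touches the interior of an edge)
    5  point overlap           (two vertices coincide)

ordered by decreasing tightness of the coupling.  Because the codes depend
only on incidence structure, the encoding is invariant under translation,
rotation and uniform scaling of the figure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from itertools import combinations

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "PieceType",
    "RelationCode",
    "Piece",
    "TangramFigure",
    "CAEMatrix",
    "CANONICAL_ORDER",
    "CANONICAL_SHAPES",
    "classify_relationship",
    "encode",
    "default_tolerance",
    "canonicalize_weights",
    "transform_figure",
    "InvalidPieceError",
    "InvalidConfigurationError",
]


class PieceType(str, Enum):
    """The seven canonical tangram piece identities."""

    LARGE_A = "large_triangle_a"
    LARGE_B = "large_triangle_b"
    MEDIUM = "medium_triangle"
    SMALL_A = "small_triangle_a"
    SMALL_B = "small_triangle_b"
    SQUARE = "square"
    PARALLELOGRAM = "parallelogram"


#: Fixed axis order of the 7x7 encoding matrix.
CANONICAL_ORDER: tuple[PieceType, ...] = (
    PieceType.LARGE_A,
    PieceType.LARGE_B,
    PieceType.MEDIUM,
    PieceType.SMALL_A,
    PieceType.SMALL_B,
    PieceType.SQUARE,
    PieceType.PARALLELOGRAM,
)

#: Canonical vertex lists (counter-clockwise, arbitrary planar units).
#: Areas follow the tangram ratios: large 8, medium 4, small 2, square 4,
#: parallelogram 4 (large:medium:small = 4:2:1; square = parallelogram =
#: the small-triangle pair).
CANONICAL_SHAPES: dict[PieceType, np.ndarray] = {
    PieceType.LARGE_A: np.array([(0.0, 0.0), (4.0, 0.0), (0.0, 4.0)]),
    PieceType.LARGE_B: np.array([(0.0, 0.0), (4.0, 0.0), (0.0, 4.0)]),
    PieceType.MEDIUM: np.array([(0.0, 0.0), (4.0, 0.0), (2.0, 2.0)]),
    PieceType.SMALL_A: np.array([(0.0, 0.0), (2.0, 0.0), (0.0, 2.0)]),
    PieceType.SMALL_B: np.array([(0.0, 0.0), (2.0, 0.0), (0.0, 2.0)]),
    PieceType.SQUARE: np.array([(0.0, 0.0), (2.0, 0.0), (2.0, 2.0), (0.0, 2.0)]),
    PieceType.PARALLELOGRAM: np.array(
        [(0.0, 0.0), (2.0, 0.0), (4.0, 2.0), (2.0, 2.0)]
    ),
}

#: Expected piece area relative to a small triangle.
RELATIVE_AREAS: dict[PieceType, float] = {
    PieceType.LARGE_A: 4.0,
    PieceType.LARGE_B: 4.0,
    PieceType.MEDIUM: 2.0,
    PieceType.SMALL_A: 1.0,
    PieceType.SMALL_B: 1.0,
    PieceType.SQUARE: 2.0,
    PieceType.PARALLELOGRAM: 2.0,
}


class RelationCode(IntEnum):
    """Boundary relation between two pieces."""

    NO_OVERLAP = 0
    COMPLETE_LINE_OVERLAP = 1
    PARTIAL_LINE_OVERLAP = 2
    LINE_CONTAINMENT = 3
    POINT_LINE_CONTACT = 4
    POINT_OVERLAP = 5


class InvalidPieceError(ValueError):
    """A polygon is degenerate, self-intersecting, or has wrong arity."""


class InvalidConfigurationError(ValueError):
    """Piece interiors overlap beyond tolerance."""


_TRIANGLES = {
    PieceType.LARGE_A,
    PieceType.LARGE_B,
    PieceType.MEDIUM,
    PieceType.SMALL_A,
    PieceType.SMALL_B,
}


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Piece:
    """One labeled tangram piece: an identity plus CCW vertex coordinates."""

    piece_id: PieceType
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidPieceError(f"{self.piece_id}: vertices must be (n, 2)")
        expected = 3 if self.piece_id in _TRIANGLES else 4
        if v.shape[0] != expected:
            raise InvalidPieceError(
                f"{self.piece_id}: expected {expected} vertices, got {v.shape[0]}"
            )
        if _signed_area(v) < 0:  # normalize to CCW
            v = v[::-1].copy()
        self.vertices = v
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0.0:
            raise InvalidPieceError(f"{self.piece_id}: degenerate or self-intersecting")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return _signed_area(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(self.polygon.centroid.coords[0])

    def edges(self) -> list[tuple[np.ndarray, np.ndarray]]:
        v = self.vertices
        return [(v[i], v[(i + 1) % len(v)]) for i in range(len(v))]

    def edge_lengths(self) -> np.ndarray:
        return np.array([np.linalg.norm(b - a) for a, b in self.edges()])


@dataclass
class TangramFigure:
    """Seven pieces, one per canonical identity, with disjoint interiors."""

    figure_id: str
    pieces: list[Piece]

    def __post_init__(self) -> None:
        ids = [p.piece_id for p in self.pieces]
        if sorted(ids, key=lambda t: t.value) != sorted(
            CANONICAL_ORDER, key=lambda t: t.value
        ):
            raise InvalidConfigurationError(
                f"{self.figure_id}: need each canonical piece exactly once, got {ids}"
            )
        # keep pieces in canonical axis order
        by_id = {p.piece_id: p for p in self.pieces}
        self.pieces = [by_id[t] for t in CANONICAL_ORDER]

    def piece(self, piece_id: PieceType) -> Piece:
        return self.pieces[CANONICAL_ORDER.index(piece_id)]

    @property
    def all_vertices(self) -> np.ndarray:
        return np.vstack([p.vertices for p in self.pieces])

    def bounding_box_diagonal(self) -> float:
        v = self.all_vertices
        return float(np.linalg.norm(v.max(axis=0) - v.min(axis=0)))

    def validate(self, tol: float | None = None, area_rtol: float = 1e-3) -> None:
        """Check disjoint interiors and canonical area ratios.

        Raises :class:`InvalidConfigurationError` for interior overlap;
        emits a warning when relative areas stray from the tangram ratios
        by more than ``area_rtol``.
        """
        tol = tol if tol is not None else default_tolerance(self)
        polys = [p.polygon for p in self.pieces]
        for (i, a), (j, b) in combinations(enumerate(polys), 2):
            inter = _interior_overlap_area(a, b, tol)
            if inter > tol * min(a.area, b.area):
                raise InvalidConfigurationError(
                    f"{self.figure_id}: pieces {self.pieces[i].piece_id.value} and "
                    f"{self.pieces[j].piece_id.value} overlap (area {inter:.3g})"
                )
        small = np.mean(
            [self.piece(t).area for t in (PieceType.SMALL_A, PieceType.SMALL_B)]
        )
        for p in self.pieces:
            expected = RELATIVE_AREAS[p.piece_id] * small
            if abs(p.area - expected) > area_rtol * expected:
                warnings.warn(
                    f"{self.figure_id}: {p.piece_id.value} area {p.area:.4g} deviates "
                    f"from canonical ratio (expected {expected:.4g})",
                    stacklevel=2,
                )


@dataclass
class CAEMatrix:
    """The 7x7 symmetric integer relation matrix of one figure."""

    weights: np.ndarray
    tolerance: float = 1e-9
    figure_id: str | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=int)
        if w.shape != (7, 7):
            raise ValueError(f"CAEMatrix must be 7x7, got {w.shape}")
        if not np.array_equal(w, w.T):
            raise ValueError("CAEMatrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("CAEMatrix diagonal must be zero")
        if w.min() < 0 or w.max() > 5:
            raise ValueError("CAEMatrix entries must lie in 0..5")
        self.weights = w

    def upper_triangle(self) -> np.ndarray:
        """The 21 pairwise codes, row-major above the diagonal."""
        iu = np.triu_indices(7, k=1)
        return self.weights[iu]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CAEMatrix):
            return NotImplemented
        return np.array_equal(self.weights, other.weights)


def default_tolerance(fig: TangramFigure) -> float:
    """Scale-free coincidence tolerance: 1e-6 x bounding-box diagonal."""
    return 1e-6 * fig.bounding_box_diagonal()


# ---------------------------------------------------------------------------
# pairwise relation classification


def _interior_overlap_area(pa: Polygon, pb: Polygon, tol: float) -> float:
    """Intersection area of the tol-eroded interiors.

    Eroding both polygons before intersecting makes the test robust to
    boundary contact: polygons sharing an edge whose coordinates differ in
    the last few ulps can otherwise make the geometry engine report a
    spurious full-containment intersection.
    """
    ea = pa.buffer(-tol)
    eb = pb.buffer(-tol)
    if ea.is_empty or eb.is_empty:
        return 0.0
    return ea.intersection(eb).area


def _project(points: np.ndarray, origin: np.ndarray, direction: np.ndarray):
    return (points - origin) @ direction


def _edge_pair_code(
    p1: np.ndarray, p2: np.ndarray, q1: np.ndarray, q2: np.ndarray, tol: float
) -> int | None:
    """Relation contributed by one pair of collinear overlapping edges.

    Returns 1/2/3 per the shared-segment rule, or ``None`` when the edges are
    not collinear or share no positive-length segment.
    """
    d = p2 - p1
    lp = np.linalg.norm(d)
    if lp <= tol:
        return None
    u = d / lp
    n = np.array([-u[1], u[0]])
    # both endpoints of (q1,q2) must lie on the support line of (p1,p2)
    if abs((q1 - p1) @ n) > tol or abs((q2 - p1) @ n) > tol:
        return None
    a0, a1 = 0.0, lp
    b0, b1 = sorted((_project(q1[None], p1, u)[0], _project(q2[None], p1, u)[0]))
    lq = b1 - b0
    lo, hi = max(a0, b0), min(a1, b1)
    overlap = hi - lo
    if overlap <= tol:
        return None
    eq_p = overlap >= lp - tol
    eq_q = overlap >= lq - tol
    if eq_p and eq_q:
        return int(RelationCode.COMPLETE_LINE_OVERLAP)
    if eq_q and b0 > a0 + tol and b1 < a1 - tol:
        return int(RelationCode.LINE_CONTAINMENT)
    if eq_p and a0 > b0 + tol and a1 < b1 - tol:
        return int(RelationCode.LINE_CONTAINMENT)
    return int(RelationCode.PARTIAL_LINE_OVERLAP)


def _point_segment_distance(
    pts: np.ndarray, s1: np.ndarray, s2: np.ndarray
) -> np.ndarray:
    d = s2 - s1
    denom = float(d @ d)
    if denom == 0.0:
        return np.linalg.norm(pts - s1, axis=1)
    t = np.clip((pts - s1) @ d / denom, 0.0, 1.0)
    proj = s1 + t[:, None] * d
    return np.linalg.norm(pts - proj, axis=1)


def classify_relationship(a: Piece, b: Piece, tol: float = 1e-9) -> RelationCode:
    """Classify the boundary relation between two non-overlapping pieces.

    When several relations hold at distinct contact loci, the lowest nonzero
    code is reported: line-based contact (1-3) is the tighter cognitive
    coupling and dominates point-based contact (4-5).
    """
    pa, pb = a.polygon, b.polygon
    if pa.area <= 0 or pb.area <= 0:
        raise InvalidPieceError("degenerate piece")
    inter = _interior_overlap_area(pa, pb, tol)
    if inter > tol * min(pa.area, pb.area):
        raise InvalidConfigurationError(
            f"interiors of {a.piece_id.value} and {b.piece_id.value} overlap "
            f"(area {inter:.3g})"
        )

    candidates: set[int] = set()
    # line-type relations from collinear edge pairs
    for e1, e2 in a.edges():
        for f1, f2 in b.edges():
            code = _edge_pair_code(e1, e2, f1, f2, tol)
            if code is not None:
                candidates.add(code)
    # point-type relations from vertex contacts
    for va, vb, first in ((a.vertices, b.vertices, a), (b.vertices, a.vertices, b)):
        other = b if first is a else a
        for v in va:
            near_vertex = np.any(np.linalg.norm(vb - v, axis=1) <= tol)
            if near_vertex:
                candidates.add(int(RelationCode.POINT_OVERLAP))
                continue
            for s1, s2 in other.edges():
                dist = _point_segment_distance(v[None], s1, s2)[0]
                if dist <= tol:
                    candidates.add(int(RelationCode.POINT_LINE_CONTACT))
                    break
    if not candidates:
        return RelationCode.NO_OVERLAP
    return RelationCode(min(candidates))


# ---------------------------------------------------------------------------
# figure-level encoding

# the 4 permutations swapping within identical piece pairs (axis indices)
_IDENTITY = (0, 1, 2, 3, 4, 5, 6)
PERMUTATION_GROUP: tuple[tuple[int, ...], ...] = (
    _IDENTITY,
    (1, 0, 2, 3, 4, 5, 6),
    (0, 1, 2, 4, 3, 5, 6),
    (1, 0, 2, 4, 3, 5, 6),
)


def _permute(weights: np.ndarray, perm: tuple[int, ...]) -> np.ndarray:
    idx = np.asarray(perm)
    return weights[np.ix_(idx, idx)]


def canonicalize_weights(weights: np.ndarray) -> np.ndarray:
    """Pick the lexicographically smallest matrix over the identical-pair swaps.

    The two large triangles (and the two small ones) are physically
    interchangeable, so the raw matrix is only defined up to swapping their
    rows/columns; canonicalization makes the encoding a well-defined function
    of the figure, independent of which twin was labeled "A".
    """
    best = None
    for perm in PERMUTATION_GROUP:
        cand = _permute(weights, perm)
        key = tuple(cand.ravel())
        if best is None or key < best[0]:
            best = (key, cand)
    return best[1]


def encode(
    fig: TangramFigure,
    tol: float | None = None,
    validate: bool = True,
    canonicalize: bool = True,
) -> CAEMatrix:
    """Compute the cognitive-associative encoding of a figure.

    The result is invariant under global translation, rotation and uniform
    scaling (the tolerance scales with the figure's bounding box), and under
    relabeling within the identical large- and small-triangle pairs.
    """
    tol = tol if tol is not None else default_tolerance(fig)
    if validate:
        fig.validate(tol=tol)
    w = np.zeros((7, 7), dtype=int)
    for (i, pi), (j, pj) in combinations(enumerate(fig.pieces), 2):
        try:
            code = classify_relationship(pi, pj, tol)
        except (InvalidPieceError, InvalidConfigurationError) as exc:
            raise type(exc)(
                f"{fig.figure_id}: pair ({pi.piece_id.value}, {pj.piece_id.value}): {exc}"
            ) from exc
        w[i, j] = w[j, i] = int(code)
    if canonicalize:
        w = canonicalize_weights(w)
    return CAEMatrix(weights=w, tolerance=tol, figure_id=fig.figure_id)


# ---------------------------------------------------------------------------
# similarity transforms


def transform_figure(
    fig: TangramFigure,
    rotation: float = 0.0,
    scale: float = 1.0,
    translation: tuple[float, float] = (0.0, 0.0),
    figure_id: str | None = None,
) -> TangramFigure:
    """Apply a similarity transform (rotation in radians, uniform scale > 0)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    c, s = np.cos(rotation), np.sin(rotation)
    rot = np.array([[c, -s], [s, c]])
    t = np.asarray(translation, dtype=float)
    pieces = [
        Piece(p.piece_id, (p.vertices @ rot.T) * scale + t) for p in fig.pieces
    ]
    return TangramFigure(figure_id=figure_id or fig.figure_id, pieces=pieces)
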