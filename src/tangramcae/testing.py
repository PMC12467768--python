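"""Independent brute-force oracles used to cross-check the fast predicates.

The boundary-sampling oracle classifies the contact between two pieces by
densely sampling edge boundaries, measuring which samples of one edge lie on
the other, and reading the relation off the dimension (point vs segment) and
extent (full edge / strict sub-edge / partial) of the contact set.  It shares
no code with :func:`tangramcae.geometry.classify_relationship`, which
reasons analytically about projected edge intervals.
"""

from __future__ import annotations

import numpy as np

from .geometry import Piece, RelationCode

__all__ = ["classify_relationship_oracle", "OracleMarginalCase"]


class OracleMarginalCase(Exception):
    """Contact geometry too close to a category boundary to sample reliably."""


def _sample_edge(a: np.ndarray, b: np.ndarray, spacing: float) -> np.ndarray:
    n = max(int(np.ceil(np.linalg.norm(b - a) / spacing)) + 1, 3)
    t = np.linspace(0.0, 1.0, n)
    return a + t[:, None] * (b - a)[None]


def _dist_to_segment(points: np.ndarray, s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    d = s2 - s1
    denom = float(d @ d)
    if denom == 0.0:
        return np.linalg.norm(points - s1, axis=1)
    t = np.clip((points - s1) @ d / denom, 0.0, 1.0)
    proj = s1 + t[:, None] * d
    return np.linalg.norm(points - proj, axis=1)


def _edges_of(p: Piece) -> list[tuple[np.ndarray, np.ndarray, float]]:
    v = p.vertices
    out = []
    for i in range(len(v)):
        a, b = v[i], v[(i + 1) % len(v)]
        out.append((a, b, float(np.linalg.norm(b - a))))
    return out


def _contact_interval(
    host: tuple[np.ndarray, np.ndarray, float],
    guest: tuple[np.ndarray, np.ndarray, float],
    spacing: float,
    contact_tol: float,
) -> tuple[float, float] | None:
    """Extent (lo, hi) along the host edge of samples lying on the guest edge.

    Returns None when fewer than a handful of consecutive samples touch,
    i.e. the contact is point-like at sampling resolution.
    """
    a, b, length = host
    pts = _sample_edge(a, b, spacing)
    mask = _dist_to_segment(pts, guest[0], guest[1]) <= contact_tol
    if not mask.any():
        return None
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    run = max(runs, key=len)
    step = length / (len(pts) - 1)
    if (run[-1] - run[0]) * step <= 3 * step:
        return None
    return (run[0] * step, run[-1] * step)


def classify_relationship_oracle(
    a: Piece, b: Piece, tol: float, spacing: float | None = None
) -> RelationCode:
    """Boundary-sampling reclassification of the relation between two pieces.

    For every edge pair the shared boundary set is measured from both sides
    by dense sampling.  A positive-length shared segment yields code 1 when
    it exhausts both edges, 3 when it exhausts exactly one edge strictly
    inside the other, and 2 otherwise.  Point-like contacts are classified
    as vertex-vertex (5) or vertex-on-edge (4) directly from the vertex
    lists.  The lowest nonzero code across all contact loci is returned,
    mirroring the documented precedence rule.
    """
    scale = float(np.abs(np.vstack([a.vertices, b.vertices])).max()) or 1.0
    if spacing is None:
        spacing = scale / 2000.0
    contact_tol = 2.0 * tol
    if spacing < 8 * contact_tol:
        spacing = 8 * contact_tol  # keep runs distinguishable from point hits
    slack = 4 * spacing

    candidates: set[int] = set()
    for host in _edges_of(a):
        for guest in _edges_of(b):
            on_host = _contact_interval(host, guest, spacing, contact_tol)
            on_guest = _contact_interval(guest, host, spacing, contact_tol)
            if on_host is None or on_guest is None:
                continue
            o_host = on_host[1] - on_host[0]
            o_guest = on_guest[1] - on_guest[0]
            if abs(o_host - o_guest) > 2 * slack:
                raise OracleMarginalCase(
                    f"inconsistent shared-segment extents {o_host:.4g}/{o_guest:.4g}"
                )
            full_host = o_host >= host[2] - slack
            full_guest = o_guest >= guest[2] - slack
            strict_in_host = on_host[0] > slack and on_host[1] < host[2] - slack
            strict_in_guest = on_guest[0] > slack and on_guest[1] < guest[2] - slack
            if full_host and full_guest:
                candidates.add(int(RelationCode.COMPLETE_LINE_OVERLAP))
            elif (full_guest and strict_in_host) or (full_host and strict_in_guest):
                candidates.add(int(RelationCode.LINE_CONTAINMENT))
            else:
                candidates.add(int(RelationCode.PARTIAL_LINE_OVERLAP))

    for first, second in ((a, b), (b, a)):
        sec_edges = _edges_of(second)
        for v in first.vertices:
            if np.linalg.norm(second.vertices - v, axis=1).min() <= contact_tol:
                candidates.add(int(RelationCode.POINT_OVERLAP))
                continue
            if min(
                _dist_to_segment(v[None], s1, s2)[0] for s1, s2, _ in sec_edges
            ) <= contact_tol:
                candidates.add(int(RelationCode.POINT_LINE_CONTACT))

    if not candidates:
        return RelationCode.NO_OVERLAP
    return RelationCode(min(candidates))
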