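"""Synthetic inputs with known ground truth for every stage of the pipeline.

Four generators:

* figures — place the seven pieces so that the encoding equals a requested
  relation template (forest-shaped contact graphs are realized
  constructively; cyclic templates and geometrically impossible codes are
  flagged unsatisfiable);
* annotations — label distributions with planted animacy (animate-word
  fraction) and abstraction (label diversity) truths;
* epochs — colored-noise EEG with planted condition-dependent
  spatiotemporal components and optional familiarity modulation;
* behavior — lognormal response times with planted dimension, repetition
  and change-of-mind effects.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dimensions import ANIMATE_LEXICON
from .geometry import (
    CANONICAL_ORDER,
    CANONICAL_SHAPES,
    CAEMatrix,
    InvalidConfigurationError,
    Piece,
    PieceType,
    TangramFigure,
    canonicalize_weights,
    classify_relationship,
    encode,
    transform_figure,
)
from .metrics import cae_distance, classical_mds
from .preprocessing import EpochSet

__all__ = [
    "ConstructiveFailureError",
    "SimFigureSpec",
    "SimComponent",
    "SimEEGSpec",
    "SimBehaviorSpec",
    "satisfiable_codes",
    "random_template",
    "gen_figures",
    "gen_annotations",
    "make_schedule",
    "gen_epochs",
    "gen_behavior",
]


class ConstructiveFailureError(RuntimeError):
    """The requested relation template cannot be realized geometrically."""


# ---------------------------------------------------------------------------
# relation templates

_EDGE_LEN_EPS = 1e-9


def _edge_lengths(piece_type: PieceType) -> np.ndarray:
    v = CANONICAL_SHAPES[piece_type]
    return np.array(
        [np.linalg.norm(v[(i + 1) % len(v)] - v[i]) for i in range(len(v))]
    )


def satisfiable_codes(a: PieceType, b: PieceType) -> tuple[int, ...]:
    """Relation codes geometrically realizable for a piece-type pair.

    Code 1 (complete line overlap) needs a common edge length; code 3 (line
    containment) needs two strictly different edge lengths.  Codes 2, 4, 5
    are always realizable.
    """
    la, lb = _edge_lengths(a), _edge_lengths(b)
    codes = [2, 4, 5]
    if np.any(np.abs(la[:, None] - lb[None]) < _EDGE_LEN_EPS):
        codes.append(1)
    if np.any(np.abs(la[:, None] - lb[None]) > 0.1):
        codes.append(3)
    return tuple(sorted(codes))


def _capacity_ok(template: np.ndarray, node: int) -> bool:
    """Conservative attachment-site accounting for one piece.

    Line contacts occupy an edge (complete overlap also pins both of its
    endpoints, partial/containment roughly one); point-line contacts occupy
    an edge interior; vertex contacts occupy a free vertex.
    """
    n_sites = len(CANONICAL_SHAPES[CANONICAL_ORDER[node]])  # edges == vertices
    codes = [int(template[node, j]) for j in range(7) if template[node, j]]
    n_line = sum(c in (1, 2, 3) for c in codes)
    n_pl = sum(c == 4 for c in codes)
    n_vv = sum(c == 5 for c in codes)
    used_vertices = 2 * sum(c in (1, 3) for c in codes) + sum(c == 2 for c in codes)
    return (n_line + n_pl) <= n_sites and (used_vertices + n_vv) <= n_sites


def _has_cycle(template: np.ndarray) -> bool:
    parent = list(range(7))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(7):
        for j in range(i + 1, 7):
            if template[i, j] != 0:
                ri, rj = find(i), find(j)
                if ri == rj:
                    return True
                parent[ri] = rj
    return False


def check_template(template: np.ndarray) -> None:
    """Raise :class:`ConstructiveFailureError` for unsatisfiable templates."""
    t = np.asarray(template, dtype=int)
    if t.shape != (7, 7) or not np.array_equal(t, t.T) or np.any(np.diag(t)):
        raise ConstructiveFailureError("template must be symmetric 7x7, zero diagonal")
    if t.min() < 0 or t.max() > 5:
        raise ConstructiveFailureError("template codes must lie in 0..5")
    for i in range(7):
        for j in range(i + 1, 7):
            code = t[i, j]
            if code and code not in satisfiable_codes(
                CANONICAL_ORDER[i], CANONICAL_ORDER[j]
            ):
                raise ConstructiveFailureError(
                    f"code {code} unsatisfiable for pair "
                    f"({CANONICAL_ORDER[i].value}, {CANONICAL_ORDER[j].value})"
                )
    if _has_cycle(t):
        raise ConstructiveFailureError(
            "cyclic contact graphs are not constructible by sequential placement"
        )
    for node in range(7):
        if not _capacity_ok(t, node):
            raise ConstructiveFailureError(
                f"{CANONICAL_ORDER[node].value} has more contacts than "
                "attachment sites"
            )


def random_template(
    rng: np.random.Generator, density: float = 0.3
) -> np.ndarray:
    """Sample a satisfiable forest-shaped relation template.

    ``density`` is the target fraction of the 21 piece pairs carrying a
    nonzero code; a forest on 7 pieces caps the count at 6 edges (0.29).
    """
    n_edges = min(int(round(density * 21)), 6)
    pairs = [(i, j) for i in range(7) for j in range(i + 1, 7)]
    rng.shuffle(pairs)
    template = np.zeros((7, 7), dtype=int)
    parent = list(range(7))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    added = 0
    for i, j in pairs:
        if added >= n_edges:
            break
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        codes = list(satisfiable_codes(CANONICAL_ORDER[i], CANONICAL_ORDER[j]))
        rng.shuffle(codes)
        for code in codes:
            template[i, j] = template[j, i] = int(code)
            if _capacity_ok(template, i) and _capacity_ok(template, j):
                parent[ri] = rj
                added += 1
                break
            template[i, j] = template[j, i] = 0
    return template


# ---------------------------------------------------------------------------
# constructive figure placement


@dataclass
class SimFigureSpec:
    """Target relation structure for generated figures."""

    template: np.ndarray | str = "random"  # 7x7 codes, or "random"
    density: float = 0.3
    jitter: float = 0.0  # vertex jitter amplitude (absolute units)
    seed: int = 0
    max_retries: int = 30


def _rigid_map(c1, c2, t1, t2) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation v with R@c1+v = t1 and R@c2+v = t2."""
    dc, dt = np.asarray(c2) - np.asarray(c1), np.asarray(t2) - np.asarray(t1)
    ang = np.arctan2(dt[1], dt[0]) - np.arctan2(dc[1], dc[0])
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    v = np.asarray(t1) - R @ np.asarray(c1)
    return R, v


def _wedge_bisector(vertices: np.ndarray, k: int) -> np.ndarray:
    """Unit bisector of the interior wedge at vertex k (convex CCW polygon)."""
    n = len(vertices)
    a = vertices[(k - 1) % n] - vertices[k]
    b = vertices[(k + 1) % n] - vertices[k]
    d = a / np.linalg.norm(a) + b / np.linalg.norm(b)
    return d / np.linalg.norm(d)


def _rotation_to(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    ang = np.arctan2(dst[1], dst[0]) - np.arctan2(src[1], src[0])
    return np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])


#: attachment sites of one piece: (occupied edge indices, occupied vertex indices)
_Sites = tuple[set[int], set[int]]


def _line_attachment_targets(
    p1: np.ndarray, p2: np.ndarray, lc: float, code: int, end: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Target endpoints for a child edge of length lc on a parent edge, reversed.

    ``end`` picks which parent-edge end a partial overlap overhangs (0 or 1).
    Returns (t1, t2) so that mapping (c1 -> t1, c2 -> t2) realizes the code,
    or None when the code is impossible for these lengths.
    """
    lp = float(np.linalg.norm(p2 - p1))
    u = (p2 - p1) / lp
    if code == 1:
        if abs(lc - lp) > _EDGE_LEN_EPS:
            return None
        lo, hi = 0.0, lp
    elif code == 3:
        if abs(lc - lp) < 0.1:
            return None
        if lc < lp:  # child edge strictly inside parent edge
            margin = rng.uniform(0.2, 0.8) * (lp - lc)
            lo, hi = margin, margin + lc
        else:  # parent edge strictly inside child edge
            margin = rng.uniform(0.2, 0.8) * (lc - lp)
            lo, hi = -margin, -margin + lc
    elif code == 2:
        # shared sub-segment equals neither edge: child overhangs one end
        o = rng.uniform(0.3, 0.7) * min(lc, lp)
        lo, hi = (o - lc, o) if end == 0 else (lp - o, lp - o + lc)
    else:
        return None
    # reversed orientation puts the child interior on the far side
    return p1 + u * hi, p1 + u * lo


def _place_child(
    parent: Piece,
    child_type: PieceType,
    code: int,
    rng: np.random.Generator,
    tol: float,
    parent_used: _Sites,
) -> tuple[Piece, _Sites, _Sites] | None:
    """Try to place a new piece realizing ``code`` against ``parent``.

    ``parent_used`` lists the parent's already-occupied edges and vertices;
    on success returns the piece plus the sites the attachment occupies on
    the parent and on the child.
    """
    base = CANONICAL_SHAPES[child_type].copy()
    nb = len(base)
    pv = parent.vertices
    np_edges = len(pv)
    used_e, used_v = parent_used

    options: list[tuple] = []
    if code in (1, 2, 3):
        for pe in range(np_edges):
            for ce in range(nb):
                for end in (0, 1) if code == 2 else (0,):
                    options.append(("edge", pe, ce, end))
    elif code == 4:
        for pe in range(np_edges):
            for ck in range(nb):
                options.append(("vertex-edge", pe, ck, 0))
    elif code == 5:
        for pk in range(np_edges):
            for ck in range(nb):
                options.append(("vertex-vertex", pk, ck, 0))
    rng.shuffle(options)

    for kind, pi_, ci_, end in options:
        if kind == "edge":
            if pi_ in used_e:
                continue
            if code == 1 and ({pi_, (pi_ + 1) % np_edges} & used_v):
                continue
            if code == 2 and ((pi_ + end) % np_edges) in used_v:
                continue
            p1, p2 = pv[pi_], pv[(pi_ + 1) % np_edges]
            c1, c2 = base[ci_], base[(ci_ + 1) % nb]
            lc = float(np.linalg.norm(c2 - c1))
            targets = _line_attachment_targets(p1, p2, lc, code, end, rng)
            if targets is None:
                continue
            R, v = _rigid_map(c1, c2, *targets)
            p_sites: _Sites = ({pi_}, set())
            c_sites: _Sites = ({ci_}, set())
            lp = float(np.linalg.norm(p2 - p1))
            if code == 1:
                p_sites[1].update({pi_, (pi_ + 1) % np_edges})
                c_sites[1].update({ci_, (ci_ + 1) % nb})
            elif code == 3:
                if lc < lp:
                    c_sites[1].update({ci_, (ci_ + 1) % nb})
                else:
                    p_sites[1].update({pi_, (pi_ + 1) % np_edges})
            elif code == 2:
                p_sites[1].add((pi_ + end) % np_edges)
                # the child end inside the parent edge: c1 maps to the far
                # target, i.e. index ci_ for end 0, ci_+1 for end 1
                c_sites[1].add(ci_ if end == 0 else (ci_ + 1) % nb)
        elif kind == "vertex-edge":
            if pi_ in used_e:
                continue
            p1, p2 = pv[pi_], pv[(pi_ + 1) % np_edges]
            u = (p2 - p1) / np.linalg.norm(p2 - p1)
            n_out = np.array([u[1], -u[0]])  # right of the CCW edge = outside
            frac = rng.uniform(0.35, 0.65)
            m = p1 + (p2 - p1) * frac
            R = _rotation_to(_wedge_bisector(base, ci_), n_out)
            v = m - R @ base[ci_]
            p_sites = ({pi_}, set())
            c_sites = (set(), {ci_})
        else:  # vertex-vertex
            if pi_ in used_v:
                continue
            bis_parent = _wedge_bisector(pv, pi_)
            R = _rotation_to(_wedge_bisector(base, ci_), -bis_parent)
            v = pv[pi_] - R @ base[ci_]
            p_sites = (set(), {pi_})
            c_sites = (set(), {ci_})
        cand = Piece(child_type, base @ R.T + v)
        try:
            got = classify_relationship(parent, cand, tol)
        except Exception:
            continue
        if int(got) == code:
            return cand, p_sites, c_sites
    return None


def _component_layout(
    nodes: list[int],
    template: np.ndarray,
    rng: np.random.Generator,
    tol: float,
    clearance: float,
) -> dict[int, Piece] | None:
    """Place one connected component of the contact forest."""
    from shapely.geometry import Polygon

    root = int(rng.choice(nodes))
    placed: dict[int, Piece] = {
        root: Piece(CANONICAL_ORDER[root], CANONICAL_SHAPES[CANONICAL_ORDER[root]])
    }
    used: dict[int, _Sites] = {root: (set(), set())}
    queue = [root]
    while queue:
        cur = queue.pop(0)
        # line attachments consume edge neighborhoods; place them first
        children = sorted(
            (n for n in nodes if n not in placed and template[cur, n] != 0),
            key=lambda n: (template[cur, n], rng.random()),
        )
        for nxt in children:
            code = int(template[cur, nxt])
            child = None
            for _ in range(30):
                res = _place_child(
                    placed[cur], CANONICAL_ORDER[nxt], code, rng, tol, used[cur]
                )
                if res is None:
                    break
                cand, p_sites, c_sites = res
                # keep clear of every piece other than the attachment parent
                poly = Polygon(cand.vertices)
                ok = all(
                    Polygon(p.vertices).distance(poly) > clearance
                    for k, p in placed.items()
                    if k != cur
                )
                if ok:
                    child = cand
                    used[cur][0].update(p_sites[0])
                    used[cur][1].update(p_sites[1])
                    used[nxt] = (set(c_sites[0]), set(c_sites[1]))
                    break
            if child is None:
                return None
            placed[nxt] = child
            queue.append(nxt)
    return placed


def _build_figure(
    template: np.ndarray, rng: np.random.Generator, figure_id: str, jitter: float
) -> TangramFigure:
    tol = 1e-9
    clearance = 0.12
    # connected components of the nonzero-edge forest
    seen: set[int] = set()
    components: list[list[int]] = []
    for start in range(7):
        if start in seen:
            continue
        comp, stack = [], [start]
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.append(x)
            stack.extend(j for j in range(7) if template[x, j] and j not in seen)
        components.append(comp)

    pieces: dict[int, Piece] = {}
    x_cursor = 0.0
    for comp in components:
        layout = _component_layout(comp, template, rng, tol, clearance)
        if layout is None:
            raise ConstructiveFailureError("component placement failed")
        xs = np.vstack([p.vertices for p in layout.values()])
        shift = np.array([x_cursor - xs[:, 0].min(), -xs[:, 1].min()])
        for k, p in layout.items():
            pieces[k] = Piece(p.piece_id, p.vertices + shift)
        x_cursor += (xs[:, 0].max() - xs[:, 0].min()) + 3.0
    fig = TangramFigure(
        figure_id=figure_id, pieces=[pieces[i] for i in range(7)]
    )
    if jitter > 0:
        jittered = [
            Piece(p.piece_id, p.vertices + rng.uniform(-jitter, jitter, p.vertices.shape))
            for p in fig.pieces
        ]
        fig = TangramFigure(figure_id=figure_id, pieces=jittered)
    # random global rotation exercises the similarity invariance of the code
    return transform_figure(fig, rotation=rng.uniform(0, 2 * np.pi))


def gen_figures(
    spec: SimFigureSpec, n: int
) -> list[tuple[TangramFigure, CAEMatrix]]:
    """Generate figures whose encodings match the requested template(s).

    Returns (figure, ground-truth encoding) pairs; the ground truth is the
    canonicalized template, and each generated figure is verified to encode
    to it exactly.  Raises :class:`ConstructiveFailureError` after bounded
    retries for unsatisfiable templates.
    """
    rng = np.random.default_rng(spec.seed)
    resample = isinstance(spec.template, str) and spec.template == "random"
    out: list[tuple[TangramFigure, CAEMatrix]] = []
    for idx in range(n):
        fig = truth = None
        for attempt in range(spec.max_retries):
            if resample and (attempt == 0 or attempt % 5 == 4):
                # a fresh random template every few stalled attempts
                template = random_template(rng, spec.density)
                truth = CAEMatrix(weights=canonicalize_weights(template))
            elif not resample and attempt == 0:
                template = np.asarray(spec.template, dtype=int)
                check_template(template)
                truth = CAEMatrix(weights=canonicalize_weights(template))
            try:
                cand = _build_figure(template, rng, f"sim_{idx:04d}", spec.jitter)
                got = encode(cand)
            except (ConstructiveFailureError, InvalidConfigurationError):
                continue
            if cae_distance(got, truth) == 0.0:
                fig = cand
                break
        if fig is None:
            raise ConstructiveFailureError(
                f"could not realize template for figure {idx} within "
                f"{spec.max_retries} retries"
            )
        out.append((fig, truth))
    return out


# ---------------------------------------------------------------------------
# annotations

_INANIMATE_WORDS = tuple(
    """
    house bridge tower boat ship car truck train plane rocket chair table
    lamp vase cup bowl bottle hat shoe boot arrow kite star mountain tree
    flower leaf rock wall gate door window roof tent church castle mill
    crane? anchor bell candle clock crown hammer knife spoon fork ladder
    letter map mask mirror pot sail shield sword wheel windmill barn fence
    """.replace("?", "").split()
)

_ANIMATE_WORDS = tuple(sorted(ANIMATE_LEXICON))


def _counts_for_abstraction(target: float, n_labels: int) -> list[int]:
    """Label multiplicities whose normalized entropy best matches ``target``.

    Uses the (m, 1, 1, ...) family: one modal label repeated m times and the
    rest distinct.
    """
    best_m, best_err = n_labels, np.inf
    for m in range(1, n_labels + 1):
        counts = [m] + [1] * (n_labels - m)
        p = np.array(counts, dtype=float) / n_labels
        h = float(-(p * np.log(p)).sum()) / np.log(n_labels)
        err = abs(h - target)
        if err < best_err:
            best_m, best_err = m, err
    return [best_m] + [1] * (n_labels - best_m)


def gen_annotations(
    figure_ids: list[str],
    animacy_truth: np.ndarray,
    abstraction_truth: np.ndarray,
    n_annotators: int = 10,
    seed: int = 0,
):
    """Annotation sets with planted animacy and abstraction ground truths.

    The animate-label count is planted exactly (round(truth x n)); label
    diversity is chosen so the measured normalized entropy tracks the
    abstraction truth.
    """
    from .dimensions import AnnotationSet

    rng = np.random.default_rng(seed)
    animacy_truth = np.asarray(animacy_truth, dtype=float)
    abstraction_truth = np.asarray(abstraction_truth, dtype=float)
    if np.any((animacy_truth < 0) | (animacy_truth > 1)):
        raise ValueError("animacy truths must lie in [0, 1]")
    if np.any((abstraction_truth < 0) | (abstraction_truth > 1)):
        raise ValueError("abstraction truths must lie in [0, 1]")
    out = []
    for fid, anim, abstr in zip(figure_ids, animacy_truth, abstraction_truth):
        target = int(round(float(anim) * n_annotators))
        h_target = float(abstr) * np.log(n_annotators)
        # label structure: an animate block (m_a), an inanimate block (m_i)
        # and distinct singletons, k of them animate.  The animate instance
        # count m_a + k is planted exactly; among the structures achieving
        # it, pick the one whose entropy best matches the target.
        best = None
        for m_a in range(0, target + 1):
            k = target - m_a
            for m_i in range(0, n_annotators - target + 1):
                s = n_annotators - m_a - m_i
                if s < 0 or k > s or (m_a == 1) or (m_i == 1):
                    continue  # blocks of one are just singletons
                counts = [c for c in (m_a, m_i) if c > 0] + [1] * s
                p = np.array(counts, dtype=float) / n_annotators
                h = float(-(p * np.log(p)).sum())
                err = abs(h - h_target)
                if best is None or err < best[0]:
                    best = (err, m_a, m_i, k)
        _, m_a, m_i, k_animate = best
        animate_pool = list(rng.permutation(_ANIMATE_WORDS))
        inanimate_pool = list(rng.permutation(_INANIMATE_WORDS))
        labels = [animate_pool.pop()] * m_a + [inanimate_pool.pop()] * m_i
        n_singles = n_annotators - m_a - m_i
        for i in range(n_singles):
            pool = animate_pool if i < k_animate else inanimate_pool
            labels.append(pool.pop())
        annotators = [f"ann{i:02d}" for i in range(n_annotators)]
        out.append(
            AnnotationSet(
                figure_id=fid,
                global_labels=list(zip(annotators, labels)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# trial schedule


def make_schedule(
    figure_ids: list[str],
    n_subjects: int,
    n_presentations: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomized presentation schedule: full cycles, reshuffled per cycle."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        trial = 0
        for pres in range(1, n_presentations + 1):
            order = rng.permutation(figure_ids)
            for fid in order:
                rows.append(
                    {
                        "subject": f"sub{s:02d}",
                        "trial": trial,
                        "figure_id": fid,
                        "presentation": pres,
                    }
                )
                trial += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EEG epochs


@dataclass
class SimComponent:
    """One planted evoked component.

    ``dimension`` names a stimulus-table column whose per-trial value scales
    the component (binary columns map to ±1, continuous ones are z-scored);
    the special value ``"image"`` gives every image its own topography, and
    ``rdm`` (an n x n dissimilarity matrix) shapes those topographies so
    neural pattern distances follow the model.
    """

    name: str
    dimension: str
    latency: float  # seconds
    duration: float = 0.1  # Gaussian envelope FWHM-like width (2 sd), seconds
    effect_size: float = 1.0  # amplitude in units of the noise RMS
    latency_sd: float = 0.0  # per-trial latency jitter
    topography_seed: int | None = None
    rdm: np.ndarray | None = None


@dataclass
class SimEEGSpec:
    """Study-conditions simulation: 61 channels, 500 Hz, −0.5 to 1.0 s."""

    n_channels: int = 61
    sfreq: float = 500.0
    tmin: float = -0.5
    tmax: float = 1.0
    baseline: tuple[float, float] = (-0.4, -0.1)
    ar_coef: float = 0.97
    noise_rank: int = 10
    noise_amplitude: float = 10.0  # baseline RMS, arbitrary units for µV
    sensor_noise: float = 0.1  # white noise relative to noise_amplitude
    components: list[SimComponent] = field(default_factory=list)
    familiarity_latency_shift: float = 0.0  # s per presentation step (vs 3rd)
    familiarity_gain: float = 0.0  # relative gain per presentation step
    artifact_fraction: float = 0.0  # epochs receiving ±artifact_amplitude
    artifact_amplitude: float = 100.0
    seed: int = 0


def _condition_values(stim: pd.DataFrame, column: str) -> pd.Series:
    v = stim[column]
    vals = v.dropna().unique()
    if set(np.asarray(vals).tolist()) <= {0, 1, True, False}:
        return v.astype(float) * 2.0 - 1.0
    x = v.astype(float)
    sd = x.std(ddof=0)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _image_topographies(
    figure_ids: list[str],
    n_channels: int,
    rng: np.random.Generator,
    rdm: np.ndarray | None,
) -> dict[str, np.ndarray]:
    n = len(figure_ids)
    if rdm is None:
        topo = rng.standard_normal((n, n_channels))
    else:
        k = min(n - 1, 10)
        emb = classical_mds(np.asarray(rdm, dtype=float), k=k).coords
        scale = np.abs(emb).max() or 1.0
        basis = np.linalg.qr(rng.standard_normal((n_channels, k)))[0]
        topo = (emb / scale) @ basis.T
    topo /= np.linalg.norm(topo, axis=1, keepdims=True) + 1e-12
    return dict(zip(figure_ids, topo))


def gen_epochs(
    spec: SimEEGSpec,
    stimulus_table: pd.DataFrame,
    schedule: pd.DataFrame,
) -> EpochSet:
    """Simulate one subject's epochs for the given trial schedule.

    Epochs are spatially-structured AR(1) noise plus one Gaussian-envelope
    component per entry of ``spec.components``, scaled by the trial's
    condition value, with optional familiarity (presentation-index)
    modulation of latency and gain.  Output is baseline-corrected.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.arange(
        round(spec.tmin * spec.sfreq), round(spec.tmax * spec.sfreq) + 1
    ) / spec.sfreq
    n_t = len(times)
    sched = schedule.reset_index(drop=True)
    n_trials = len(sched)
    stim = stimulus_table.set_index("figure_id")

    # colored noise: rank-limited spatial mixing of AR(1) latents
    mixing = rng.standard_normal((spec.n_channels, spec.noise_rank))
    mixing /= np.linalg.norm(mixing, axis=0, keepdims=True)
    innov_sd = np.sqrt(1.0 - spec.ar_coef**2)
    latents = np.empty((n_trials, spec.noise_rank, n_t))
    latents[:, :, 0] = rng.standard_normal((n_trials, spec.noise_rank))
    eps = rng.standard_normal((n_trials, spec.noise_rank, n_t)) * innov_sd
    for t in range(1, n_t):
        latents[:, :, t] = spec.ar_coef * latents[:, :, t - 1] + eps[:, :, t]
    data = np.einsum("cr,nrt->nct", mixing, latents)
    rms = float(np.sqrt(np.mean(data**2))) or 1.0
    data *= spec.noise_amplitude / rms  # calibrate baseline RMS
    data += (
        rng.standard_normal((n_trials, spec.n_channels, n_t))
        * spec.sensor_noise
        * spec.noise_amplitude
    )

    for comp in spec.components:
        if not (spec.tmin <= comp.latency <= spec.tmax):
            raise ValueError(
                f"component {comp.name!r} latency {comp.latency} outside epoch"
            )
        crng = np.random.default_rng(
            comp.topography_seed
            if comp.topography_seed is not None
            else rng.integers(2**31)
        )
        if comp.dimension == "image":
            topo_by_img = _image_topographies(
                list(stim.index), spec.n_channels, crng, comp.rdm
            )
            topos = np.stack([topo_by_img[f] for f in sched.figure_id])
            values = np.ones(n_trials)
        else:
            topo = crng.standard_normal(spec.n_channels)
            topo /= np.linalg.norm(topo)
            topos = np.tile(topo, (n_trials, 1))
            values = (
                _condition_values(stim, comp.dimension)
                .reindex(sched.figure_id)
                .to_numpy()
            )
        pres = sched.presentation.to_numpy() if "presentation" in sched else 3
        lat = (
            comp.latency
            + spec.familiarity_latency_shift * (np.asarray(pres) - 3)
            + crng.normal(0.0, comp.latency_sd, n_trials)
        )
        gain = 1.0 + spec.familiarity_gain * (np.asarray(pres) - 3)
        sd = comp.duration / 2.0
        envelope = np.exp(-0.5 * ((times[None] - lat[:, None]) / sd) ** 2)
        amp = comp.effect_size * spec.noise_amplitude * values * gain
        data += amp[:, None, None] * topos[:, :, None] * envelope[:, None, :]

    if spec.artifact_fraction > 0:
        n_art = int(round(spec.artifact_fraction * n_trials))
        art_idx = rng.choice(n_trials, size=n_art, replace=False)
        onset = np.searchsorted(times, 0.0)
        for i in art_idx:
            ch = int(rng.integers(spec.n_channels))
            t0 = int(rng.integers(onset, n_t - 10))
            data[i, ch, t0 : t0 + 10] += spec.artifact_amplitude * (
                1 if rng.random() < 0.5 else -1
            )
        sched = sched.assign(artifact=np.isin(np.arange(n_trials), art_idx))

    bmask = (times >= spec.baseline[0]) & (times <= spec.baseline[1])
    data -= data[:, :, bmask].mean(axis=2, keepdims=True)

    meta = sched.copy()
    for col in stimulus_table.columns:
        if col != "figure_id" and col not in meta.columns:
            meta[col] = stim[col].reindex(meta.figure_id).to_numpy()
    ch_names = [f"EEG{i:03d}" for i in range(spec.n_channels)]
    return EpochSet(data=data, times=times, ch_names=ch_names, metadata=meta)


# ---------------------------------------------------------------------------
# behavior


@dataclass
class SimBehaviorSpec:
    """Planted response-time and choice effects."""

    mu_log_rt: float = np.log(0.9)
    sigma_log_rt: float = 0.25
    effects: dict[str, float] = field(
        default_factory=lambda: {
            "abstraction": 0.15,  # log-units per z: abstract is slower
            "animacy_binary": -0.08,  # animals recognized faster
            "lfd": -0.05,  # salient local features speed recognition
            "local_deviation": -0.05,
        }
    )
    repetition_effect: tuple[float, ...] = (0.12, 0.05, 0.0, 0.0, 0.0)
    base_error: float = 0.04
    abstraction_error: float = 0.10  # extra error rate per abstraction unit
    change_of_mind_fraction: float = 0.115
    seed: int = 0


def gen_behavior(
    spec: SimBehaviorSpec,
    stimulus_table: pd.DataFrame,
    schedule: pd.DataFrame,
) -> pd.DataFrame:
    """Simulate per-trial responses and RTs with planted effects.

    Responses are stable within subject x image (a consistent
    interpretation), except for a planted fraction of change-of-mind images
    whose response sequences contain exactly one transition.  RTs are
    lognormal with additive dimension, repetition and noise terms.
    """
    rng = np.random.default_rng(spec.seed)
    stim = stimulus_table.set_index("figure_id")
    tangram_ids = [
        f for f in stim.index if bool(stim.loc[f].get("is_tangram", True))
    ]
    n_com = int(round(spec.change_of_mind_fraction * len(tangram_ids)))
    com_images = set(rng.choice(tangram_ids, size=n_com, replace=False))

    z_cols = {}
    for col in spec.effects:
        if col in stim.columns:
            z_cols[col] = _condition_values(stim.reset_index(), col).to_numpy()
    stim_z = pd.DataFrame(z_cols, index=stim.index)

    rows = []
    for subject, sub_sched in schedule.groupby("subject", sort=False):
        sub_sched = sub_sched.sort_values("trial")
        # consistent per-image interpretation for this subject
        responses: dict[str, int] = {}
        transition_at: dict[str, tuple[int, int]] = {}  # image -> (index, start)
        for fid in stim.index:
            true_animal = int(stim.loc[fid].get("animacy_binary", 0))
            err = spec.base_error + spec.abstraction_error * float(
                stim.loc[fid].get("abstraction", 0.0)
            )
            resp = true_animal if rng.random() > err else 1 - true_animal
            responses[fid] = resp
            if fid in com_images:
                idx = int(rng.integers(2, 6))  # transition at presentation 2..5
                start = int(rng.random() < 0.5)
                transition_at[fid] = (idx, start)
        for _, row in sub_sched.iterrows():
            fid, pres = row.figure_id, int(row.presentation)
            if fid in transition_at:
                idx, start = transition_at[fid]
                resp = start if pres < idx else 1 - start
            else:
                resp = responses[fid]
            log_rt = spec.mu_log_rt + rng.normal(0.0, spec.sigma_log_rt)
            for col, beta in spec.effects.items():
                if col in stim_z.columns:
                    log_rt += beta * float(stim_z.loc[fid, col])
            log_rt += spec.repetition_effect[pres - 1]
            rows.append(
                {
                    "subject": subject,
                    "trial": int(row.trial),
                    "figure_id": fid,
                    "presentation": pres,
                    "response": "animal" if resp else "non-animal",
                    "rt": float(np.exp(log_rt)),
                    "n_keypresses": 1,
                    "premature": False,
                    "change_of_mind_truth": fid in com_images,
                }
            )
    return pd.DataFrame(rows)
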