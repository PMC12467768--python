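"""Distances between encodings, MDS embedding, and animacy separability.

The encoding distance is a normalized L1 distance on the 21 upper-triangle
relation codes, minimized over the four permutations that swap the two
physically identical large triangles and/or the two identical small
triangles.  Because those permutations form a group, the minimized distance
remains a metric (identity, symmetry and the triangle inequality hold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.manifold import MDS

from .geometry import PERMUTATION_GROUP, CAEMatrix, _permute

__all__ = [
    "cae_distance",
    "distance_matrix",
    "classical_mds",
    "mds_embed",
    "separability_test",
    "Embedding",
]

_IU = np.triu_indices(7, k=1)


def cae_distance(m1: CAEMatrix | np.ndarray, m2: CAEMatrix | np.ndarray) -> float:
    """Permutation-minimized normalized L1 distance between two encodings.

    d = min over the identical-piece swaps pi of
        sum_{i<j} |m1[i,j] - m2[pi(i),pi(j)]| / 21,  in [0, 5].
    """
    w1 = m1.weights if isinstance(m1, CAEMatrix) else np.asarray(m1)
    w2 = m2.weights if isinstance(m2, CAEMatrix) else np.asarray(m2)
    if w1.shape != (7, 7) or w2.shape != (7, 7):
        raise ValueError("encodings must be 7x7 matrices")
    best = np.inf
    for perm in PERMUTATION_GROUP:
        d = np.abs(w1[_IU] - _permute(w2, perm)[_IU]).sum() / 21.0
        best = min(best, float(d))
    return best


def distance_matrix(matrices: list[CAEMatrix | np.ndarray]) -> np.ndarray:
    """Symmetric pairwise encoding-distance matrix."""
    n = len(matrices)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = cae_distance(matrices[i], matrices[j])
    return D


@dataclass
class Embedding:
    """Low-dimensional coordinates of figures plus the embedding stress."""

    coords: np.ndarray  # (n, k)
    stress: float

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


def classical_mds(D: np.ndarray, k: int = 2) -> Embedding:
    """Torgerson double-centering MDS (deterministic, eigendecomposition)."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    fitted = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
    iu = np.triu_indices(n, k=1)
    stress = float(np.sqrt(((D[iu] - fitted[iu]) ** 2).sum()))
    return Embedding(coords=coords, stress=stress)


def mds_embed(
    D: np.ndarray, k: int = 2, seed: int = 0, kind: str = "metric", n_init: int = 8
) -> Embedding:
    """Embed a distance matrix in k dimensions by stress-minimizing MDS.

    ``kind='metric'`` (default) uses SMACOF with ``n_init`` restarts and a
    fixed seed; ``kind='classical'`` uses the deterministic Torgerson
    solution.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} points for a {k}-D embedding")
    if kind == "classical":
        return classical_mds(D, k)
    if kind != "metric":
        raise ValueError(f"unknown MDS kind {kind!r}")
    if np.allclose(D, 0.0):
        return Embedding(coords=np.zeros((n, k)), stress=0.0)
    model = MDS(
        n_components=k,
        dissimilarity="precomputed",
        metric_mds=True,
        n_init=n_init,
        random_state=seed,
        normalized_stress=False,
    )
    coords = model.fit_transform(D)
    return Embedding(coords=coords, stress=float(np.sqrt(model.stress_)))


def separability_test(
    emb: Embedding, labels: np.ndarray
) -> dict[str, float | int]:
    """Best-axis two-sample t-test of a binary label in embedding space.

    Runs a pooled-variance Student t-test of the two label groups along each
    embedding axis (df = n - 2) and reports the axis with the largest |t|
    together with its two-sided p-value.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("separability test needs exactly two label groups")
    x_mask = labels == groups[0]
    if x_mask.sum() < 2 or (~x_mask).sum() < 2:
        raise ValueError("need at least two figures per label group")
    best = None
    n = len(labels)
    for axis in range(emb.n_dims):
        x = emb.coords[x_mask, axis]
        y = emb.coords[~x_mask, axis]
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (n - 2)
        if sp2 == 0.0:
            t = 0.0
        else:
            t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        if best is None or abs(t) > abs(best[0]):
            best = (t, axis)
    t, axis = best
    p = 2 * stats.t.sf(abs(t), df=n - 2) if t != 0.0 else 1.0
    return {"t": float(t), "p": float(p), "axis": int(axis), "df": n - 2}
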