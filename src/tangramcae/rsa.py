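"""Representational similarity analysis with time-resolved GLM.

Neural representational dissimilarity matrices (RDMs) come from pairwise
image decoding (higher cross-validated accuracy = greater neural
dissimilarity).  Six candidate model RDMs predict that structure from
stimulus properties: three semantic models (animacy, abstraction level,
object category group) and three feature models (local feature density,
local feature tags, connection structure).  At each timepoint and subject
the vectorized lower triangle of the neural RDM is regressed on the
z-scored model predictors (OLS with intercept); group analysis tests the
across-subject betas against zero with BH-FDR over timepoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import cae_distance, classical_mds

__all__ = [
    "MODEL_NAMES",
    "ModelRDM",
    "build_model_rdms",
    "model_space_mds",
    "timewise_glm",
    "glm_group_stats",
    "stimulus_embedding",
]

MODEL_NAMES = (
    "animacy",
    "abstraction",
    "lfd",
    "object_level",
    "feature_level",
    "connections",
)

#: grouping used for two-panel reporting: image structure vs semantic abstraction
MODEL_GROUPS = {
    "image_structure": ("connections", "feature_level", "lfd"),
    "semantic_abstraction": ("abstraction", "animacy", "object_level"),
}


@dataclass
class ModelRDM:
    """One candidate dissimilarity model over the stimulus set."""

    name: str
    values: np.ndarray  # (n, n), symmetric, zero diagonal
    missing: np.ndarray | None = None  # boolean mask of imputed entries

    def lower_triangle(self) -> np.ndarray:
        il = np.tril_indices(self.values.shape[0], k=-1)
        return self.values[il]

    def standardized(self) -> np.ndarray:
        """Z-scored lower-triangle vector (the regression predictor)."""
        v = self.lower_triangle()
        sd = v.std(ddof=0)
        return (v - v.mean()) / (sd if sd > 0 else 1.0)


def _same_different(values: np.ndarray) -> np.ndarray:
    return (values[:, None] != values[None, :]).astype(float)


def _abs_diff(values: np.ndarray) -> np.ndarray:
    return np.abs(values[:, None] - values[None, :])


def _jaccard_distance(tag_sets: list[frozenset]) -> np.ndarray:
    n = len(tag_sets)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = tag_sets[i], tag_sets[j]
            union = len(a | b)
            D[i, j] = D[j, i] = 1.0 - (len(a & b) / union if union else 1.0)
    return D


def build_model_rdms(
    stimulus_table: pd.DataFrame,
    encodings: dict[str, object] | None = None,
    part_tags: dict[str, frozenset] | None = None,
) -> list[ModelRDM]:
    """Construct the six candidate model RDMs from stimulus properties.

    Category models (animacy, object_level) are same/different; continuous
    models (abstraction, lfd) are absolute score differences; feature_level
    is the Jaccard distance between part-tag sets; connections is the
    encoding distance.  Encoding-based entries for non-tangram stimuli are
    imputed at the maximum observed distance and flagged in ``missing``.
    """
    df = stimulus_table.reset_index(drop=True)
    ids = df.figure_id.tolist()
    n = len(ids)
    models: list[ModelRDM] = []

    spec = {
        "animacy": ("animacy_binary", _same_different),
        "abstraction": ("abstraction", _abs_diff),
        "lfd": ("lfd", _abs_diff),
        "object_level": ("group_index", _same_different),
    }
    for name, (col, fn) in spec.items():
        if col not in df.columns:
            warnings.warn(f"model {name!r} skipped: missing column {col!r}",
                          stacklevel=2)
            continue
        models.append(ModelRDM(name=name, values=fn(df[col].to_numpy())))

    if part_tags is not None:
        sets = [frozenset(part_tags.get(f, frozenset())) for f in ids]
        models.append(ModelRDM(name="feature_level", values=_jaccard_distance(sets)))
    else:
        warnings.warn("model 'feature_level' skipped: no part tags", stacklevel=2)

    if encodings is not None:
        have = [f in encodings for f in ids]
        D = np.zeros((n, n))
        missing = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                if have[i] and have[j]:
                    D[i, j] = D[j, i] = cae_distance(encodings[ids[i]], encodings[ids[j]])
                else:
                    missing[i, j] = missing[j, i] = True
        if missing.any():
            mx = D[~missing & ~np.eye(n, dtype=bool)].max() if n > 1 else 1.0
            D[missing] = mx
        models.append(ModelRDM(name="connections", values=D,
                               missing=missing if missing.any() else None))
    else:
        warnings.warn("model 'connections' skipped: no encodings", stacklevel=2)
    return models


def model_space_mds(models: list[ModelRDM], k: int = 2) -> pd.DataFrame:
    """Embed models in 2-D: distance = 1 − Pearson r of lower triangles."""
    if len(models) < 3:
        raise ValueError("model-space MDS needs at least three models")
    vecs = [m.lower_triangle() for m in models]
    n = len(models)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = np.corrcoef(vecs[i], vecs[j])[0, 1]
            D[i, j] = D[j, i] = 1.0 - r
    emb = classical_mds(D, k=k)
    return pd.DataFrame(
        emb.coords, index=[m.name for m in models],
        columns=[f"dim{i+1}" for i in range(k)],
    )


def timewise_glm(
    neural: np.ndarray,
    models: list[ModelRDM],
) -> np.ndarray:
    """Per-timepoint OLS betas of one subject's neural RDM series.

    ``neural`` is (n_times, n, n); the z-scored lower triangle at each
    timepoint is regressed on the standardized model predictors plus an
    intercept.  Returns betas of shape (n_times, n_models).
    """
    t, n, _ = neural.shape
    il = np.tril_indices(n, k=-1)
    X = np.column_stack([m.standardized() for m in models])
    X = np.column_stack([np.ones(len(X)), X])
    cond = np.linalg.cond(X)
    if cond > 1e8:
        warnings.warn(
            f"model design is near-collinear (condition number {cond:.2g}); "
            "using pseudo-inverse", stacklevel=2,
        )
    pinv = np.linalg.pinv(X)
    betas = np.empty((t, len(models)))
    for ti in range(t):
        y = neural[ti][il]
        sd = y.std(ddof=0)
        yz = (y - y.mean()) / (sd if sd > 0 else 1.0)
        betas[ti] = (pinv @ yz)[1:]
    return betas


def glm_group_stats(
    betas: np.ndarray,
    model_names: list[str],
    times: np.ndarray,
    q: float = 0.05,
) -> pd.DataFrame:
    """Across-subject beta series: mean, SE, t vs 0, FDR mask.

    ``betas`` is (n_subjects, n_times, n_models); BH-FDR correction is
    applied jointly over all model x timepoint values.
    """
    n_sub, n_t, n_mod = betas.shape
    tvals, pvals = stats.ttest_1samp(betas, 0.0, axis=0)  # (n_t, n_mod)
    sig, p_adj = multipletests(pvals.ravel(), alpha=q, method="fdr_bh")[:2]
    sig = sig.reshape(n_t, n_mod)
    p_adj = p_adj.reshape(n_t, n_mod)
    rows = []
    for mi, name in enumerate(model_names):
        b = betas[:, :, mi]
        for ti in range(n_t):
            rows.append(
                {
                    "time": times[ti],
                    "model": name,
                    "beta": b[:, ti].mean(),
                    "se": b[:, ti].std(ddof=1) / np.sqrt(n_sub),
                    "t": tvals[ti, mi],
                    "p": pvals[ti, mi],
                    "p_fdr": p_adj[ti, mi],
                    "significant": bool(sig[ti, mi]),
                }
            )
    return pd.DataFrame(rows)


def stimulus_embedding(
    rdm: np.ndarray,
    method: str = "tsne",
    seed: int = 0,
    perplexity: float = 15.0,
) -> tuple[np.ndarray, float]:
    """2-D embedding of a mean neural RDM (t-SNE or metric MDS).

    Returns (coordinates (n, 2), trustworthiness of the embedding).
    """
    from sklearn.manifold import TSNE, MDS, trustworthiness

    D = np.asarray(rdm, dtype=float)
    n = D.shape[0]
    if np.allclose(D, 0.0):
        return np.zeros((n, 2)), 1.0
    if method == "tsne":
        model = TSNE(
            n_components=2,
            metric="precomputed",
            init="random",
            random_state=seed,
            perplexity=min(perplexity, (n - 1) / 3),
        )
        coords = model.fit_transform(D)
    elif method == "mds":
        model = MDS(
            n_components=2,
            dissimilarity="precomputed",
            random_state=seed,
            normalized_stress=False,
        )
        coords = model.fit_transform(D)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    tw = trustworthiness(D, coords, metric="precomputed",
                         n_neighbors=min(5, (n - 1) // 2))
    return coords, float(tw)
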