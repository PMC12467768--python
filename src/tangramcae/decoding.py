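"""Time-resolved multivariate decoding of epochs.

Within-subject decoding uses a shrinkage-regularized linear discriminant
(LDA with analytic covariance shrinkage) on the channel vector at each
timepoint, with stratified cross-validation.  Group-level inference tests
fold-averaged accuracies against chance across subjects, with BH-FDR over
timepoints for decoding curves and cluster-based sign-permutation tests for
temporal generalization matrices.  Channel weights are reported both as raw
discriminant weights and as activation patterns (covariance-projected
weights), which are the interpretable topographies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .preprocessing import EpochSet

__all__ = [
    "DecodingCurve",
    "TGMatrix",
    "balance_trials",
    "decode_timecourse",
    "group_curve_stats",
    "decode_pairwise_images",
    "temporal_generalization",
    "tgm_cluster_test",
    "familiarity_split",
]


def _lda() -> LinearDiscriminantAnalysis:
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")


class _ShrinkageLDA:
    """Binary LDA with Ledoit-Wolf analytic covariance shrinkage.

    Minimal reimplementation for the inner decoding loops, where the
    framework overhead of a full estimator dwarfs the linear algebra on
    (trials x channels) blocks.  Matches sklearn's
    ``LinearDiscriminantAnalysis(solver='lsqr', shrinkage='auto')`` decision
    rule for two classes.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_ShrinkageLDA":
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("_ShrinkageLDA is binary-only")
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        masks = [y == c for c in self.classes_]
        means = [X[m].mean(axis=0) for m in masks]
        Xc = X.copy()
        for m, mu in zip(masks, means):
            Xc[m] -= mu
        # Ledoit-Wolf shrinkage toward the scaled identity
        S = (Xc.T @ Xc) / n
        mu_tr = np.trace(S) / p
        delta2 = float(((S - mu_tr * np.eye(p)) ** 2).sum()) / p
        X2 = Xc**2
        beta2 = float((X2.T @ X2).sum() / n - (S**2).sum()) / (n * p)
        shrink = 1.0 if delta2 == 0 else min(beta2 / delta2, 1.0)
        cov = (1.0 - shrink) * S + shrink * mu_tr * np.eye(p)
        diff = means[1] - means[0]
        self.coef_ = np.linalg.solve(cov, diff)
        priors = np.array([m.mean() for m in masks])
        self.intercept_ = (
            -0.5 * (means[0] + means[1]) @ self.coef_
            + np.log(priors[1] / priors[0])
        )
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


@dataclass
class DecodingCurve:
    """Per-timepoint cross-validated accuracy for one subject and contrast."""

    times: np.ndarray
    accuracy: np.ndarray  # (n_times,)
    chance: float
    n_folds: int
    weights: np.ndarray | None = None  # (n_channels, n_times), discriminant
    patterns: np.ndarray | None = None  # (n_channels, n_times), activation


@dataclass
class TGMatrix:
    """Train-time x test-time generalization accuracies."""

    train_times: np.ndarray
    test_times: np.ndarray
    accuracy: np.ndarray  # (n_train_times, n_test_times)
    train_condition: str = ""
    test_condition: str = ""
    chance: float = 0.5


def balance_trials(
    metadata: pd.DataFrame,
    target: str,
    covariates: list[str],
    seed: int = 0,
) -> np.ndarray:
    """Subsample trials so covariate composition matches across target classes.

    Within every combination of the covariate columns, each target class is
    subsampled to the smallest class count in that combination.  Returns the
    retained row indices.
    """
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    groups = metadata.groupby(covariates, sort=False) if covariates else [
        (None, metadata)
    ]
    for _, grp in groups:
        counts = grp[target].value_counts()
        if len(counts) < metadata[target].nunique():
            continue  # a class is absent in this stratum; drop it entirely
        m = counts.min()
        for _, sub in grp.groupby(target, sort=False):
            idx = sub.index.to_numpy()
            keep.extend(rng.choice(idx, size=m, replace=False))
    return np.sort(np.asarray(keep, dtype=int))


def _fold_weights_patterns(
    clf: LinearDiscriminantAnalysis, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    w = clf.coef_.ravel()
    # activation pattern (covariance-projected weights): interpretable topography
    pattern = np.cov(X.T) @ w
    return w, pattern


def decode_timecourse(
    epochs: EpochSet,
    labels: np.ndarray | str,
    n_folds: int = 5,
    seed: int = 0,
    return_weights: bool = True,
) -> DecodingCurve:
    """Sliding shrinkage-LDA decoding of a binary (or k-class) contrast.

    ``labels`` is a per-trial vector or the name of a metadata column.
    Accuracy at each timepoint is averaged over stratified CV folds.
    """
    y = (
        epochs.metadata[labels].to_numpy()
        if isinstance(labels, str)
        else np.asarray(labels)
    )
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("decoding contrast needs at least two classes")
    n_folds = min(n_folds, int(counts.min()))
    if n_folds < 2:
        raise ValueError("need at least two trials per class")
    X = epochs.data  # (n, c, t)
    n, c, t = X.shape
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(n), y))
    acc = np.zeros(t)
    w_sum = np.zeros((c, t))
    p_sum = np.zeros((c, t))
    binary = len(classes) == 2
    for ti in range(t):
        Xt = X[:, :, ti]
        fold_acc = []
        for tr, te in folds:
            clf = _ShrinkageLDA() if binary else _lda()
            clf.fit(Xt[tr], y[tr])
            fold_acc.append(clf.score(Xt[te], y[te]))
            if return_weights and binary:
                w, p = _fold_weights_patterns(clf, Xt[tr])
                w_sum[:, ti] += w
                p_sum[:, ti] += p
        acc[ti] = float(np.mean(fold_acc))
    chance = float(counts.max() / counts.sum()) if len(classes) > 2 else 0.5
    return DecodingCurve(
        times=epochs.times,
        accuracy=acc,
        chance=chance,
        n_folds=n_folds,
        weights=w_sum / n_folds if return_weights and binary else None,
        patterns=p_sum / n_folds if return_weights and binary else None,
    )


def group_curve_stats(
    curves: list[DecodingCurve], q: float = 0.05
) -> pd.DataFrame:
    """Group-level curve: mean, SEM, one-sample t vs chance, BH-FDR mask.

    The test is one-sided (above chance): cross-validated accuracy is biased
    slightly below chance under the null, so a two-sided test would flag
    spurious below-chance timepoints.
    """
    accs = np.stack([c.accuracy for c in curves])  # (n_subjects, n_times)
    chance = curves[0].chance
    tvals, pvals = stats.ttest_1samp(accs, chance, axis=0, alternative="greater")
    sig, p_adj = multipletests(pvals, alpha=q, method="fdr_bh")[:2]
    return pd.DataFrame(
        {
            "time": curves[0].times,
            "mean_accuracy": accs.mean(axis=0),
            "sem": accs.std(axis=0, ddof=1) / np.sqrt(len(curves)),
            "t": tvals,
            "p": pvals,
            "p_fdr": p_adj,
            "significant": sig,
        }
    )


def decode_pairwise_images(
    epochs: EpochSet,
    image_ids: list[str] | None = None,
    n_folds: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Cross-validated pairwise image decoding: per-timepoint n x n accuracies.

    For every unordered image pair and timepoint, shrinkage-LDA accuracy is
    estimated with stratified CV over that pair's trials.  Pairs with too
    few trials are imputed by the row/column mean and reported via NaN
    before imputation.  Returns (accuracies (t, n, n), image order).
    """
    meta = epochs.metadata
    ids = image_ids or sorted(meta.figure_id.unique())
    n_img = len(ids)
    t = epochs.data.shape[2]
    acc = np.full((t, n_img, n_img), np.nan)
    trials_by_img = {f: np.flatnonzero((meta.figure_id == f).to_numpy()) for f in ids}
    for i in range(n_img):
        for j in range(i + 1, n_img):
            ti_, tj_ = trials_by_img[ids[i]], trials_by_img[ids[j]]
            if len(ti_) < 2 or len(tj_) < 2:
                continue
            idx = np.concatenate([ti_, tj_])
            y = np.concatenate([np.zeros(len(ti_)), np.ones(len(tj_))])
            k = min(n_folds, len(ti_), len(tj_))
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            folds = list(skf.split(np.zeros(len(idx)), y))
            X = epochs.data[idx]
            for ts in range(t):
                fold_acc = [
                    _ShrinkageLDA().fit(X[tr, :, ts], y[tr])
                    .score(X[te, :, ts], y[te])
                    for tr, te in folds
                ]
                acc[ts, i, j] = acc[ts, j, i] = float(np.mean(fold_acc))
    # impute missing pairs by the row/column mean at each timepoint
    for ts in range(t):
        A = acc[ts]
        missing = np.isnan(A) & ~np.eye(n_img, dtype=bool)
        if missing.any():
            rowmean = np.nanmean(np.where(np.eye(n_img, dtype=bool), np.nan, A), axis=1)
            fill = (rowmean[:, None] + rowmean[None, :]) / 2
            A[missing] = fill[missing]
        np.fill_diagonal(A, 0.0)
    return acc, ids


def familiarity_split(
    metadata: pd.DataFrame,
    mode: str = "presentation",
    unfamiliar: tuple[int, ...] = (1, 2),
    familiar: tuple[int, ...] = (4, 5),
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (unfamiliar, familiar) over trials.

    Default splits by presentation index (1-2 vs 4-5, the middle
    presentation dropped, consistent with RT stabilization from the third
    presentation onward); ``mode='rt'`` splits at the within-subject median
    response time instead.
    """
    if mode == "presentation":
        unfam = metadata.presentation.isin(unfamiliar).to_numpy()
        fam = metadata.presentation.isin(familiar).to_numpy()
    elif mode == "rt":
        med = metadata.groupby("subject").rt.transform("median") \
            if "subject" in metadata.columns else metadata.rt.median()
        unfam = (metadata.rt > med).to_numpy()  # slow responses = unfamiliar
        fam = (metadata.rt <= med).to_numpy()
    else:
        raise ValueError(f"unknown familiarity split mode {mode!r}")
    if not unfam.any() or not fam.any():
        raise ValueError("familiarity split produced an empty group")
    return unfam, fam


def temporal_generalization(
    epochs: EpochSet,
    labels: np.ndarray | str,
    train_mask: np.ndarray,
    test_mask: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    train_condition: str = "A",
    test_condition: str = "B",
) -> TGMatrix:
    """Train at each timepoint on one split, test at all timepoints on the other.

    When the splits are disjoint, classifiers are trained on CV subsets of
    the training split and accuracies averaged over folds (test trials are
    never seen in training).  When train and test splits share trials,
    held-out folds of the shared trials are used for testing.
    """
    y = (
        epochs.metadata[labels].to_numpy()
        if isinstance(labels, str)
        else np.asarray(labels)
    )
    train_idx = np.flatnonzero(train_mask)
    test_idx = np.flatnonzero(test_mask)
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("empty train or test split")
    X = epochs.data
    t = X.shape[2]
    y_tr_all = y[train_idx]
    counts = pd.Series(y_tr_all).value_counts()
    k = int(min(n_folds, counts.min()))
    if k < 2:
        raise ValueError("need at least two training trials per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(train_idx)), y_tr_all))
    overlap = bool(np.intersect1d(train_idx, test_idx).size)
    acc = np.zeros((t, t))
    for fold_i, (tr, ho) in enumerate(folds):
        tr_rows = train_idx[tr]
        if overlap:
            te_rows = np.intersect1d(train_idx[ho], test_idx)
            if te_rows.size == 0:
                continue
        else:
            te_rows = test_idx
        Xte = X[te_rows]  # (m, c, t)
        yte = y[te_rows]
        m = len(te_rows)
        for ti in range(t):
            clf = _ShrinkageLDA()
            clf.fit(X[tr_rows, :, ti], y[tr_rows])
            pred = clf.predict(
                Xte.transpose(0, 2, 1).reshape(m * t, -1)
            ).reshape(m, t)
            acc[ti] += (pred == yte[:, None]).mean(axis=0)
    acc /= len(folds)
    return TGMatrix(
        train_times=epochs.times,
        test_times=epochs.times,
        accuracy=acc,
        train_condition=train_condition,
        test_condition=test_condition,
    )


def tgm_cluster_test(
    tgms: list[TGMatrix],
    n_permutations: int = 500,
    cluster_p: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Cluster-based sign-permutation test of TG accuracies against chance.

    Returns boolean masks of significantly above- and below-chance clusters
    over the train x test time grid (two one-sided tests at ``alpha``).
    """
    from mne.stats import permutation_cluster_1samp_test

    data = np.stack([t.accuracy - t.chance for t in tgms])
    n_sub = data.shape[0]
    thresh = stats.t.ppf(1 - cluster_p / 2, df=n_sub - 1)
    masks = {}
    for name, sign in (("above", 1.0), ("below", -1.0)):
        _, clusters, cluster_pv, _ = permutation_cluster_1samp_test(
            sign * data,
            threshold=thresh,
            n_permutations=n_permutations,
            tail=1,
            seed=seed,
            out_type="mask",
            verbose="error",
        )
        mask = np.zeros(data.shape[1:], dtype=bool)
        for cl, pv in zip(clusters, cluster_pv):
            if pv < alpha:
                mask |= cl
        masks[name] = mask
    return masks
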