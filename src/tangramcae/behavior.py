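"""Response-time statistics across representation dimensions and repetitions.

Group tests operate on subject-level means of normalized reaction times
(z-scored log RT within subject), with the subject as the unit of analysis.
Nonparametric Wilcoxon tests are used throughout: rank-sum between stimulus
groups, signed-rank across subjects for within-subject contrasts, with
BH-FDR over the family of dimension tests.  Change-of-mind detection flags
subject-image response sequences with exactly one animal/non-animal
transition over the five presentations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_rt",
    "dimension_rt_tests",
    "repetition_curve",
    "detect_change_of_mind",
    "ChangeOfMindRecord",
]

_SD_FLOOR = 1e-12


def normalize_rt(trials: pd.DataFrame, method: str = "zlog") -> pd.DataFrame:
    """Add a ``normalized_rt`` column: within-subject z of log RT.

    ``method='z'`` z-scores raw RTs instead.  Subjects need >= 10 trials;
    constant RTs map to zeros (SD floor guard).
    """
    if method not in ("zlog", "z"):
        raise ValueError(f"unknown normalization {method!r}")
    out = trials.copy()
    vals = np.log(out.rt.to_numpy()) if method == "zlog" else out.rt.to_numpy()
    out["_v"] = vals
    norm = np.empty(len(out))
    for _, grp in out.groupby("subject", sort=False):
        if len(grp) < 10:
            raise ValueError(
                f"subject {grp.subject.iloc[0]!r} has fewer than 10 trials"
            )
        v = grp["_v"].to_numpy()
        sd = v.std(ddof=0)
        norm[out.index.get_indexer(grp.index)] = (
            (v - v.mean()) / sd if sd > _SD_FLOOR else np.zeros(len(v))
        )
    out["normalized_rt"] = norm
    return out.drop(columns="_v")


def _subject_group_means(
    trials: pd.DataFrame, group_col: str, groups: tuple
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject mean normalized RT in two stimulus groups (paired)."""
    means = (
        trials[trials[group_col].isin(groups)]
        .groupby(["subject", group_col], observed=True)
        .normalized_rt.mean()
        .unstack(group_col)
        .dropna()
    )
    return means[groups[0]].to_numpy(), means[groups[1]].to_numpy()


def dimension_rt_tests(
    trials: pd.DataFrame,
    stimulus_table: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon tests of normalized RT between dimension groups, FDR-corrected.

    Tests abstraction (high vs low tertile), animacy (animal vs non-animal
    stimuli), LFD (high vs low tertile) and local deviation (high vs low,
    median split).  Group statistics use subject-level mean normalized RTs
    with signed-rank tests on the paired per-subject differences: every
    contrast is within-subject, and per-subject normalization makes the two
    group means anti-correlated, which invalidates an unpaired rank-sum.
    """
    stim = stimulus_table.set_index("figure_id")
    df = trials.merge(
        stim[[c for c in ("abstraction_tertile", "lfd_tertile", "animacy_binary",
                          "local_deviation") if c in stim.columns]],
        left_on="figure_id", right_index=True, how="left",
    )
    if "local_deviation" in df.columns:
        med = stim.local_deviation.median()
        df["ldev_group"] = np.where(df.local_deviation > med, "high", "low")
    rows = []

    def _one(dimension, col, groups, flavor):
        if col not in df.columns:
            return
        a, b = _subject_group_means(df, col, groups)
        if len(a) == 0 or len(b) == 0:
            return
        if flavor == "ranksum":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
        else:
            diff = a - b
            if np.allclose(diff, 0):
                rows.append({"dimension": dimension, "W": 0.0, "p": 1.0,
                             "direction": "none", "n_subjects": len(a)})
                return
            mode = "exact" if len(diff) <= 25 else "auto"
            res = stats.wilcoxon(diff, alternative="two-sided", mode=mode)
        direction = f"{groups[0]}>{groups[1]}" if a.mean() > b.mean() \
            else f"{groups[1]}>{groups[0]}"
        rows.append({"dimension": dimension, "W": float(res.statistic),
                     "p": float(res.pvalue), "direction": direction,
                     "n_subjects": len(a)})

    _one("abstraction", "abstraction_tertile", ("high", "low"), "signedrank")
    if "animacy_binary" in df.columns:
        df["animacy_group"] = np.where(df.animacy_binary == 1, "animal", "non-animal")
        _one("animacy", "animacy_group", ("animal", "non-animal"), "signedrank")
    _one("lfd", "lfd_tertile", ("high", "low"), "signedrank")
    _one("local_deviation", "ldev_group", ("high", "low"), "signedrank")

    out = pd.DataFrame(rows)
    if len(out):
        sig, p_adj = multipletests(out.p, alpha=q, method="fdr_bh")[:2]
        out["p_fdr"] = p_adj
        out["significant"] = sig
    return out


def repetition_curve(trials: pd.DataFrame, q: float = 0.05) -> dict:
    """Normalized RT across presentations 1-5 with adjacent-pair tests.

    Returns per-presentation subject-mean RT with CIs, signed-rank tests of
    adjacent presentations (FDR-corrected), and the trial-level Pearson
    correlation between presentation index and normalized RT.
    """
    pres = sorted(trials.presentation.unique())
    if len(pres) < 2:
        raise ValueError("need at least two presentations")
    subj_means = (
        trials.groupby(["subject", "presentation"])
        .normalized_rt.mean()
        .unstack("presentation")
        .dropna()
    )
    curve = pd.DataFrame(
        {
            "presentation": pres,
            "mean": [subj_means[p].mean() for p in pres],
            "sem": [
                subj_means[p].std(ddof=1) / np.sqrt(len(subj_means)) for p in pres
            ],
        }
    )
    tests = []
    for p1, p2 in zip(pres[:-1], pres[1:]):
        diff = (subj_means[p1] - subj_means[p2]).to_numpy()
        if np.allclose(diff, 0):
            w, p = 0.0, 1.0
        else:
            mode = "exact" if len(diff) <= 25 else "auto"
            res = stats.wilcoxon(diff, alternative="two-sided", mode=mode)
            w, p = float(res.statistic), float(res.pvalue)
        tests.append({"pair": f"{p1}v{p2}", "W": w, "p": p})
    tests = pd.DataFrame(tests)
    sig, p_adj = multipletests(tests.p, alpha=q, method="fdr_bh")[:2]
    tests["p_fdr"] = p_adj
    tests["significant"] = sig
    r, r_p = stats.pearsonr(trials.presentation, trials.normalized_rt)
    return {"curve": curve, "adjacent_tests": tests,
            "correlation_r": float(r), "correlation_p": float(r_p)}


@dataclass
class ChangeOfMindRecord:
    """One subject-image pair with a single response reversal."""

    subject: str
    figure_id: str
    direction: str  # "activation" (non-animal -> animal) or "suppression"
    transition_index: int  # presentation at which the response flipped (2-5)


def detect_change_of_mind(
    trials: pd.DataFrame,
    animal_response: str = "animal",
    tangram_only: bool = True,
    stimulus_table: pd.DataFrame | None = None,
) -> tuple[list[ChangeOfMindRecord], dict]:
    """Flag subject-image response sequences with exactly one transition.

    A pair qualifies when its ordered responses across presentations contain
    exactly one animal/non-animal switch; the direction is "activation"
    (non-animal to animal) or "suppression".  The image-level expected count
    is the mean over subjects of per-subject flagged-image counts
    (fractional values allowed), and the fraction divides by the number of
    analyzable (tangram) images.
    """
    df = trials
    if tangram_only and stimulus_table is not None and \
            "is_tangram" in stimulus_table.columns:
        keep = set(stimulus_table.loc[stimulus_table.is_tangram, "figure_id"])
        df = df[df.figure_id.isin(keep)]
    records: list[ChangeOfMindRecord] = []
    per_subject_counts: dict[str, int] = {}
    n_images = df.figure_id.nunique()
    for (subject, fid), grp in df.groupby(["subject", "figure_id"], sort=False):
        grp = grp.sort_values("presentation")
        if len(grp) < 2:
            continue
        seq = (grp.response == animal_response).astype(int).to_numpy()
        flips = np.flatnonzero(np.diff(seq) != 0)
        if len(flips) != 1:
            per_subject_counts.setdefault(subject, 0)
            continue
        direction = "activation" if seq[flips[0] + 1] == 1 else "suppression"
        records.append(
            ChangeOfMindRecord(
                subject=subject,
                figure_id=fid,
                direction=direction,
                transition_index=int(grp.presentation.iloc[flips[0] + 1]),
            )
        )
        per_subject_counts[subject] = per_subject_counts.get(subject, 0) + 1
    n_subjects = df.subject.nunique()
    expected_count = (
        sum(per_subject_counts.values()) / n_subjects if n_subjects else 0.0
    )
    summary = {
        "n_images": n_images,
        "n_subjects": n_subjects,
        "expected_image_count": expected_count,
        "fraction": expected_count / n_images if n_images else 0.0,
        "n_activation": sum(r.direction == "activation" for r in records),
        "n_suppression": sum(r.direction == "suppression" for r in records),
    }
    return records, summary
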