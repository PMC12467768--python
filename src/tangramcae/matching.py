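"""The 10-candidate annotation-matching task over cognitive-associative codes.

A matching trial presents one annotation (a whole-figure label, or the bag
of part labels of a figure) and ten candidate figures; the task is to pick
the figure the annotation describes.  The matcher is a multi-class SVM over
vectorized encodings: each of the 21 pairwise relation cells is expanded to
five binary indicators (one per nonzero relation code, 105 features total)
because the codes are nominal, not ordinal.  At test time the candidate
whose encoding scores highest for the query label is chosen; chance is 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .geometry import CAEMatrix

__all__ = [
    "MatchingTrial",
    "MatchingResult",
    "encode_features",
    "AnnotationMatcher",
    "train_matcher",
    "run_matching",
]

_IU = np.triu_indices(7, k=1)


def encode_features(matrices) -> np.ndarray:
    """One-hot expand encodings to (n, 105): 21 cells x codes 1..5."""
    mats = np.stack(
        [m.weights if isinstance(m, CAEMatrix) else np.asarray(m) for m in matrices]
    )
    cells = mats[:, _IU[0], _IU[1]]  # (n, 21), values 0..5
    feats = np.zeros((len(mats), 21, 5))
    for code in range(1, 6):
        feats[:, :, code - 1] = cells == code
    return feats.reshape(len(mats), 105)


@dataclass
class MatchingTrial:
    """One 10-choice trial: a query annotation and ten candidate figures."""

    trial_id: str
    query_label: str
    candidates: list[str]
    correct: str
    condition: str = "whole+black"

    def __post_init__(self) -> None:
        if len(self.candidates) != 10:
            raise ValueError(f"{self.trial_id}: need exactly 10 candidates")
        if self.correct not in self.candidates:
            raise ValueError(f"{self.trial_id}: correct id not among candidates")


@dataclass
class MatchingResult:
    """Per-trial choices and overall accuracy for one condition."""

    chosen: dict[str, str]
    accuracy: float
    n_trials: int
    n_skipped: int = 0
    condition: str = "whole+black"
    chance: float = 0.1


class AnnotationMatcher(BaseEstimator, ClassifierMixin):
    """SVM label-scoring model over one-hot CAE features (sklearn API).

    ``fit`` takes encodings (list of 7x7 matrices or an (n, 105) feature
    array) and their label strings; ``score_label`` returns the decision
    score of one label for each of a set of candidate encodings.
    """

    def __init__(self, kernel: str = "rbf", C: float = 1.0, seed: int = 0):
        self.kernel = kernel
        self.C = C
        self.seed = seed

    @staticmethod
    def _features(X) -> np.ndarray:
        X = np.asarray(X) if not isinstance(X, list) else X
        if isinstance(X, np.ndarray) and X.ndim == 2 and X.shape[1] == 105:
            return X
        return encode_features(X)

    def fit(self, X, y):
        Xf = self._features(X)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least two labels")
        if counts.min() < 2:
            raise ValueError("every label needs at least two examples")
        self.svc_ = SVC(
            kernel=self.kernel,
            C=self.C,
            decision_function_shape="ovr",
            random_state=self.seed,
        )
        self.svc_.fit(Xf, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(self._features(X))

    def decision_scores(self, X) -> np.ndarray:
        """(n, n_classes) one-vs-rest decision values."""
        check_is_fitted(self, "svc_")
        scores = self.svc_.decision_function(self._features(X))
        if scores.ndim == 1:  # binary SVC: expand to two columns
            scores = np.column_stack([-scores, scores])
        return scores

    def score_label(self, label: str, X) -> np.ndarray:
        """Decision score of one label for each candidate encoding.

        Unseen labels score 0 for every candidate (with a warning).
        """
        check_is_fitted(self, "svc_")
        Xf = self._features(X)
        if label not in self.classes_:
            warnings.warn(f"label {label!r} unseen at training time; scoring 0",
                          stacklevel=2)
            return np.zeros(len(Xf))
        col = int(np.where(self.classes_ == label)[0][0])
        return self.decision_scores(Xf)[:, col]


def train_matcher(
    train_set: list[tuple[CAEMatrix | np.ndarray, str]],
    kernel: str = "rbf",
    seed: int = 0,
    C: float = 1.0,
) -> AnnotationMatcher:
    """Fit an :class:`AnnotationMatcher` on (encoding, label) pairs."""
    X = [m for m, _ in train_set]
    y = [lab for _, lab in train_set]
    return AnnotationMatcher(kernel=kernel, C=C, seed=seed).fit(X, y)


def run_matching(
    matcher: AnnotationMatcher,
    trials: list[MatchingTrial],
    encodings: dict[str, CAEMatrix | np.ndarray],
    part_bags: dict[str, list[str]] | None = None,
) -> MatchingResult:
    """Score every trial's candidates and report 10-choice accuracy.

    For part-label trials (``query_label`` of the form ``parts:<figure>``,
    or when ``part_bags`` supplies the bag), the candidate score is the sum
    of per-part-label scores.  Ties break toward the lowest candidate index.
    Trials with a missing candidate encoding are skipped (and excluded from
    the denominator) with a warning.
    """
    chosen: dict[str, str] = {}
    n_correct = 0
    n_skipped = 0
    condition = trials[0].condition if trials else "whole+black"
    for trial in trials:
        missing = [c for c in trial.candidates if c not in encodings]
        if missing:
            warnings.warn(
                f"{trial.trial_id}: missing encodings for {missing}; trial skipped",
                stacklevel=2,
            )
            n_skipped += 1
            continue
        cand_mats = [encodings[c] for c in trial.candidates]
        labels = (
            part_bags.get(trial.query_label, [trial.query_label])
            if part_bags is not None
            else [trial.query_label]
        )
        scores = np.zeros(10)
        for lab in labels:
            scores += matcher.score_label(lab, cand_mats)
        pick = trial.candidates[int(np.argmax(scores))]
        chosen[trial.trial_id] = pick
        n_correct += pick == trial.correct
    n_scored = len(trials) - n_skipped
    acc = n_correct / n_scored if n_scored else float("nan")
    return MatchingResult(
        chosen=chosen,
        accuracy=acc,
        n_trials=n_scored,
        n_skipped=n_skipped,
        condition=condition,
    )
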