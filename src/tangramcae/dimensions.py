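"""Per-figure representation dimensions: animacy, abstraction, LFD.

Animacy is the fraction of a figure's global annotation labels whose head
noun names an animate entity.  Abstraction is operationalized as annotation
diversity: the normalized Shannon entropy of the label distribution (a
figure everyone names the same way scores 0; one where every annotator says
something different scores 1).  Local feature density (LFD) measures how
much of a figure's categorical discriminability is carried by small-scale
connection patterns versus the full configuration, read off a decision-tree
classification profile computed at varying encoding-matrix granularity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .geometry import CAEMatrix

__all__ = [
    "ANIMATE_LEXICON",
    "AnnotationSet",
    "StimulusRecord",
    "GranularityProfile",
    "animacy_score",
    "abstraction_level",
    "canonical_label",
    "granularity_profile",
    "lfd",
    "local_deviation",
    "fit_dimension_tree",
    "assign_tertiles",
    "select_stimuli",
]

#: Editable list of animate head nouns (animals, people, agentive roles).
ANIMATE_LEXICON: frozenset[str] = frozenset(
    """
    animal dog cat bird fish horse cow sheep goat pig rabbit fox wolf bear
    deer moose elk lion tiger leopard cheetah elephant giraffe zebra camel
    monkey ape gorilla chimp human person man woman child baby boy girl
    dancer runner swimmer skater worker farmer hunter soldier knight king
    queen wizard witch angel ghost giant dwarf clown athlete player rider
    duck goose swan chicken rooster hen turkey owl eagle hawk falcon crow
    raven sparrow robin penguin ostrich flamingo stork crane heron gull
    parrot peacock dove pigeon hummingbird woodpecker kingfisher
    snake lizard turtle tortoise frog toad salamander crocodile alligator
    dinosaur dragon whale dolphin shark seal walrus otter octopus squid
    crab lobster shrimp snail slug worm insect bug beetle butterfly moth
    bee wasp ant spider scorpion fly mosquito dragonfly grasshopper cricket
    mouse rat squirrel chipmunk hamster hedgehog bat mole kangaroo koala
    panda raccoon skunk badger weasel ferret mongoose meerkat sloth
    runner dancer swimmer priest monk nun sailor pirate cowboy ninja robot
    mermaid centaur unicorn phoenix griffin yeti
    """.split()
)

_PLURAL_EXCEPTIONS = {"geese": "goose", "mice": "mouse", "men": "man",
                      "women": "woman", "children": "child", "people": "person",
                      "wolves": "wolf", "foxes": "fox"}


def canonical_label(label: str) -> str:
    """Lowercase and singularize a free-text annotation label."""
    s = label.strip().lower()
    if s in _PLURAL_EXCEPTIONS:
        return _PLURAL_EXCEPTIONS[s]
    if s.endswith("ies") and len(s) > 4:
        return s[:-3] + "y"
    for suf in ("ches", "shes", "sses", "xes", "zes"):
        if s.endswith(suf):
            return s[:-2]
    if s.endswith("s") and not s.endswith("ss") and len(s) > 3:
        return s[:-1]
    return s


def _head_in_lexicon(label: str, lexicon: frozenset[str]) -> bool:
    """Match the final noun token, raw or singularized, against the lexicon."""
    if not label.strip():
        return False
    head = label.split()[-1].lower()
    return head in lexicon or canonical_label(head) in lexicon


@dataclass
class AnnotationSet:
    """Free-text annotations of one figure: whole-figure and per-piece labels."""

    figure_id: str
    global_labels: list[tuple[str, str]]  # (annotator, label)
    part_labels: list[tuple[str, str, str]] = field(default_factory=list)
    # (annotator, piece_id, part string such as "head" / "leg" / "wing")

    def __post_init__(self) -> None:
        if len(self.global_labels) < 1:
            raise ValueError(f"{self.figure_id}: at least one global label required")
        if len(self.global_labels) < 10:
            warnings.warn(
                f"{self.figure_id}: fewer than 10 global annotations "
                f"({len(self.global_labels)})",
                stacklevel=2,
            )

    @property
    def labels(self) -> list[str]:
        return [lab for _, lab in self.global_labels]

    @property
    def part_tags(self) -> frozenset[str]:
        return frozenset(canonical_label(tag) for _, _, tag in self.part_labels)


def animacy_score(
    ann: AnnotationSet, lexicon: frozenset[str] | None = None
) -> float:
    """Fraction of global labels whose head noun is in the animate lexicon."""
    lexicon = ANIMATE_LEXICON if lexicon is None else lexicon
    labels = ann.labels
    if not labels:
        raise ValueError(f"{ann.figure_id}: no global annotations")
    hits = sum(_head_in_lexicon(lab, lexicon) for lab in labels)
    return hits / len(labels)


def abstraction_level(ann: AnnotationSet) -> float:
    """Normalized Shannon entropy of the canonicalized label distribution.

    H(counts) / log(n_labels), so 0 = perfect agreement, 1 = all distinct.
    """
    labels = [canonical_label(lab) for lab in ann.labels]
    if len(labels) < 2:
        raise ValueError(f"{ann.figure_id}: need >= 2 labels for abstraction")
    counts = pd.Series(labels).value_counts().to_numpy(dtype=float)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(h / np.log(len(labels)))


# ---------------------------------------------------------------------------
# granularity profile and local feature density

_CELLS = list(zip(*np.triu_indices(7, k=1)))  # the 21 upper-triangle cells


def _cell_columns(matrices: np.ndarray) -> np.ndarray:
    """(n, 21) matrix of upper-triangle codes."""
    iu = np.triu_indices(7, k=1)
    return matrices[:, iu[0], iu[1]]


def _gini_gain(x: np.ndarray, y: np.ndarray) -> float:
    """Impurity decrease of the best single threshold split on one cell."""
    tree = DecisionTreeClassifier(max_depth=1, random_state=0)
    tree.fit(x.reshape(-1, 1), y)
    if tree.tree_.node_count < 3:
        return 0.0
    t = tree.tree_
    n = t.n_node_samples[0]
    return float(
        t.impurity[0]
        - (t.n_node_samples[1] / n) * t.impurity[1]
        - (t.n_node_samples[2] / n) * t.impurity[2]
    )


@dataclass
class GranularityProfile:
    """Cross-validated accuracy of category decoding at each matrix scale.

    ``accuracy[s]`` is the decision-tree accuracy when the classifier sees
    only the best s-piece submatrix of the encoding; ``chance`` is the
    majority-class frequency.  Scale 2 (single connections) is the "local"
    task, scale 7 (full matrix) the "global" one.

    The local and global contributions decompose hierarchically: the local
    excess is what the best single connection achieves above chance, and the
    global excess is what the full configuration adds *beyond* the local
    scale.  Because the full matrix nests every local cell, its raw accuracy
    cannot fall below the local one; the incremental decomposition is what
    makes the two contributions complementary (and capable of the trade-off
    seen empirically between local and global information).
    """

    accuracy: dict[int, float]
    chance: float
    local_scale: int = 2
    global_scale: int = 7

    @property
    def local_excess(self) -> float:
        return max(self.accuracy[self.local_scale] - self.chance, 0.0)

    @property
    def global_excess(self) -> float:
        return max(
            self.accuracy[self.global_scale] - self.accuracy[self.local_scale], 0.0
        )


def _subset_cells(subset: tuple[int, ...]) -> list[int]:
    """Indices into the 21 upper-triangle cells covered by a piece subset."""
    return [
        k for k, (i, j) in enumerate(_CELLS) if i in subset and j in subset
    ]


def granularity_profile(
    dataset: list[tuple[CAEMatrix | np.ndarray, object]],
    scales: tuple[int, ...] = (2, 3, 4, 5, 6, 7),
    cv_folds: int = 5,
    seed: int = 0,
    max_depth: int = 4,
) -> GranularityProfile:
    """Classification accuracy as a function of encoding-matrix granularity.

    For each scale s, the best single s-piece submatrix is chosen on the
    training folds by the summed Gini gain of its cells, and a CART tree
    (depth ``max_depth``) restricted to those cells is scored on the held-out
    fold.
    """
    mats = np.stack(
        [m.weights if isinstance(m, CAEMatrix) else np.asarray(m) for m, _ in dataset]
    )
    y = np.asarray([lab for _, lab in dataset])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("granularity profile needs >= 2 classes")
    if counts.min() < max(cv_folds, 5):
        raise ValueError(
            f"every class needs >= {max(cv_folds, 5)} examples for "
            f"{cv_folds}-fold stratified CV"
        )
    X = _cell_columns(mats)
    chance = float(counts.max() / counts.sum())
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    fold_gains = [
        np.array([_gini_gain(X[tr, k], y[tr]) for k in range(21)]) for tr, _ in folds
    ]

    def _tree_acc(tr, te, cells) -> float:
        tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
        tree.fit(X[np.ix_(tr, cells)], y[tr])
        return float(tree.score(X[np.ix_(te, cells)], y[te]))

    def _best_cells(gains, s) -> list[int]:
        best_subset, best_score = [], -1.0
        for subset in itertools.combinations(range(7), s):
            cells = _subset_cells(subset)
            score = gains[cells].sum() if cells else 0.0
            if score > best_score:
                best_subset, best_score = cells, score
        return best_subset

    accuracy: dict[int, float] = {}
    for s in scales:
        if not 1 <= s <= 7:
            raise ValueError(f"scale must be 1..7, got {s}")
        fold_acc = []
        for (tr, te), gains in zip(folds, fold_gains):
            cells = _best_cells(gains, s)
            if not cells:  # s == 1: no visible cells, predict majority
                maj = classes[np.argmax([np.sum(y[tr] == c) for c in classes])]
                fold_acc.append(float(np.mean(y[te] == maj)))
                continue
            fold_acc.append(_tree_acc(tr, te, cells))
        accuracy[s] = float(np.mean(fold_acc))
    return GranularityProfile(accuracy=accuracy, chance=chance)


def lfd(profile: GranularityProfile) -> float:
    """Local feature density: the local share of above-chance discriminability.

    lfd = local_excess / (local_excess + global_excess), with both terms
    floored at zero; 0.5 when neither scale beats chance.  The local excess
    is the best single connection's accuracy above chance and the global
    excess is the increment the full matrix adds beyond the local scale, so
    the two terms partition the total discriminability into complementary
    shares.
    """
    le, ge = profile.local_excess, profile.global_excess
    if le + ge == 0.0:
        return 0.5
    return float(le / (le + ge))


def local_deviation(lfd_values: np.ndarray | list[float]) -> np.ndarray:
    """Absolute deviation of each figure's LFD from the set median."""
    v = np.asarray(lfd_values, dtype=float)
    if v.size < 3:
        raise ValueError("local deviation needs >= 3 figures")
    return np.abs(v - np.median(v))


def fit_dimension_tree(
    dataset: list[tuple[CAEMatrix | np.ndarray, object]],
    max_depth: int = 4,
    seed: int = 0,
) -> tuple[DecisionTreeClassifier, pd.DataFrame]:
    """CART tree over the 21 connection cells plus ranked cell importances.

    Returns the fitted tree and a table (cell i, j, Gini importance) sorted
    by importance, identifying the critical local connections for the target
    dimension.
    """
    mats = np.stack(
        [m.weights if isinstance(m, CAEMatrix) else np.asarray(m) for m, _ in dataset]
    )
    y = np.asarray([lab for _, lab in dataset])
    if len(np.unique(y)) < 2:
        raise ValueError("target dimension is constant; nothing to classify")
    X = _cell_columns(mats)
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    tree.fit(X, y)
    table = pd.DataFrame(
        {
            "piece_i": [i for i, _ in _CELLS],
            "piece_j": [j for _, j in _CELLS],
            "importance": tree.feature_importances_,
        }
    ).sort_values("importance", ascending=False, ignore_index=True)
    return tree, table


# ---------------------------------------------------------------------------
# stimulus records and curation


@dataclass
class StimulusRecord:
    """One stimulus with its dimension scores and group assignments."""

    figure_id: str
    animacy_score: float
    abstraction: float
    lfd: float
    local_deviation: float = 0.0
    feature_tags: frozenset[str] = frozenset()
    is_tangram: bool = True
    animacy_binary: int | None = None
    abstraction_tertile: str | None = None
    lfd_tertile: str | None = None
    group_index: int | None = None


_TERTILE_NAMES = ("low", "medium", "high")


def assign_tertiles(values: np.ndarray) -> list[str]:
    """Empirical terciles (ties to the lower bin), near-equal occupancy."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="stable")
    out = [""] * len(v)
    for rank, idx in enumerate(order):
        out[idx] = _TERTILE_NAMES[min(rank * 3 // len(v), 2)]
    return out


def select_stimuli(
    records: list[StimulusRecord],
    n_target: int,
    seed: int = 0,
    lfd_trim: float = 0.05,
) -> pd.DataFrame:
    """Curate a balanced stimulus set from a scored pool.

    Figures with extreme LFD (outside the ``lfd_trim``..``1 - lfd_trim``
    quantiles) are excluded first; the remainder is greedily drawn to fill
    the (animacy x abstraction-tertile x LFD-tertile) cells as evenly as
    possible.  The returned table carries tertile assignments and the
    nine-group ordering used for RDM displays: groups 1-8 cross binary
    animacy, abstraction (split at the median) and LFD (split at the
    median); group 9 collects non-tangram (natural-image) controls.
    """
    if len(records) < n_target:
        raise ValueError(f"pool of {len(records)} smaller than target {n_target}")
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "figure_id": [r.figure_id for r in records],
            "animacy_score": [r.animacy_score for r in records],
            "abstraction": [r.abstraction for r in records],
            "lfd": [r.lfd for r in records],
            "local_deviation": [r.local_deviation for r in records],
            "is_tangram": [r.is_tangram for r in records],
        }
    )
    tang = df[df.is_tangram]
    lo, hi = np.quantile(tang.lfd, [lfd_trim, 1 - lfd_trim]) if len(tang) else (0, 1)
    eligible = df[(~df.is_tangram) | ((df.lfd >= lo) & (df.lfd <= hi))].copy()
    if len(eligible) < n_target:
        eligible = df.copy()

    eligible["animacy_binary"] = (eligible.animacy_score >= 0.5).astype(int)
    eligible["abstraction_tertile"] = assign_tertiles(eligible.abstraction.to_numpy())
    eligible["lfd_tertile"] = assign_tertiles(eligible.lfd.to_numpy())
    eligible["cell"] = (
        eligible.animacy_binary.astype(str)
        + "|" + eligible.abstraction_tertile
        + "|" + eligible.lfd_tertile
    )

    cells = sorted(eligible.cell.unique())
    pools = {
        c: list(rng.permutation(eligible.index[eligible.cell == c].to_numpy()))
        for c in cells
    }
    chosen: list[int] = []
    while len(chosen) < n_target:
        progressed = False
        for c in cells:
            if pools[c] and len(chosen) < n_target:
                chosen.append(pools[c].pop())
                progressed = True
        if not progressed:
            warnings.warn(
                f"balance infeasible: only {len(chosen)} of {n_target} filled; "
                f"cell counts {[len(pools[c]) for c in cells]}",
                stacklevel=2,
            )
            break
    sel = eligible.loc[chosen].copy()

    # nine-group ordering for RDM displays
    abs_med = sel[sel.is_tangram].abstraction.median()
    lfd_med = sel[sel.is_tangram].lfd.median()
    group = np.where(
        ~sel.is_tangram,
        9,
        1
        + 4 * sel.animacy_binary
        + 2 * (sel.abstraction > abs_med).astype(int)
        + (sel.lfd > lfd_med).astype(int),
    )
    sel["group_index"] = group
    sel = sel.sort_values(["group_index", "figure_id"], ignore_index=True)
    ldev = local_deviation(sel.lfd.to_numpy()) if len(sel) >= 3 else 0.0
    sel["local_deviation"] = ldev
    return sel.drop(columns=["cell"])
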