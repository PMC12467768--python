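"""Animacy, abstraction, LFD semantics, dimension trees, stimulus curation."""

import numpy as np
import pandas as pd
import pytest

from tangramcae import (
    AnnotationSet,
    StimulusRecord,
    abstraction_level,
    animacy_score,
    fit_dimension_tree,
    granularity_profile,
    lfd,
    local_deviation,
    select_stimuli,
)
from tangramcae.dimensions import GranularityProfile, assign_tertiles


def _ann(labels, fid="f0"):
    return AnnotationSet(
        figure_id=fid,
        global_labels=[(f"a{i}", lab) for i, lab in enumerate(labels)],
    )


class TestAnimacy:
    def test_all_animate(self):
        assert animacy_score(_ann(["dog", "cat", "bird", "dancer"] * 3)) == 1.0

    def test_all_inanimate(self):
        assert animacy_score(_ann(["house", "bridge"] * 5)) == 0.0

    def test_fraction(self):
        labels = ["dog"] * 6 + ["house"] * 4
        assert animacy_score(_ann(labels)) == pytest.approx(0.6)

    def test_head_noun_matching(self):
        # the final noun token decides; plural forms are singularized
        assert animacy_score(_ann(["big dogs"] * 10)) == 1.0
        assert animacy_score(_ann(["dog house"] * 10)) == 0.0


class TestAbstraction:
    def test_identical_labels(self):
        assert abstraction_level(_ann(["dog"] * 10)) == 0.0

    def test_all_distinct(self):
        labels = ["dog", "cat", "bird", "fish", "horse",
                  "house", "boat", "tree", "lamp", "chair"]
        assert abstraction_level(_ann(labels)) == pytest.approx(1.0)

    def test_532_counts(self):
        """Counts (5,3,2) over 10 labels: H = 1.0297 nats / ln 10 = 0.4472."""
        labels = ["dog"] * 5 + ["cat"] * 3 + ["house"] * 2
        assert abstraction_level(_ann(labels)) == pytest.approx(0.4472, abs=1e-3)

    def test_merging_labels_never_increases_entropy(self, rng):
        words = ["dog", "cat", "bird", "house", "boat", "tree"]
        for _ in range(20):
            labels = list(rng.choice(words, size=12))
            base = abstraction_level(_ann(labels))
            distinct = sorted(set(labels))
            if len(distinct) < 2:
                continue
            merged = [distinct[0] if l == distinct[1] else l for l in labels]
            assert abstraction_level(_ann(merged)) <= base + 1e-12

    def test_too_few_labels(self):
        with pytest.raises(ValueError):
            abstraction_level(_ann(["dog"]))


def _planted_dataset(rng, n, rule):
    """Random encodings labeled by a planted rule on the matrix."""
    iu = np.triu_indices(7, k=1)
    data = []
    for _ in range(n):
        w = np.zeros((7, 7), dtype=int)
        w[iu] = rng.integers(0, 3, 21)
        w = w + w.T
        data.append((w, rule(w)))
    return data


class TestGranularityAndLfd:
    def test_independent_labels_near_chance(self, rng):
        data = _planted_dataset(rng, 120, lambda w: 0)
        data = [(w, int(rng.random() < 0.5)) for w, _ in data]
        prof = granularity_profile(data, scales=(2, 7), seed=0)
        for acc in prof.accuracy.values():
            # binomial 95% band around the majority-class chance level
            assert abs(acc - prof.chance) < 2.5 * np.sqrt(0.25 / 120) + 0.05

    def test_single_cell_rule_local_scale(self, rng):
        """A label readable from one cell is decoded at the 2-piece scale
        and carries no information in the rest of the configuration."""
        data = _planted_dataset(rng, 120, lambda w: int(w[1, 3] >= 1))
        prof = granularity_profile(data, scales=(2, 7), seed=0)
        assert prof.accuracy[2] > 0.95
        assert prof.accuracy[7] > 0.95  # the full matrix nests the cell
        assert lfd(prof) > 0.8  # the full matrix adds nothing beyond the cell

    def test_parity_rule_needs_global_scale(self, rng):
        """Total-edge-count parity is invisible to any single connection.

        Encodings vary in two cells only, so the parity of the total count
        is their XOR: a relational rule no single cell can decode.
        """
        iu = np.triu_indices(7, 1)

        def make(n):
            out = []
            for _ in range(n):
                w = np.zeros((7, 7), dtype=int)
                w[0, 1] = w[1, 0] = rng.integers(0, 2)
                w[2, 3] = w[3, 2] = rng.integers(0, 2)
                w[4, 5] = w[5, 4] = 2  # constant cells leave parity unchanged
                out.append((w, int(np.sum(w[iu]) % 2)))
            return out

        data = make(240)
        prof = granularity_profile(data, scales=(2, 7), seed=0)
        assert prof.accuracy[7] > prof.accuracy[2] + 0.1
        assert lfd(prof) < 0.2

    def test_lfd_bounds_and_edge_cases(self):
        # all discriminability local: the global scale adds nothing
        all_local = GranularityProfile(accuracy={2: 0.8, 7: 0.8}, chance=0.5)
        assert lfd(all_local) == 1.0
        only_global = GranularityProfile(accuracy={2: 0.5, 7: 0.9}, chance=0.5)
        assert lfd(only_global) == 0.0
        neither = GranularityProfile(accuracy={2: 0.5, 7: 0.5}, chance=0.5)
        assert lfd(neither) == 0.5
        split = GranularityProfile(accuracy={2: 0.7, 7: 0.9}, chance=0.5)
        assert lfd(split) == pytest.approx(0.5)
        below = GranularityProfile(accuracy={2: 0.3, 7: 0.7}, chance=0.5)
        assert 0.0 <= lfd(below) <= 1.0

    def test_class_size_guard(self, rng):
        data = _planted_dataset(rng, 6, lambda w: int(w[0, 1] > 1))
        with pytest.raises(ValueError):
            granularity_profile(data, cv_folds=5)


class TestLocalDeviation:
    def test_all_equal(self):
        assert np.allclose(local_deviation([0.4, 0.4, 0.4]), 0.0)

    def test_example_values(self):
        assert np.allclose(local_deviation([0.1, 0.5, 0.9]), [0.4, 0.0, 0.4])

    def test_median_invariance(self):
        base = np.array([0.1, 0.5, 0.9])
        with_median = np.array([0.1, 0.5, 0.9, 0.5])
        assert np.allclose(local_deviation(with_median)[:3], local_deviation(base))


class TestDimensionTree:
    def test_planted_cell_has_top_importance(self, rng):
        data = _planted_dataset(rng, 200, lambda w: int(w[1, 3] >= 1))
        tree, table = fit_dimension_tree(data, seed=0)
        top = table.iloc[0]
        assert (top.piece_i, top.piece_j) == (1, 3)
        assert table.importance.sum() == pytest.approx(1.0)

    def test_noise_target_below_permutation_null(self, rng):
        data = _planted_dataset(rng, 150, lambda w: 0)
        y = rng.integers(0, 2, len(data))
        data = [(w, int(lab)) for (w, _), lab in zip(data, y)]
        _, table = fit_dimension_tree(data, max_depth=1, seed=0)
        null_max = []
        for _ in range(30):
            perm = rng.permutation(y)
            pd_ = [(w, int(l)) for (w, _), l in zip(data, perm)]
            null_max.append(fit_dimension_tree(pd_, max_depth=1, seed=0)[1]
                            .importance.max())
        assert table.importance.max() <= np.quantile(null_max, 0.97) + 1e-9

    def test_constant_target_errors(self, rng):
        data = _planted_dataset(rng, 30, lambda w: 1)
        with pytest.raises(ValueError):
            fit_dimension_tree(data)


def _pool(rng, n, tangram=True):
    return [
        StimulusRecord(
            figure_id=f"p{i:03d}",
            animacy_score=rng.uniform(0, 1),
            abstraction=rng.uniform(0, 1),
            lfd=rng.uniform(0, 1),
            is_tangram=tangram,
        )
        for i in range(n)
    ]


class TestSelectStimuli:
    def test_pool_equals_target(self, rng):
        pool = _pool(rng, 20)
        sel = select_stimuli(pool, n_target=20, lfd_trim=0.0)
        assert len(sel) == 20

    def test_balanced_selection_from_large_pool(self, rng):
        pool = _pool(rng, 900)
        sel = select_stimuli(pool, n_target=90, seed=1)
        assert len(sel) == 90
        # marginals across tertiles are near-uniform
        for col in ("abstraction_tertile", "lfd_tertile"):
            counts = sel[col].value_counts()
            assert counts.max() - counts.min() <= 2

    def test_deterministic(self, rng):
        pool = _pool(rng, 200)
        a = select_stimuli(pool, n_target=60, seed=3)
        b = select_stimuli(pool, n_target=60, seed=3)
        assert a.figure_id.tolist() == b.figure_id.tolist()

    def test_nine_groups(self, rng):
        pool = _pool(rng, 300) + _pool(np.random.default_rng(1), 30, tangram=False)
        sel = select_stimuli(pool, n_target=85, seed=0)
        groups = set(sel.group_index)
        assert groups <= set(range(1, 10))
        assert (sel.loc[~sel.is_tangram, "group_index"] == 9).all()

    def test_pool_too_small(self, rng):
        with pytest.raises(ValueError):
            select_stimuli(_pool(rng, 5), n_target=10)


def test_assign_tertiles_near_equal():
    vals = np.arange(10)
    t = assign_tertiles(vals)
    counts = pd.Series(t).value_counts()
    assert counts.max() - counts.min() <= 1
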