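"""Time-resolved decoding, pairwise image decoding, temporal generalization."""

import numpy as np
import pandas as pd
import pytest

from tangramcae import (
    SimComponent,
    SimEEGSpec,
    decode_pairwise_images,
    decode_timecourse,
    familiarity_split,
    gen_epochs,
    group_curve_stats,
    make_schedule,
    temporal_generalization,
)
from tangramcae.decoding import balance_trials


def _epochs(stim_table, schedule, components, seed=0, n_channels=12, **kw):
    spec = SimEEGSpec(n_channels=n_channels, sfreq=100, components=components,
                      seed=seed, **kw)
    return gen_epochs(spec, stim_table, schedule)


@pytest.fixture(scope="module")
def planted_epochs(stim_table, schedule):
    comp = SimComponent("anim", "animacy_binary", latency=0.45, duration=0.12,
                        effect_size=0.8, topography_seed=42)
    return _epochs(stim_table, schedule, [comp], seed=1)


class TestDecodeTimecourse:
    def test_prestim_at_chance_and_peak_at_latency(self, planted_epochs):
        curve = decode_timecourse(planted_epochs, "animacy_binary", seed=0)
        pre = curve.accuracy[curve.times < 0]
        assert abs(pre.mean() - 0.5) < 0.08
        peak_t = curve.times[np.argmax(curve.accuracy)]
        assert 0.35 <= peak_t <= 0.55
        assert curve.accuracy.max() > 0.8

    def test_shuffled_labels_null(self, planted_epochs, rng):
        y = rng.permutation(planted_epochs.metadata.animacy_binary.to_numpy())
        curve = decode_timecourse(planted_epochs, y, seed=0)
        assert abs(curve.accuracy.mean() - 0.5) < 0.06

    def test_pattern_recovery_at_peak(self, stim_table, schedule):
        """The activation pattern at peak matches the planted topography."""
        topo_seed = 7
        comp = SimComponent("anim", "animacy_binary", latency=0.3, duration=0.1,
                            effect_size=1.2, topography_seed=topo_seed)
        ep = _epochs(stim_table, schedule, [comp], seed=3)
        curve = decode_timecourse(ep, "animacy_binary", seed=0)
        planted = np.random.default_rng(topo_seed).standard_normal(12)
        planted /= np.linalg.norm(planted)
        peak = int(np.argmax(curve.accuracy))
        pat = curve.patterns[:, peak]
        cos = abs(pat @ planted) / (np.linalg.norm(pat) * np.linalg.norm(planted))
        assert cos > 0.8

    def test_group_stats_null_mask_empty(self, stim_table):
        """No planted signal: the FDR mask over timepoints stays empty."""
        curves = []
        for s in range(12):
            sched = make_schedule(stim_table.figure_id.tolist(), 1,
                                  n_presentations=8, seed=s)
            ep = _epochs(stim_table, sched, [], seed=100 + s)
            ep = ep.crop(0.0, 0.4).decimate(4)
            curves.append(decode_timecourse(ep, "animacy_binary", n_folds=4,
                                            seed=0, return_weights=False))
        stats = group_curve_stats(curves)
        assert not stats.significant.any()

    def test_single_class_errors(self, planted_epochs):
        with pytest.raises(ValueError):
            decode_timecourse(planted_epochs, np.zeros(planted_epochs.n_trials))


class TestPairwiseImages:
    def test_matrix_structure_and_recovery(self, stim_table, schedule):
        comp = SimComponent("img", "image", latency=0.3, duration=0.1,
                            effect_size=3.0, topography_seed=11)
        ep = _epochs(stim_table, schedule, [comp], seed=5).crop(0.1, 0.5)
        acc, ids = decode_pairwise_images(ep, seed=0)
        t_peak = int(np.argmin(np.abs(ep.times - 0.3)))
        A = acc[t_peak]
        assert np.allclose(A, A.T)
        assert np.allclose(np.diag(A), 0.0)
        iu = np.triu_indices(len(ids), 1)
        assert A[iu].mean() > 0.8  # distinct planted topographies decode well

    def test_null_images_near_chance(self, stim_table, schedule):
        ep = _epochs(stim_table, schedule, [], seed=6).crop(0.2, 0.3)
        acc, ids = decode_pairwise_images(ep, seed=0)
        iu = np.triu_indices(len(ids), 1)
        assert abs(acc[:, iu[0], iu[1]].mean() - 0.5) < 0.1


class TestFamiliaritySplit:
    def test_presentation_split(self, schedule):
        unfam, fam = familiarity_split(schedule)
        assert set(schedule.presentation[unfam]) == {1, 2}
        assert set(schedule.presentation[fam]) == {4, 5}
        assert not (unfam & fam).any()

    def test_rt_split(self, schedule, rng):
        meta = schedule.copy()
        meta["rt"] = rng.uniform(0.3, 2.0, len(meta))
        unfam, fam = familiarity_split(meta, mode="rt")
        assert unfam.sum() + fam.sum() == len(meta)


class TestTemporalGeneralization:
    def test_sustained_code_generalizes_in_block(self, stim_table, schedule):
        comp = SimComponent("anim", "animacy_binary", latency=0.35, duration=0.3,
                            effect_size=1.0, topography_seed=3)
        ep = _epochs(stim_table, schedule, [comp], seed=7).crop(0.0, 0.7)
        mask = np.ones(ep.n_trials, dtype=bool)
        tgm = temporal_generalization(ep, "animacy_binary", mask, mask, seed=0)
        # the sustained window cross-generalizes: a square above-chance block
        win = (ep.times >= 0.25) & (ep.times <= 0.45)
        block = tgm.accuracy[np.ix_(win, win)]
        off = tgm.accuracy[np.ix_(ep.times < 0.1, ep.times < 0.1)]
        assert block.mean() > 0.75
        assert abs(off.mean() - 0.5) < 0.1

    def test_diagonal_matches_timecourse(self, planted_epochs):
        ep = planted_epochs.crop(0.2, 0.6)
        mask = np.ones(ep.n_trials, dtype=bool)
        tgm = temporal_generalization(ep, "animacy_binary", mask, mask,
                                      n_folds=5, seed=0)
        curve = decode_timecourse(ep, "animacy_binary", n_folds=5, seed=0,
                                  return_weights=False)
        diag = np.diag(tgm.accuracy)
        assert np.abs(diag - curve.accuracy).mean() < 0.08

    def test_latency_shift_asymmetry(self, stim_table):
        """Delayed familiar-trial code puts generalization mass off-diagonal."""
        sched = make_schedule(stim_table.figure_id.tolist(), 1,
                              n_presentations=5, seed=9)
        comp = SimComponent("anim", "animacy_binary", latency=0.3, duration=0.08,
                            effect_size=1.2, topography_seed=13)
        ep = _epochs(stim_table, sched, [comp], seed=8,
                     familiarity_latency_shift=0.05).crop(0.0, 0.7)
        unfam, fam = familiarity_split(ep.metadata)
        tgm = temporal_generalization(
            ep, "animacy_binary", train_mask=fam, test_mask=unfam, seed=0,
            train_condition="familiar", test_condition="unfamiliar",
        )
        # familiar training times lag unfamiliar testing times: accuracy mass
        # sits where train_time > test_time (above the diagonal when the
        # train axis points up in the conventional TGM display)
        excess = tgm.accuracy - 0.5
        train_later = excess[tgm.train_times[:, None] > tgm.test_times[None] + 0.02]
        train_earlier = excess[tgm.train_times[:, None] < tgm.test_times[None] - 0.02]
        assert train_later.sum() > train_earlier.sum()

    def test_empty_split_errors(self, planted_epochs):
        mask = np.zeros(planted_epochs.n_trials, dtype=bool)
        with pytest.raises(ValueError):
            temporal_generalization(
                planted_epochs, "animacy_binary", mask, ~mask, seed=0
            )


class TestBalanceTrials:
    def test_covariate_composition_equalized(self, rng):
        meta = pd.DataFrame({
            "target": rng.integers(0, 2, 300),
            "cov": rng.integers(0, 3, 300),
        })
        idx = balance_trials(meta, "target", ["cov"], seed=0)
        sub = meta.loc[idx]
        tab = sub.groupby(["cov", "target"]).size().unstack()
        assert (tab[0] == tab[1]).all()
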