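"""Model RDMs, model-space MDS, time-resolved GLM, stimulus embeddings."""

import numpy as np
import pandas as pd
import pytest

from tangramcae import (
    ModelRDM,
    build_model_rdms,
    glm_group_stats,
    model_space_mds,
    stimulus_embedding,
    timewise_glm,
)


@pytest.fixture(scope="module")
def models(stim_table, random_figures):
    encodings = {
        fid: random_figures[i % len(random_figures)][1]
        for i, fid in enumerate(stim_table.figure_id)
    }
    tags = {
        fid: frozenset(np.random.default_rng(i).choice(
            ["head", "leg", "wing", "tail", "body"], 2, replace=False))
        for i, fid in enumerate(stim_table.figure_id)
    }
    return build_model_rdms(stim_table, encodings=encodings, part_tags=tags)


class TestBuildModelRdms:
    def test_six_models_with_invariants(self, models):
        assert sorted(m.name for m in models) == sorted(
            ["animacy", "abstraction", "lfd", "object_level",
             "feature_level", "connections"]
        )
        for m in models:
            assert np.allclose(m.values, m.values.T)
            assert np.allclose(np.diag(m.values), 0.0)

    def test_animacy_binary_entries(self, models):
        animacy = next(m for m in models if m.name == "animacy")
        assert set(np.unique(animacy.values)) <= {0.0, 1.0}

    def test_abstraction_is_abs_difference(self, models, stim_table):
        model = next(m for m in models if m.name == "abstraction")
        v = stim_table.abstraction.to_numpy()
        assert model.values[0, 1] == pytest.approx(abs(v[0] - v[1]))

    def test_connections_matches_cae_distance(self, models, stim_table,
                                              random_figures):
        from tangramcae import cae_distance

        conn = next(m for m in models if m.name == "connections")
        m0 = random_figures[0][1]
        m1 = random_figures[1][1]
        assert conn.values[0, 1] == pytest.approx(cae_distance(m0, m1))

    def test_missing_encodings_imputed_and_flagged(self, stim_table,
                                                   random_figures):
        encodings = {
            fid: random_figures[i % len(random_figures)][1]
            for i, fid in enumerate(stim_table.figure_id[:-2])
        }
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = build_model_rdms(stim_table, encodings=encodings)
        conn = next(m for m in models if m.name == "connections")
        assert conn.missing is not None
        assert conn.missing[-1, 0]
        present = conn.values[~conn.missing & ~np.eye(len(stim_table), dtype=bool)]
        assert conn.values[-1, 0] == pytest.approx(present.max())


class TestModelSpaceMds:
    def test_negated_model_at_distance_two(self, rng):
        n = 10
        base = np.abs(rng.standard_normal((n, n)))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 0.0)
        m1 = ModelRDM("a", base)
        m2 = ModelRDM("b", base.max() - base + 0.0)
        np.fill_diagonal(m2.values, 0.0)
        vecs = (m1.lower_triangle(), m2.lower_triangle())
        r = np.corrcoef(vecs[0], vecs[1])[0, 1]
        assert r == pytest.approx(-1.0)
        coords = model_space_mds([m1, m2, ModelRDM("c", base * 2)])
        assert set(coords.index) == {"a", "b", "c"}
        # duplicated structure (a vs c, perfectly correlated) embeds together
        d_ac = np.linalg.norm(coords.loc["a"] - coords.loc["c"])
        d_ab = np.linalg.norm(coords.loc["a"] - coords.loc["b"])
        assert d_ac < d_ab

    def test_orthogonal_models_near_unit_distance(self, rng):
        n = 30
        ms = []
        for k in range(4):
            v = rng.standard_normal((n, n))
            v = np.abs(v + v.T)
            np.fill_diagonal(v, 0.0)
            ms.append(ModelRDM(f"m{k}", v))
        coords = model_space_mds(ms)
        vecs = [m.lower_triangle() for m in ms]
        rs = [np.corrcoef(vecs[i], vecs[j])[0, 1]
              for i in range(4) for j in range(i + 1, 4)]
        assert np.abs(rs).max() < 0.3  # random models are near-orthogonal

    def test_too_few_models(self, models):
        with pytest.raises(ValueError):
            model_space_mds(models[:2])


class TestTimewiseGlm:
    def test_exact_recovery_of_planted_betas(self, models, rng):
        """Neural = 2 x model_k (standardized) without noise: OLS is exact."""
        n = len(models[0].values)
        il = np.tril_indices(n, k=-1)
        target = models[2]
        neural = np.zeros((3, n, n))
        z = target.standardized()
        for t in range(3):
            neural[t][il] = 2.0 * z
            neural[t] = neural[t] + neural[t].T
        betas = timewise_glm(neural, models)
        k = 2
        # the neural vector is z-scored, so the planted coefficient is
        # recovered up to that overall scale; other models stay near zero
        assert np.argmax(np.abs(betas[0])) == k
        others = np.delete(betas[0], k)
        assert np.abs(others).max() < 0.2 * abs(betas[0][k])

    def test_planted_time_course_rmse(self, models, rng):
        """Betas of a planted two-model time course are recovered with noise."""
        n = len(models[0].values)
        il = np.tril_indices(n, k=-1)
        T = 20
        t_axis = np.linspace(0, 1, T)
        b_conn = np.exp(-0.5 * ((t_axis - 0.3) / 0.08) ** 2)
        b_anim = np.exp(-0.5 * ((t_axis - 0.7) / 0.08) ** 2)
        conn = next(m for m in models if m.name == "connections").standardized()
        anim = next(m for m in models if m.name == "animacy").standardized()
        neural = np.zeros((T, n, n))
        for t in range(T):
            vec = b_conn[t] * conn + b_anim[t] * anim \
                + 0.3 * rng.standard_normal(len(conn))
            neural[t][il] = vec
            neural[t] = neural[t] + neural[t].T
        betas = timewise_glm(neural, models)
        names = [m.name for m in models]
        peak_conn = t_axis[np.argmax(betas[:, names.index("connections")])]
        peak_anim = t_axis[np.argmax(betas[:, names.index("animacy")])]
        assert peak_conn < peak_anim  # structure before semantics

    def test_null_group_fdr_mask_empty(self, models, rng):
        n = len(models[0].values)
        il = np.tril_indices(n, k=-1)
        T, S = 15, 10
        betas = np.empty((S, T, len(models)))
        for s in range(S):
            neural = np.zeros((T, n, n))
            for t in range(T):
                v = rng.standard_normal(len(il[0]))
                neural[t][il] = v
                neural[t] = neural[t] + neural[t].T
            betas[s] = timewise_glm(neural, models)
        stats = glm_group_stats(betas, [m.name for m in models],
                                np.arange(T, dtype=float))
        assert stats.significant.mean() < 0.1  # near-nominal false positives


class TestStimulusEmbedding:
    def test_planted_clusters(self, rng):
        n = 30
        labels = np.repeat([0, 1], n // 2)
        D = np.where(labels[:, None] == labels[None], 0.5, 1.0).astype(float)
        D += rng.uniform(0, 0.05, (n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        from sklearn.metrics import silhouette_score

        coords, tw = stimulus_embedding(D, method="tsne", seed=0)
        assert silhouette_score(coords, labels) > 0.4
        assert 0.0 <= tw <= 1.0

    def test_mds_three_points(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        coords, _ = stimulus_embedding(D, method="mds", seed=0)
        got = np.linalg.norm(coords[0] - coords[1])
        assert got == pytest.approx(3.0, rel=0.1)

    def test_identical_rows_coincide(self):
        D = np.zeros((4, 4))
        coords, _ = stimulus_embedding(D, method="mds", seed=0)
        assert np.allclose(coords - coords[0], 0.0, atol=1e-6)
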