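import numpy as np
import pytest

from fmsm.datasets import SimilarityMatrix
from fmsm.model import FMSM, DivergenceError, FmsmParams, FmsmState, FMSMResults
from fmsm.similarity import identity_similarity
from fmsm import synthetic
from tests.conftest import make_dataset


def sim(S, names=None):
    S = np.asarray(S, dtype=float)
    names = names or [f"m{i + 1}" for i in range(S.shape[0])]
    return SimilarityMatrix(names, S, np.ones(S.shape[0], dtype=bool))


class TestInitialisation:
    def test_full_rank_copies_similarity(self):
        ds = make_dataset([[1, 0], [0, 1]])
        model = FMSM(ds, sim(np.eye(2)))
        state = model.initialize()
        assert np.array_equal(state.P, np.eye(2))
        assert np.array_equal(state.P @ state.Q.T, np.eye(2))
        assert state.P is not state.Q

    def test_full_rank_product_is_similarity_squared(self, tiny):
        model = FMSM(tiny.dataset, identity_similarity(tiny.dataset.mirnas))
        S = model.mirna_similarity.S
        state = model.initialize()
        assert np.allclose(state.P @ state.Q.T, S @ S.T)

    def test_low_rank_recovers_rank_d_similarity(self):
        rng = np.random.default_rng(5)
        F = rng.normal(size=(8, 3))
        S = F @ F.T
        S = S / np.abs(S).max()  # PSD, rank 3
        np.fill_diagonal(S, 1.0)
        # make exactly rank-3 PSD without unit diagonal requirement
        S = F @ F.T
        ds = make_dataset((rng.random((4, 8)) < 0.4).astype(int))
        sm = SimilarityMatrix(ds.mirnas, S, np.ones(8, bool))
        model = FMSM(ds, sm, params=FmsmParams(latent_dim=3))
        state = model.initialize()
        assert np.linalg.norm(state.P @ state.Q.T - S) < 1e-8

    def test_latent_dim_larger_than_nm_rejected(self):
        ds = make_dataset([[1, 0], [0, 1]])
        with pytest.raises(ValueError):
            FMSM(ds, sim(np.eye(2)), params=FmsmParams(latent_dim=3))


class TestPredictRaw:
    def test_empty_neighbourhood_gives_bias_sum(self):
        ds = make_dataset([[1, 0], [0, 0]])
        model = FMSM(ds, sim(np.eye(2)))
        state = FmsmState(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        # disease d2 has no positives at all
        assert model.predict_raw(state, 1, 0) == 0.0
        # excluding the sole positive leaves an empty sum
        assert model.predict_raw(state, 0, 0) == 0.0

    def test_hand_computed_score(self):
        # two neighbours with inner products 0.3 and 0.5, alpha = 0.5:
        # r = 0.1 + 0.2 + (1/sqrt(2)) * 0.8
        ds = make_dataset([[1, 1, 1]])  # n_d+ = 3, predict for m3 (a positive)
        P = np.array([[0.3, 0.0], [0.5, 0.0], [9.9, 9.9]])
        Q = np.zeros((3, 2))
        Q[2] = [1.0, 0.0]
        state = FmsmState(P, Q, np.array([0.1]), np.array([0.0, 0.0, 0.2]))
        model = FMSM(ds, sim(np.eye(3)), params=FmsmParams(alpha=0.5))
        assert model.predict_raw(state, 0, 2) == pytest.approx(
            0.3 + 0.8 / np.sqrt(2)
        )

    def test_alpha_zero_is_unweighted_sum(self):
        ds = make_dataset([[1, 1, 1]])
        P = np.array([[0.3, 0.0], [0.5, 0.0], [0.0, 0.0]])
        Q = np.zeros((3, 2))
        Q[2] = [1.0, 0.0]
        state = FmsmState(P, Q, np.zeros(1), np.zeros(3))
        model = FMSM(ds, sim(np.eye(3)), params=FmsmParams(alpha=0.0))
        assert model.predict_raw(state, 0, 2) == pytest.approx(0.8)

    def test_score_invariant_to_own_label(self):
        # toggling U[d, m] must not change the pair's own raw score
        rng = np.random.default_rng(3)
        U = (rng.random((4, 6)) < 0.4).astype(int)
        U[1, 2] = 1
        U_off = U.copy()
        U_off[1, 2] = 0
        state = FmsmState(
            rng.normal(size=(6, 6)), rng.normal(size=(6, 6)),
            rng.normal(size=4), rng.normal(size=6),
        )
        m_on = FMSM(make_dataset(U), sim(np.eye(6)))
        m_off = FMSM(make_dataset(U_off), sim(np.eye(6)))
        assert m_on.predict_raw(state, 1, 2) == pytest.approx(
            m_off.predict_raw(state, 1, 2), abs=1e-12
        )


class TestObjective:
    def test_single_positive_zero_model(self):
        ds = make_dataset([[1]])
        model = FMSM(ds, sim(np.eye(1)), params=FmsmParams(beta=0, lam=0, gamma=0))
        state = FmsmState(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros(1), np.zeros(1))
        assert model.objective(state) == pytest.approx(0.5)

    def test_negative_predicted_at_zero_adds_nothing(self):
        ds = make_dataset([[1, 0]])
        model = FMSM(ds, sim(np.eye(2)), params=FmsmParams(beta=0, lam=0, gamma=0))
        state = FmsmState(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros(1), np.zeros(2))
        assert model.objective(state, [(0, 1)]) == model.objective(state)

    def test_pure_regularisation_term(self):
        # beta/2 * (||I||_F^2 + ||I||_F^2) = 0.1/2 * 4 = 0.2 with empty data term
        ds = make_dataset(np.zeros((1, 2), dtype=int))
        model = FMSM(ds, sim(np.eye(2)))
        state = FmsmState(np.eye(2), np.eye(2), np.zeros(1), np.zeros(2))
        assert model.objective(state) == pytest.approx(0.2)

    def test_non_finite_state_rejected(self):
        ds = make_dataset([[1]])
        model = FMSM(ds, sim(np.eye(1)))
        state = FmsmState(
            np.array([[np.inf]]), np.zeros((1, 1)), np.zeros(1), np.zeros(1)
        )
        with pytest.raises(DivergenceError):
            model.objective(state)


class TestNegativeSampling:
    def test_rho_zero_gives_empty_set(self):
        ds = make_dataset([[1, 0], [0, 1]])
        model = FMSM(ds, sim(np.eye(2)))
        assert model.sample_negatives(np.random.default_rng(0), rho=0).size == 0

    def test_sample_size_is_rho_times_positives(self, tiny):
        model = FMSM(tiny.dataset, identity_similarity(tiny.dataset.mirnas))
        A = model.sample_negatives(np.random.default_rng(0), rho=3)
        assert len(A) == 3 * tiny.dataset.n_associations

    def test_samples_are_unknown_pairs(self, tiny):
        model = FMSM(tiny.dataset, identity_similarity(tiny.dataset.mirnas))
        A = model.sample_negatives(np.random.default_rng(1))
        pairs = {tuple(p) for p in A.tolist()}
        assert pairs.isdisjoint(tiny.dataset.R)
        assert len(pairs) == len(A)  # without replacement

    def test_identical_seed_identical_sample(self, tiny):
        model = FMSM(tiny.dataset, identity_similarity(tiny.dataset.mirnas))
        a = model.sample_negatives(np.random.default_rng(7))
        b = model.sample_negatives(np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_negative_rho_rejected(self, tiny):
        model = FMSM(tiny.dataset, identity_similarity(tiny.dataset.mirnas))
        with pytest.raises(ValueError):
            model.sample_negatives(np.random.default_rng(0), rho=-1)


class TestTraining:
    def test_zero_learning_rate_leaves_model_unchanged(self, tiny):
        model = FMSM(
            tiny.dataset, identity_similarity(tiny.dataset.mirnas),
            params=FmsmParams(eta=0.0, max_iters=5),
        )
        start = model.initialize()
        results = model.fit(seed=0)
        for a, b in zip(results.state, start):
            assert np.array_equal(a, b)

    def test_objective_decreases_on_synthetic_fixture(self):
        data = synthetic.generate(
            synthetic.SyntheticConfig(nd=20, nm=30, n_tissues=10, density=0.05, seed=3)
        )
        model = FMSM.from_data(data.dataset, data.expression, data.mesh)
        eval_negatives = model.sample_negatives(np.random.default_rng(99))
        before = model.objective(model.initialize(), eval_negatives)
        results = model.fit(seed=0)
        after = model.objective(results.state, eval_negatives)
        assert after < before
        assert results.loss_path[-1] < results.loss_path[0]

    def test_fit_is_deterministic_given_seed(self, tiny):
        model = FMSM(
            tiny.dataset, identity_similarity(tiny.dataset.mirnas),
            params=FmsmParams(max_iters=10),
        )
        r1 = model.fit(seed=4)
        r2 = model.fit(seed=4)
        for a, b in zip(r1.state, r2.state):
            assert np.array_equal(a, b)

    def test_divergent_learning_rate_raises(self, tiny):
        model = FMSM(
            tiny.dataset, identity_similarity(tiny.dataset.mirnas),
            params=FmsmParams(eta=50.0),
        )
        with pytest.raises(DivergenceError, match="smaller learning rate"):
            model.fit(seed=0)


class TestAggregation:
    def _results(self, U, S_d, S_m, b_d, params):
        ds = make_dataset(U)
        model = FMSM(
            ds,
            SimilarityMatrix(ds.mirnas, np.asarray(S_m, float), np.ones(ds.nm, bool)),
            SimilarityMatrix(ds.diseases, np.asarray(S_d, float), np.ones(ds.nd, bool)),
            params,
        )
        nm = ds.nm
        state = FmsmState(
            np.zeros((nm, nm)), np.zeros((nm, nm)),
            np.asarray(b_d, float), np.zeros(nm),
        )
        return FMSMResults(model, state, np.array([]), seed=0)

    def test_zero_weights_reduce_to_raw_score(self):
        res = self._results(
            [[0, 1], [1, 0]], np.eye(2), np.eye(2), [0.3, 0.0],
            FmsmParams(w_d=0.0, w_m=0.0),
        )
        assert np.allclose(res.score_matrix(), res.raw_score_matrix())

    def test_hand_computed_aggregate(self):
        # unknown pair (d1, m2): raw 0.5 via b_d; one disease neighbour with
        # S_d = 0.8, one miRNA neighbour with S_m = 0.4 -> 0.5 + 0.8 + 0.4
        res = self._results(
            [[1, 0], [0, 1]],
            [[1.0, 0.8], [0.8, 1.0]],
            [[1.0, 0.4], [0.4, 1.0]],
            [0.5, 0.0],
            FmsmParams(),
        )
        assert res.score_matrix()[0, 1] == pytest.approx(1.7)

    def test_empty_neighbour_sets_contribute_zero(self):
        # m2 associated with no disease -> disease term 0 for its column;
        # d2 has no associations -> miRNA term 0 for its row
        res = self._results(
            [[1, 0], [0, 0]],
            [[1.0, 0.9], [0.9, 1.0]],
            [[1.0, 0.9], [0.9, 1.0]],
            [0.0, 0.0],
            FmsmParams(),
        )
        scores = res.score_matrix()
        assert scores[0, 1] == pytest.approx(0.9)  # miRNA term only
        assert scores[1, 1] == pytest.approx(0.0)

    def test_raw_matrix_matches_pairwise_prediction(self, tiny):
        model = FMSM(
            tiny.dataset, identity_similarity(tiny.dataset.mirnas),
            params=FmsmParams(max_iters=5),
        )
        res = model.fit(seed=0)
        raw = res.raw_score_matrix()
        for d in range(tiny.dataset.nd):
            for m in range(tiny.dataset.nm):
                assert raw[d, m] == pytest.approx(res.predict_raw(d, m), abs=1e-9)


class TestRankings:
    def test_known_pairs_are_masked(self, tiny):
        model = FMSM.from_data(
            tiny.dataset, tiny.expression, tiny.mesh, FmsmParams(max_iters=5)
        )
        res = model.fit(seed=0)
        ranked = res.rankings()
        for d, disease in enumerate(tiny.dataset.diseases):
            listed = {m for m, _ in ranked[disease]}
            known = {
                tiny.dataset.mirnas[j]
                for j in np.flatnonzero(tiny.dataset.U[d])
            }
            assert listed.isdisjoint(known)

    def test_top_n_limits_output(self, tiny):
        model = FMSM.from_data(
            tiny.dataset, tiny.expression, tiny.mesh, FmsmParams(max_iters=5)
        )
        res = model.fit(seed=0)
        assert all(len(v) <= 3 for v in res.rankings(top_n=3).values())

    def test_summary_mentions_dimensions(self, tiny):
        model = FMSM.from_data(
            tiny.dataset, tiny.expression, tiny.mesh, FmsmParams(max_iters=2)
        )
        text = model.fit(seed=0).summary()
        assert str(tiny.dataset.nd) in text and str(tiny.dataset.nm) in text
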