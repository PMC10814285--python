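import numpy as np
import pytest

from fairgibbs.datasets import InputError, LabeledDataset, balance, generate_well_specified
from fairgibbs.fairlets import (
    FairletAssignment,
    build_cost_matrix,
    decompose,
    solve_optimal_fairlets,
)
from fairgibbs.gibbs_clustering import ClusteringState, LossSpec, map_clustering
from fairgibbs.posterior import (
    GibbsConfig,
    canonical_labels,
    coclustering,
    dahl_least_squares,
    expand_labels,
    log_joint,
    map_estimate,
    misclassification_prob,
    run_mcem,
    run_mcmc,
    summarize,
)


@pytest.fixture(scope="module")
def t2_dataset():
    rng = np.random.default_rng(42)
    pts = rng.normal(size=(9, 2))
    labels = np.array([1, 1, 1, 2, 2, 2, 2, 2, 2])
    return LabeledDataset(pts, labels)


class TestLogJoint:
    def test_zero_temperatures_and_linearity(self, toy_dataset):
        cost = build_cost_matrix(toy_dataset)
        b = solve_optimal_fairlets(cost, 1)
        u = decompose(b, toy_dataset).centers
        state = ClusteringState.from_labels(u, np.array([1, 1, 2]), 2, LossSpec())
        assert log_joint(b, cost, state, 0.0, 0.0) == 0.0
        v1 = log_joint(b, cost, state, 1.0, 1.0)
        v2 = log_joint(b, cost, state, 2.0, 2.0)
        assert v2 == pytest.approx(2 * v1)

    def test_optimum_maximizes_over_enumeration(self, toy_dataset):
        """(B', MAP C) attains the maximal log joint over all (B, C) pairs."""
        import itertools

        from conftest import enumerate_permutation_matrices, enumerate_two_partitions

        cost = build_cost_matrix(toy_dataset)
        loss = LossSpec()
        best = -np.inf
        for bmat in enumerate_permutation_matrices(3):
            b = FairletAssignment(bmat, 1)
            u = decompose(b, toy_dataset).centers
            for part in enumerate_two_partitions(3):
                state = ClusteringState.from_labels(u, part, 2, loss)
                best = max(best, log_joint(b, cost, state, 1.0, 1.0))
        b_opt = solve_optimal_fairlets(cost, 1)
        u_opt = decompose(b_opt, toy_dataset).centers
        map_state = map_clustering(u_opt, 2, loss, rng=np.random.default_rng(0))
        assert log_joint(b_opt, cost, map_state, 1.0, 1.0) == pytest.approx(best)


class TestExpandLabels:
    def test_structural_balance(self, t2_dataset):
        cost = build_cost_matrix(t2_dataset)
        b = solve_optimal_fairlets(cost, 2)
        dec = decompose(b, t2_dataset)
        obs = expand_labels(np.array([1, 1, 2]), dec, t2_dataset.n)
        # each cluster inherits the (1, t) composition => balance exactly 1/t
        assert balance(obs, t2_dataset.labels) == pytest.approx(0.5)
        # observation-level sizes are (t+1) times fairlet-level sizes
        assert (obs == 1).sum() == 3 * 2 and (obs == 2).sum() == 3 * 1

    def test_t1_balance_one(self, toy_dataset):
        cost = build_cost_matrix(toy_dataset)
        dec = decompose(solve_optimal_fairlets(cost, 1), toy_dataset)
        obs = expand_labels(np.array([1, 2, 2]), dec, toy_dataset.n)
        assert balance(obs, toy_dataset.labels) == pytest.approx(1.0)


class TestSummaries:
    def test_coclustering_identical_draws(self):
        draw = np.array([1, 1, 2, 2])
        eta = coclustering(np.array([draw, draw]))
        assoc = (draw[:, None] == draw[None, :]).astype(float)
        np.testing.assert_array_equal(eta, assoc)

    def test_coclustering_matches_naive_oracle(self, rng):
        parts = rng.integers(1, 4, size=(10, 6))
        parts[:, :3] = [1, 2, 3]
        eta = coclustering(parts)
        naive = np.zeros((6, 6))
        for s in parts:
            for i in range(6):
                for j in range(6):
                    naive[i, j] += float(s[i] == s[j])
        np.testing.assert_allclose(eta, naive / 10)
        assert np.allclose(eta, eta.T) and np.allclose(np.diag(eta), 1.0)

    def test_coclustering_empty_rejected(self):
        with pytest.raises(InputError):
            coclustering(np.empty((0, 4), dtype=int))

    def test_dahl_majority_draw_wins(self):
        a = np.array([1, 1, 2, 2])
        b = np.array([1, 2, 1, 2])
        ls = dahl_least_squares(np.array([a, a, b]))
        assert np.array_equal(ls, a)

    def test_dahl_single_draw(self):
        a = np.array([1, 2, 2])
        assert np.array_equal(dahl_least_squares(np.array([a])), a)

    def test_dahl_objective_is_minimal(self, rng):
        parts = rng.integers(1, 3, size=(8, 5))
        parts[:, 0] = 1
        parts[:, 1] = 2
        eta = coclustering(parts)
        ls = dahl_least_squares(parts, eta)
        obj = lambda s: (((s[:, None] == s[None, :]).astype(float) - eta) ** 2).sum()
        assert all(obj(ls) <= obj(s) + 1e-12 for s in parts)

    def test_misclassification_hand_case(self):
        # 4 observations, 2 draws; MAP = draw 1
        draws = np.array([[1, 1, 2, 2], [1, 2, 2, 2]])
        eta = coclustering(draws)
        points = np.array([[0.0], [0.1], [5.0], [5.1]])
        map_part = draws[0]
        mis = misclassification_prob(eta, map_part, points)
        # cluster {0,1}: medioid 0 (ties -> lowest summed discrepancy); 1-eta[1,0]=0.5
        # cluster {2,3}: medioid 2; 1-eta[3,2]=0
        np.testing.assert_allclose(mis, [0.0, 0.5, 0.0, 0.0])

    def test_medioids_have_zero_misclassification(self, rng):
        draws = rng.integers(1, 3, size=(20, 8))
        draws[:, 0] = 1
        draws[:, 1] = 2
        eta = coclustering(draws)
        pts = rng.normal(size=(8, 2))
        map_part = draws[0]
        mis = misclassification_prob(eta, map_part, pts)
        assert (mis >= 0).all() and (mis <= 1).all()
        for c in (1, 2):
            members = np.flatnonzero(map_part == c)
            assert mis[members].min() == pytest.approx(0.0)


class TestCanonical:
    def test_first_occurrence_relabeling(self):
        assert canonical_labels(np.array([3, 3, 1, 2])).tolist() == [1, 1, 2, 3]


class TestChains:
    CFG = dict(n_iterations=120, burn_in=20, thin=2, seed=7)

    def test_mcem_deterministic_and_fair(self):
        ds, _ = generate_well_specified(7)
        cfg = GibbsConfig(mode="mcem", **self.CFG)
        d1, d2 = run_mcem(ds, cfg), run_mcem(ds, cfg)
        assert np.array_equal(d1.partitions, d2.partitions)
        assert d1.n_draws == (120 - 20) // 2
        for s in d1.partitions:
            assert balance(s, ds.labels) == pytest.approx(1.0)

    def test_mcem_cold_chain_matches_map(self):
        ds, _ = generate_well_specified(2)
        cfg = GibbsConfig(mode="mcem", lam_c=1000.0, **self.CFG)
        draws = run_mcem(ds, cfg)
        # zero-temperature degeneracy: every stored draw identical
        assert (draws.partitions == draws.partitions[0]).all()

    def test_mcmc_conservation_invariants(self, t2_dataset):
        cfg = GibbsConfig(mode="mcmc", n_iterations=200, burn_in=50, thin=3, seed=1)
        draws = run_mcmc(t2_dataset, cfg)
        for b in draws.assignments:
            assert (b.sum(axis=1) == 2).all() and (b.sum(axis=0) == 1).all()
        for s in draws.partitions:
            assert len(np.unique(s)) == 2
            assert balance(s, t2_dataset.labels) == pytest.approx(0.5)

    def test_map_estimate_argmax_contract(self, t2_dataset):
        cfg = GibbsConfig(mode="mcmc", n_iterations=100, burn_in=10, seed=3)
        draws = run_mcmc(t2_dataset, cfg)
        m = map_estimate(draws)
        idx = int(np.argmax(draws.log_joint))
        assert np.array_equal(m, draws.partitions[idx])
        assert draws.log_joint[idx] >= draws.log_joint.max() - 1e-12

    def test_cold_joint_map_matches_two_step_estimator(self):
        """At large temperatures the MCMC MAP equals fairlets-then-Lloyd."""
        ds, _ = generate_well_specified(1)
        cfg = GibbsConfig(
            mode="mcmc", lam_f=100.0, lam_c=100.0,
            n_iterations=150, burn_in=50, seed=1,
        )
        draws = run_mcmc(ds, cfg)
        mcmc_map = map_estimate(draws)
        cost = build_cost_matrix(ds)
        dec = decompose(solve_optimal_fairlets(cost, 1), ds)
        two_step = map_clustering(dec.centers, 2, LossSpec(), rng=np.random.default_rng(0))
        expected = expand_labels(canonical_labels(two_step.labels), dec, ds.n)
        assert np.array_equal(mcmc_map, expected)

    def test_summarize_contracts(self):
        ds, _ = generate_well_specified(4)
        cfg = GibbsConfig(mode="mcmc", n_iterations=150, burn_in=50, seed=4)
        draws = run_mcmc(ds, cfg)
        s = summarize(draws)
        assert np.allclose(s.coclustering, s.coclustering.T)
        assert np.allclose(np.diag(s.coclustering), 1.0)
        assert any((p == s.ls_partition).all() for p in draws.partitions)
        assert ((s.misclassification >= 0) & (s.misclassification <= 1)).all()
        assert (s.balance_per_draw == 1.0).all()

    def test_bad_config_rejected(self):
        from fairgibbs.fairlets import ConfigError

        with pytest.raises(ConfigError):
            GibbsConfig(burn_in=50, n_iterations=50)
        with pytest.raises(ConfigError):
            GibbsConfig(mode="vi")
        with pytest.raises(ConfigError):
            GibbsConfig(thin=0)
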