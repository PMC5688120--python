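"""MSM estimation: clustering, counting, trimming, reversible MLE, spectra."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from kinasemsm import msm, synthetic as syn, tica
from kinasemsm.features import FeatureTrajectory


class TestKmeans:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0.0, 0.0], [20.0, 0.0], [0.0, 20.0]])
        blobs = [c + 0.5 * rng.standard_normal((200, 2)) for c in centers]
        traj = FeatureTrajectory(np.concatenate(blobs), 1.0)
        model, (labels,) = msm.kmeans_discretize([traj], 3, seed=1)
        # each blob maps to exactly one cluster
        for k in range(3):
            blob_labels = labels[200 * k: 200 * (k + 1)]
            assert len(np.unique(blob_labels)) == 1
        # inertia equals within-blob sum of squares around blob means
        want = sum(((b - b.mean(axis=0)) ** 2).sum() for b in blobs)
        assert model.inertia == pytest.approx(want, rel=1e-10)

    def test_same_seed_identical_labels(self):
        rng = np.random.default_rng(2)
        traj = FeatureTrajectory(rng.standard_normal((500, 2)), 1.0)
        _, (a,) = msm.kmeans_discretize([traj], 5, seed=3)
        _, (b,) = msm.kmeans_discretize([traj], 5, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_assignment_is_nearest_center(self):
        rng = np.random.default_rng(4)
        traj = FeatureTrajectory(rng.standard_normal((300, 2)), 1.0)
        model, (labels,) = msm.kmeans_discretize([traj], 4, seed=5)
        np.testing.assert_array_equal(model.assign(traj.values), labels)

    def test_too_few_clusters_rejected(self):
        traj = FeatureTrajectory(np.zeros((10, 1)), 1.0)
        with pytest.raises(ValueError):
            msm.kmeans_discretize([traj], 1, seed=0)


class TestCounting:
    def test_alternating_trajectory_lag_one(self):
        c = msm.count_transitions([np.array([0, 1, 0, 1])], 1)
        np.testing.assert_array_equal(c.matrix, [[0, 2], [1, 0]])

    def test_alternating_trajectory_lag_two(self):
        c = msm.count_transitions([np.array([0, 1, 0, 1])], 2)
        np.testing.assert_array_equal(c.matrix, [[1, 0], [0, 1]])

    def test_constant_trajectory_diagonal(self):
        c = msm.count_transitions([np.zeros(10, dtype=int)], 1)
        assert c.matrix[0, 0] == 9

    @given(st.lists(st.integers(0, 3), min_size=5, max_size=40),
           st.integers(min_value=1, max_value=3))
    def test_sliding_counts_match_pair_enumeration(self, traj, lag):
        traj = np.asarray(traj)
        c = msm.count_transitions([traj], lag, n_states=4)
        want = np.zeros((4, 4))
        for t in range(len(traj) - lag):
            want[traj[t], traj[t + lag]] += 1
        np.testing.assert_array_equal(c.matrix, want)

    def test_lag_longer_than_all_trajectories(self):
        with pytest.raises(ValueError, match="lag"):
            msm.count_transitions([np.array([0, 1])], 5)


class TestErgodicTrim:
    def test_larger_block_retained(self):
        c = np.zeros((5, 5))
        c[:3, :3] = 1.0
        c[3:, 3:] = 1.0
        trimmed, active = msm.ergodic_trim(msm.CountMatrix(c, 1))
        np.testing.assert_array_equal(active, [0, 1, 2])
        assert trimmed.n_states == 3

    def test_fully_connected_is_identity(self):
        c = np.ones((4, 4))
        trimmed, active = msm.ergodic_trim(msm.CountMatrix(c, 1))
        np.testing.assert_array_equal(active, np.arange(4))
        np.testing.assert_array_equal(trimmed.matrix, c)

    def test_matches_networkx_scc_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            c = (rng.random((8, 8)) < 0.2).astype(float)
            if not c.any():
                continue
            _, active = msm.ergodic_trim(msm.CountMatrix(c, 1))
            g = nx.from_numpy_array(c, create_using=nx.DiGraph)
            sccs = sorted(nx.strongly_connected_components(g),
                          key=lambda s: (len(s), c[np.ix_(sorted(s), sorted(s))].sum(),
                                         -min(s)))
            want = np.array(sorted(sccs[-1]))
            np.testing.assert_array_equal(active, want)

    def test_one_way_edge_excluded_from_component(self):
        # 0→1 only; each node is its own SCC: the tie-break keeps the one
        # with more counts
        c = np.array([[0.0, 5.0], [0.0, 3.0]])
        _, active = msm.ergodic_trim(msm.CountMatrix(c, 1))
        np.testing.assert_array_equal(active, [1])


class TestReversibleMLE:
    def test_symmetric_counts_equal_row_normalization(self):
        rng = np.random.default_rng(7)
        a = rng.integers(1, 50, size=(5, 5)).astype(float)
        c = a + a.T
        model = msm.mle_reversible(msm.CountMatrix(c, 1))
        want = c / c.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(model.transition_matrix, want, atol=1e-10)

    def test_two_state_closed_form(self):
        c = msm.CountMatrix(np.array([[8.0, 2.0], [2.0, 8.0]]), 1)
        model = msm.mle_reversible(c)
        np.testing.assert_allclose(model.transition_matrix, [[0.8, 0.2], [0.2, 0.8]], atol=1e-10)
        np.testing.assert_allclose(model.stationary, [0.5, 0.5], atol=1e-10)

    def test_detailed_balance_and_likelihood_dominance(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            c = rng.integers(0, 30, size=(6, 6)).astype(float)
            c += np.diag(rng.integers(5, 20, size=6))  # keep connected-ish
            c[c.sum(axis=1) == 0, 0] = 1
            trimmed, active = msm.ergodic_trim(msm.CountMatrix(c, 1))
            model = msm.mle_reversible(trimmed)
            t, pi = model.transition_matrix, model.stationary
            np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-10)
            flux = pi[:, None] * t
            assert np.max(np.abs(flux - flux.T)) < 1e-8
            # likelihood at least that of the symmetrized-counts reversible baseline
            cm = trimmed.matrix
            base = (cm + cm.T) / (cm + cm.T).sum(axis=1, keepdims=True)
            mask = (cm > 0)
            ll_base = np.sum(cm[mask] * np.log(base[mask]))
            assert model.loglik >= ll_base - 1e-8

    def test_disconnected_counts_rejected(self):
        c = np.zeros((3, 3))
        c[0, 0] = 5
        with pytest.raises(ValueError, match="disconnected"):
            msm.mle_reversible(msm.CountMatrix(c, 1))


class TestSpectral:
    def make_model(self, t, lag_ns):
        t = np.asarray(t, dtype=float)
        evals, evecs = np.linalg.eig(t.T)
        pi = np.abs(evecs[:, np.argmax(evals.real)].real)
        pi /= pi.sum()
        return msm.TransitionModel(t, lag_ns, pi, np.sort(evals.real)[::-1],
                                   np.arange(t.shape[0]))

    def test_two_state_implied_timescale(self):
        model = self.make_model([[0.9, 0.1], [0.1, 0.9]], 80.0)
        evals, ts = msm.spectral_decompose(model, 1)
        assert evals[1] == pytest.approx(0.8, abs=1e-12)
        assert ts[0] == pytest.approx(80.0 / np.log(1.25), abs=0.01)  # 358.5 ns

    def test_stationary_matches_boltzmann_on_fixture(self, asp_chain):
        pi = asp_chain.stationary
        np.testing.assert_allclose(pi @ asp_chain.transition_matrix, pi, atol=1e-10)

    def test_timescales_monotone_decreasing(self, asp_chain):
        model = self.make_model(asp_chain.transition_matrix, asp_chain.dt)
        _, ts = msm.spectral_decompose(model, 5)
        assert np.all(np.diff(ts) <= 1e-9)

    def test_estimator_consistency_on_sampled_chain(self, three_state_chain):
        trajs = syn.sample_discrete(three_state_chain, 10_000, 100, seed=9)
        counts = msm.count_transitions(trajs, 1)
        trimmed, active = msm.ergodic_trim(counts)
        model = msm.mle_reversible(trimmed, lag_ns=three_state_chain.dt, active_set=active)
        assert np.max(np.abs(model.transition_matrix - three_state_chain.transition_matrix)) < 0.02
        np.testing.assert_allclose(model.stationary, three_state_chain.stationary, atol=0.01)
        evals, _ = msm.spectral_decompose(model)
        assert np.all(evals[1:] <= 1.0 + 1e-10)


class TestImpliedTimescales:
    def test_flat_for_markovian_data(self, three_state_chain):
        trajs = syn.sample_discrete(three_state_chain, 20_000, 50, seed=10)
        table, suggested = msm.implied_timescale_scan(trajs, [1, 2, 4, 8], 2, dt_ns=1.0)
        t1 = table["t1_ns"].to_numpy()
        assert np.all(np.abs(t1 - t1.mean()) < 0.1 * t1.mean())
        assert suggested == 1

    def test_single_state_data_clean_report(self):
        table, suggested = msm.implied_timescale_scan(
            [np.zeros(100, dtype=int)], [1, 2], 2, dt_ns=1.0)
        assert table["t1_ns"].isna().all()
        assert suggested is None


class TestMacrostates:
    def test_fixture_macrostates_match_majority_generator_labels(self, asp_chain):
        spec = syn.default_emission_spec(asp_chain)
        labels = syn.sample_discrete(asp_chain, 2000, 30, seed=11)
        trajs = syn.emit_features(labels, spec, seed=12, dt=asp_chain.dt)
        from kinasemsm.features import normalize_features
        normed, norm = normalize_features(trajs)
        tm = tica.fit_tica(normed, 80.0, 3, kinetic_mapping=True)
        tics = tica.transform(normed, tm)
        cm, dtrajs = msm.kmeans_discretize(tics, 12, seed=13)
        from kinasemsm.pipeline import macro_reference_points
        refs = macro_reference_points(syn.macro_mean_points(asp_chain, spec), norm, tm)
        macro_map = msm.assign_macrostates(cm, msm.nearest_reference_rules(refs))
        # oracle: majority true macrostate label among frames of each cluster
        all_true = np.concatenate([asp_chain.macro_labels[l] for l in labels])
        all_assigned = np.concatenate(dtrajs)
        for k in range(cm.n_clusters):
            frames = all_assigned == k
            if frames.sum() == 0:
                continue
            vals, counts = np.unique(all_true[frames], return_counts=True)
            assert macro_map.labels[k] == vals[np.argmax(counts)]

    def test_single_rule_matches_everything(self):
        cm = msm.ClusterModel(np.zeros((3, 2)), 3, 0, 0.0)
        mp = msm.assign_macrostates(cm, [("all", lambda c: True)])
        assert set(mp.labels) == {"all"}

    def test_overlapping_rules_rejected(self):
        cm = msm.ClusterModel(np.zeros((2, 2)), 2, 0, 0.0)
        with pytest.raises(ValueError, match="partition"):
            msm.assign_macrostates(cm, [("a", lambda c: True), ("b", lambda c: True)])


class TestPopulationsAndFreeEnergies:
    def test_identity_map_returns_stationary(self, three_state_chain):
        t = three_state_chain.transition_matrix
        pi = three_state_chain.stationary
        model = msm.TransitionModel(t, 1.0, pi, np.ones(3), np.arange(3))
        mp = msm.MacrostateMap(np.array([f"s{i}" for i in range(3)], dtype=object))
        pops = msm.macrostate_populations(model, mp)
        np.testing.assert_allclose([pops[f"s{i}"] for i in range(3)], pi, atol=1e-15)
        assert sum(pops.values()) == pytest.approx(1.0, abs=1e-12)

    def test_free_energy_arithmetic(self):
        g = msm.free_energies({"a": 0.52, "b": 0.01}, temperature=300.0, reference="a")
        assert g["a"] == pytest.approx(0.0, abs=1e-12)
        assert g["b"] == pytest.approx(2.35, abs=0.01)

    def test_scaling_populations_leaves_differences_unchanged(self):
        p = {"a": 0.3, "b": 0.1, "c": 0.6}
        g1 = msm.free_energies(p)
        g2 = msm.free_energies({k: 10 * v for k, v in p.items()})
        for k in p:
            assert g1[k] - g1["a"] == pytest.approx(g2[k] - g2["a"], abs=1e-12)

    def test_zero_population_maps_to_infinity(self):
        g = msm.free_energies({"a": 0.5, "b": 0.0})
        assert np.isinf(g["b"])


@pytest.fixture(scope="module")
def cv_data(asp_chain):
    spec = syn.default_emission_spec(asp_chain, d=20, noise_dims=10)
    labels = syn.sample_discrete(asp_chain, 800, 20, seed=14)
    return syn.emit_features(labels, spec, seed=15, dt=asp_chain.dt)


class TestCrossValidation:
    def test_degenerate_grid_returns_single_combination(self, cv_data):
        grid = {"tica_lag_ns": [80.0], "n_components": [3],
                "kinetic_mapping": [True], "n_clusters": [8]}
        table, best = msm.cross_validate(cv_data, grid, n_folds=3, seed=16,
                                         markov_lag_ns=80.0, n_timescales=3)
        assert len(table) == 1
        assert best["n_clusters"] == 8

    def test_undersplitting_scores_lower(self, cv_data):
        grid = {"tica_lag_ns": [80.0], "n_components": [3],
                "kinetic_mapping": [True], "n_clusters": [2, 12]}
        table, best = msm.cross_validate(cv_data, grid, n_folds=3, seed=17,
                                         markov_lag_ns=80.0, n_timescales=3)
        s2 = table.loc[table.n_clusters == 2, "mean_score"].item()
        s12 = table.loc[table.n_clusters == 12, "mean_score"].item()
        assert s12 >= s2
        assert best["n_clusters"] == 12

    def test_time_shuffled_data_scores_collapse_to_stationary(self, cv_data):
        rng = np.random.default_rng(18)
        shuffled = []
        for t in cv_data:
            perm = rng.permutation(t.values.shape[0])
            shuffled.append(FeatureTrajectory(t.values[perm], t.dt, list(t.names)))
        grid = {"tica_lag_ns": [80.0], "n_components": [3],
                "kinetic_mapping": [False], "n_clusters": [8]}
        table, _ = msm.cross_validate(shuffled, grid, n_folds=3, seed=19,
                                      markov_lag_ns=80.0, n_timescales=3)
        # only the stationary process survives: score ≈ 1 (sum of 4 eigenvalues
        # of which only μ₁ = 1 is real signal)
        assert table["mean_score"].item() == pytest.approx(1.0, abs=0.35)
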