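"""Skeleton estimators: Fisher-z CI test, PC, mutual information, CLR, ARACNE."""

import numpy as np
import pytest

import spgies as sp
from spgies.skeletons import estimate_skeleton


def _obs_sampleset(data):
    return sp.SampleSet(data, sp.InterventionFamily.observational(data.shape[0]))


class TestFisherZ:
    def test_null_calibration(self):
        """Under independence the rejection rate tracks alpha (3-SE band)."""
        rng = np.random.default_rng(0)
        alpha, reps = 0.05, 500
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=(200, 2))
            _, _, indep = sp.fisher_z_ci_test(x, 0, 1, [], alpha)
            rejections += not indep
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) < 3 * se

    def test_perfect_correlation_is_dependent(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(500, 1))
        data = np.column_stack([x, x])
        stat, p, indep = sp.fisher_z_ci_test(data, 0, 1, [], 0.01)
        assert p < 1e-10 and not indep

    def test_chain_conditional_independence(self):
        dag = sp.DirectedGraph.from_edges(3, [(0, 1), (1, 2)])
        sem = sp.GaussianSEM(dag, np.array([[0, .9, 0], [0, 0, .9], [0, 0, 0.0]]),
                             np.ones(3))
        data = sp.sample_observational(sem, 20_000, seed=2).data
        _, _, indep_marg = sp.fisher_z_ci_test(data, 0, 2, [], 0.01)
        _, _, indep_cond = sp.fisher_z_ci_test(data, 0, 2, [1], 0.01)
        assert not indep_marg and indep_cond

    def test_conditioning_set_size_guard(self):
        with pytest.raises(ValueError):
            sp.fisher_z_ci_test(np.zeros((6, 5)), 0, 1, [2, 3, 4], 0.01)


class TestPC:
    def test_collider_is_oriented(self):
        dag = sp.DirectedGraph.from_edges(3, [(0, 2), (1, 2)])
        sem = sp.GaussianSEM(dag, np.array([[0, 0, .8], [0, 0, .8], [0, 0, 0.0]]),
                             np.ones(3))
        samples = sp.sample_observational(sem, 5000, seed=3)
        cp = sp.pc_estimate(samples, alpha=0.01)
        assert cp.directed[0, 2] == 1 and cp.directed[1, 2] == 1
        assert not cp.undirected.any()

    def test_chain_left_undirected(self):
        dag = sp.DirectedGraph.from_edges(3, [(0, 1), (1, 2)])
        sem = sp.GaussianSEM(dag, np.array([[0, .9, 0], [0, 0, .9], [0, 0, 0.0]]),
                             np.ones(3))
        samples = sp.sample_observational(sem, 5000, seed=4)
        cp = sp.pc_estimate(samples, alpha=0.01)
        assert not cp.directed.any()
        assert cp.undirected_edges() == [(0, 1), (1, 2)]

    def test_independent_columns_give_empty_graph(self):
        rng = np.random.default_rng(5)
        samples = _obs_sampleset(rng.normal(size=(2000, 6)))
        cp = sp.pc_estimate(samples, alpha=0.01)
        assert cp.n_edges() <= 1  # alpha-controlled false positives

    def test_recovers_essential_graph_of_fixed_dag(self):
        """High-sample PC equals the true essential graph in >= 95% of seeds."""
        dag = sp.DirectedGraph.from_edges(
            6, [(0, 1), (1, 2), (3, 2), (2, 4), (3, 5)]
        )
        truth = sp.essential_graph(dag)
        hits = 0
        seeds = 50
        for s in range(seeds):
            sem = sp.random_sem(dag, seed=s, weight_range=(0.5, 1.0))
            samples = sp.sample_observational(sem, 10_000, seed=s)
            cp = sp.pc_estimate(samples, alpha=0.01)
            hits += (np.array_equal(cp.directed, truth.directed)
                     and np.array_equal(cp.undirected, truth.undirected))
        assert hits >= 0.95 * seeds

    def test_uses_only_observational_rows(self, ws10_benchmark):
        _, _, samples = ws10_benchmark
        full = sp.pc_estimate(samples, alpha=0.01)
        obs_only = sp.pc_estimate(samples.observational(), alpha=0.01)
        assert np.array_equal(full.directed, obs_only.directed)
        assert np.array_equal(full.undirected, obs_only.undirected)


class TestMutualInformation:
    def test_independent_columns_vanish(self):
        rng = np.random.default_rng(6)
        samples = _obs_sampleset(rng.normal(size=(10_000, 4)))
        mi = sp.mutual_information_matrix(samples, "gaussian")
        assert np.all(mi < 0.02)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(7)
        samples = _obs_sampleset(rng.normal(size=(200, 5)))
        for est in ("gaussian", "histogram"):
            mi = sp.mutual_information_matrix(samples, est)
            assert np.array_equal(mi, mi.T)
            assert np.all(np.diag(mi) == 0)

    def test_perfect_pair_is_maximal_under_histogram(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(2000, 1))
        data = np.column_stack([x, x, rng.normal(size=(2000, 2))])
        mi = sp.mutual_information_matrix(_obs_sampleset(data), "histogram")
        assert mi[0, 1] == mi.max()

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50_000)
        y = 0.6 * x + 0.8 * rng.normal(size=50_000)
        mi = sp.mutual_information_matrix(_obs_sampleset(np.column_stack([x, y])))
        rho2 = 0.36 / (0.36 + 0.64)
        assert abs(mi[0, 1] - (-0.5 * np.log(1 - rho2))) < 0.01

    def test_zero_variance_column_warns(self):
        data = np.column_stack([np.ones(100), np.random.default_rng(0).normal(size=100)])
        with pytest.warns(UserWarning):
            mi = sp.mutual_information_matrix(_obs_sampleset(data))
        assert mi[0, 1] == 0


class TestCLR:
    def test_constant_matrix_gives_zero_scores(self):
        # all off-diagonal MI equal: every row background has zero spread
        scores = sp.clr_scores(np.full((4, 4), 0.2) - 0.2 * np.eye(4))
        assert np.allclose(scores, 0.0)

    def test_strong_pair_attains_maximum(self):
        mi = np.array([
            [0.0, 2.0, 0.1, 0.2],
            [2.0, 0.0, 0.2, 0.1],
            [0.1, 0.2, 0.0, 0.15],
            [0.2, 0.1, 0.15, 0.0],
        ])
        scores = sp.clr_scores(mi)
        assert scores[0, 1] == scores.max() > 0
        assert np.array_equal(scores, scores.T)


class TestThresholding:
    def test_full_fraction_gives_complete_graph(self):
        rng = np.random.default_rng(10)
        s = rng.random((6, 6))
        s = (s + s.T) / 2
        g = sp.threshold_top_fraction(s, 1.0)
        assert g.n_edges() == 15

    def test_top_ten_percent_count(self):
        rng = np.random.default_rng(11)
        s = rng.random((10, 10))
        s = (s + s.T) / 2
        assert sp.threshold_top_fraction(s, 0.10).n_edges() == 5  # ceil(0.1 * 45)

    def test_tie_break_by_index_order(self):
        g = sp.threshold_top_fraction(np.zeros((4, 4)), 0.5)  # ceil(0.5*6)=3
        assert g.undirected_edges() == [(0, 1), (0, 2), (0, 3)]

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            sp.threshold_top_fraction(np.zeros((3, 3)), 0.0)


class TestAracne:
    def test_dpi_removes_weakest_triangle_edge(self):
        mi = np.array([
            [0.0, 0.9, 0.2],
            [0.9, 0.0, 0.8],
            [0.2, 0.8, 0.0],
        ])
        g = sp.aracne_prune(mi, mi_threshold=0.1)
        assert g.undirected_edges() == [(0, 1), (1, 2)]

    def test_no_triangles_nothing_removed(self):
        mi = np.zeros((4, 4))
        mi[0, 1] = mi[1, 0] = 0.5
        mi[2, 3] = mi[3, 2] = 0.4
        g = sp.aracne_prune(mi, mi_threshold=0.1)
        assert g.n_edges() == 2

    def test_threshold_above_max_empties_graph(self):
        rng = np.random.default_rng(12)
        mi = rng.random((5, 5))
        mi = (mi + mi.T) / 2
        assert sp.aracne_prune(mi, mi_threshold=2.0).n_edges() == 0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        mi = rng.random((6, 6))
        mi = (mi + mi.T) / 2
        np.fill_diagonal(mi, 0)
        perm = rng.permutation(6)
        g = sp.aracne_prune(mi, 0.4)
        gp = sp.aracne_prune(mi[np.ix_(perm, perm)], 0.4)
        adj = g.skeleton_adjacency()
        assert np.array_equal(adj[np.ix_(perm, perm)], gp.skeleton_adjacency())


class TestNullThreshold:
    def test_monotone_in_p_value(self):
        rng = np.random.default_rng(14)
        samples = _obs_sampleset(rng.normal(size=(200, 8)))
        t_strict = sp.mi_null_threshold(samples, 1e-8, 500, seed=0)
        t_loose = sp.mi_null_threshold(samples, 1e-2, 500, seed=0)
        assert t_strict > t_loose

    def test_empirical_self_consistency(self):
        rng = np.random.default_rng(15)
        samples = _obs_sampleset(rng.normal(size=(300, 10)))
        cutoff = sp.mi_null_threshold(samples, 0.05, 1000, seed=1)
        # fresh null draws: about 5% should exceed the cutoff
        data = samples.data
        exceed = 0
        reps = 1000
        rng2 = np.random.default_rng(2)
        for _ in range(reps):
            i, j = rng2.choice(10, 2, replace=False)
            y = data[rng2.permutation(300), j]
            r = np.clip(np.corrcoef(data[:, i], y)[0, 1], -1 + 1e-12, 1 - 1e-12)
            exceed += (-0.5 * np.log(1 - r**2)) > cutoff
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(exceed / reps - 0.05) < 4 * se

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(16)
        samples = _obs_sampleset(rng.normal(size=(100, 5)))
        assert sp.mi_null_threshold(samples, 1e-4, 300, seed=7) == \
               sp.mi_null_threshold(samples, 1e-4, 300, seed=7)


class TestDeviationMatrix:
    def test_nondescendant_scores_small_descendant_large(self):
        dag = sp.DirectedGraph.from_edges(3, [(0, 1), (1, 2)])
        sem = sp.GaussianSEM(dag, np.array([[0, .9, 0], [0, 0, .9], [0, 0, 0.0]]),
                             np.ones(3))
        samples = sp.sample_observational(sem, 50_000, seed=17)
        # append exact-conditional-mean knockout responses for determinism
        for node in range(3):
            samples = samples.concat(
                sp.sample_intervention(sem, node, 0.0, 1, seed=node))
        scores = sp.deviation_matrix(samples)
        assert np.all(np.diag(scores) == 0)

    def test_scale_invariance(self, ws10_benchmark):
        _, _, samples = ws10_benchmark
        scores = sp.deviation_matrix(samples)
        scaled = sp.SampleSet(samples.data * 10.0, samples.family,
                              samples.node_labels)
        assert np.allclose(sp.deviation_matrix(scaled), scores)

    def test_missing_knockout_raises(self, ws10_benchmark):
        _, _, samples = ws10_benchmark
        obs = samples.observational()
        with pytest.raises(ValueError):
            sp.deviation_matrix(obs)


def test_estimate_skeleton_dispatch(ws10_benchmark):
    _, _, samples = ws10_benchmark
    assert estimate_skeleton(samples, "none") is None
    for method in ("pc", "clr", "aracne"):
        g = estimate_skeleton(samples, method, {"n_permutations": 200})
        assert isinstance(g, sp.PartiallyDirectedGraph)
    with pytest.raises(ValueError):
        estimate_skeleton(samples, "bogus")
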