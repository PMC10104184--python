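"""GIES search, interventional BIC scoring, and the skeleton-primed variant."""

import numpy as np
import pytest

import spgies as sp
from spgies.gies import GIES, SPGIES, InterventionalScoreCache

from conftest import all_dags


def _two_node_dataset(w=0.9, n_obs=100, n_int=1, seed=0):
    dag = sp.DirectedGraph.from_edges(2, [(0, 1)])
    sem = sp.GaussianSEM(dag, np.array([[0.0, w], [0.0, 0.0]]), np.ones(2))
    s = sp.sample_observational(sem, n_obs, seed=seed)
    s = s.concat(sp.sample_intervention(sem, 0, 0.0, n_int, seed=seed))
    s = s.concat(sp.sample_intervention(sem, 1, 0.0, n_int, seed=seed + 10_000))
    return dag, sem, s


class TestLocalScore:
    def test_degenerate_designs_get_sentinel(self):
        data = np.zeros((10, 2))
        data[:, 1] = np.random.default_rng(0).normal(size=10)
        s = sp.SampleSet(data, sp.InterventionFamily.observational(10))
        assert sp.local_score(0, [], s) == float("-inf")  # zero variance
        # duplicated parent columns: rank-deficient design
        x = np.random.default_rng(1).normal(size=(50, 1))
        data = np.column_stack([x, x, x @ np.array([[2.0]])])
        s = sp.SampleSet(data, sp.InterventionFamily.observational(50))
        assert sp.local_score(2, [0, 1], s) == float("-inf")

    def test_true_parent_helps_spurious_parent_hurts(self):
        dag = sp.DirectedGraph.from_edges(3, [(0, 1)])
        sem = sp.GaussianSEM(
            dag, np.array([[0, .8, 0], [0, 0, 0], [0, 0, 0.0]]), np.ones(3))
        s = sp.sample_observational(sem, 10_000, seed=2)
        assert sp.local_score(1, [0], s) > sp.local_score(1, [], s)
        assert sp.local_score(1, [0, 2], s) < sp.local_score(1, [0], s)

    def test_usable_rows_exclude_own_interventions(self):
        _, _, s = _two_node_dataset(n_int=5)
        cache = InterventionalScoreCache(s)
        assert len(cache.usable_rows(0)) == 105
        assert len(cache.usable_rows(1)) == 105

    def test_total_score_is_sum_of_local_scores(self, ws10_benchmark):
        dag, _, samples = ws10_benchmark
        cache = InterventionalScoreCache(samples)
        total = cache.total_score(dag.adjacency)
        by_hand = sum(cache.local_score(j, dag.parents(j)) for j in range(10))
        assert total == pytest.approx(by_hand)


class TestGreedySearch:
    def test_score_trace_strictly_increases(self, ws10_benchmark):
        _, _, samples = ws10_benchmark
        res = sp.fit_gies(samples)
        trace = np.asarray(res.score_trace)
        assert np.all(np.diff(trace) > 0)
        assert res.score == pytest.approx(trace[-1])

    def test_final_score_matches_recomputation(self, ws10_benchmark):
        """Decomposability: accumulated move gains equal a from-scratch total."""
        _, _, samples = ws10_benchmark
        res = sp.fit_gies(samples)
        fresh = InterventionalScoreCache(samples).total_score(res.member_dag.adjacency)
        assert res.score == pytest.approx(fresh)

    def test_empty_allowed_set_gives_empty_graph(self, ws10_benchmark):
        _, _, samples = ws10_benchmark
        res = sp.fit_gies(samples, allowed=sp.PartiallyDirectedGraph.empty(10))
        assert res.graph.n_edges() == 0

    def test_restriction_is_respected(self, ws10_benchmark):
        dag, _, samples = ws10_benchmark
        allowed = sp.skeleton_of(dag)
        res = sp.fit_gies(samples, allowed=allowed)
        est = res.member_dag.adjacency
        assert np.all(((est + est.T) > 0) <= allowed.skeleton_adjacency().astype(bool))

    def test_member_dag_is_acyclic_and_consistent_with_graph(self, ws10_benchmark):
        _, _, samples = ws10_benchmark
        res = sp.fit_gies(samples)
        assert sp.is_acyclic(res.member_dag)
        ie = sp.i_essential_graph(res.member_dag, samples.family)
        assert np.array_equal(ie.directed, res.graph.directed)
        assert np.array_equal(ie.undirected, res.graph.undirected)

    def test_observational_chain_left_undirected(self):
        dag = sp.DirectedGraph.from_edges(3, [(0, 1), (1, 2)])
        sem = sp.GaussianSEM(
            dag, np.array([[0, .9, 0], [0, 0, .9], [0, 0, 0.0]]), np.ones(3))
        samples = sp.sample_observational(sem, 5000, seed=3)
        res = sp.fit_gies(samples)
        assert not res.graph.directed.any()
        assert res.graph.undirected_edges() == [(0, 1), (1, 2)]

    def test_two_node_fit_agrees_with_two_model_score_oracle(self):
        """The fitted direction is the argmax of the two candidate models."""
        for seed in range(20):
            _, _, s = _two_node_dataset(w=0.9, seed=seed)
            cache = InterventionalScoreCache(s)
            fwd = cache.local_score(0, []) + cache.local_score(1, [0])
            rev = cache.local_score(1, []) + cache.local_score(0, [1])
            res = sp.fit_gies(s)
            est = res.member_dag.adjacency
            if est.sum() == 1:  # an edge was kept
                assert bool(est[0, 1]) == (fwd > rev)

    def test_score_equivalence_within_interventional_mec(self):
        """I-equivalent DAGs receive equal interventional BIC totals."""
        rng = np.random.default_rng(4)
        dags4 = all_dags(4)
        picks = rng.choice(len(dags4), size=12, replace=False)
        fam = sp.InterventionFamily([frozenset({0})])
        for idx in picks:
            g = dags4[idx]
            sem = sp.random_sem(g, seed=int(idx))
            s = sp.sample_observational(sem, 300, seed=int(idx))
            s = s.concat(sp.sample_intervention(sem, 0, 0.0, 50, seed=int(idx)))
            cache = InterventionalScoreCache(s)
            scores = [cache.total_score(m.adjacency)
                      for m in sp.enumerate_mec(g, fam)]
            assert np.allclose(scores, scores[0], rtol=1e-9, atol=1e-6)

    def test_consistency_on_five_node_sems(self):
        """Large-sample fits recover the exact DAG in >= 90% of seeds."""
        hits, seeds = 0, 20
        for s in range(seeds):
            u = sp.random_topology("erdos_renyi", 5, {"p": 0.5}, seed=s)
            dag = sp.orient_random(u, seed=s)
            sem = sp.random_sem(dag, seed=s, weight_range=(0.5, 1.0))
            data = sp.sample_observational(sem, 10_000, seed=s)
            for node in range(5):
                data = data.concat(
                    sp.sample_intervention(sem, node, 0.0, 100, seed=1000 * s + node))
            res = sp.fit_gies(data)
            hits += np.array_equal(res.member_dag.adjacency, dag.adjacency)
        assert hits >= 0.9 * seeds


class TestSPGIES:
    def test_none_skeleton_equals_unrestricted(self, ws10_benchmark):
        _, _, samples = ws10_benchmark
        a = sp.sp_gies(samples, "none")
        b = sp.fit_gies(samples)
        assert np.array_equal(a.member_dag.adjacency, b.member_dag.adjacency)
        assert a.score == pytest.approx(b.score)

    def test_estimate_stays_inside_oracle_skeleton(self, ws10_benchmark):
        dag, _, samples = ws10_benchmark
        model = GIES(samples, allowed=sp.skeleton_of(dag))
        res = model.fit()
        est = res.member_dag.adjacency
        true_sk = sp.skeleton_of(dag).skeleton_adjacency().astype(bool)
        assert np.all(((est + est.T) > 0) <= true_sk)

    def test_records_both_stages_provenance(self, ws10_benchmark):
        _, _, samples = ws10_benchmark
        res = sp.sp_gies(samples, "pc", {"alpha": 0.05})
        assert res.method == "sp-gies"
        assert res.params["skeleton_method"] == "pc"
        assert res.params["skeleton_params"]["alpha"] == 0.05

    def test_unknown_skeleton_method_raises(self, ws10_benchmark):
        _, _, samples = ws10_benchmark
        with pytest.raises(ValueError):
            sp.sp_gies(samples, "mystery")


class TestResultsObject:
    def test_null_result_baseline(self):
        res = sp.null_result(10)
        assert res.graph.n_edges() == 0 and res.member_dag.n_edges() == 0
        truth = sp.DirectedGraph.from_edges(10, [(0, 1), (2, 3), (4, 5)])
        assert sp.shd(truth, res.graph) == 3

    def test_summary_mentions_method_and_edges(self, ws10_benchmark):
        _, _, samples = ws10_benchmark
        res = sp.sp_gies(samples, "pc")
        text = res.summary()
        assert "sp-gies" in text and "Edges" in text

    def test_from_dataframe_round_trip(self, ws10_benchmark):
        from spgies.io import sampleset_to_dataframe

        _, _, samples = ws10_benchmark
        frame = sampleset_to_dataframe(samples)
        model = GIES.from_dataframe(frame)
        direct = GIES(samples)
        assert np.array_equal(model.samples.data, direct.samples.data)
        assert model.samples.family.targets == direct.samples.family.targets

    def test_invalid_phase_rejected(self, ws10_benchmark):
        _, _, samples = ws10_benchmark
        with pytest.raises(ValueError):
            GIES(samples, phases=("forward", "sideways"))
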