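import itertools
import math

import numpy as np
import pytest

from psnet import (
    QueryContext,
    SimilarityNetwork,
    ValidationError,
    build_target_comembership,
    combine_networks,
    propagate_labels,
    solve_network_weights,
)


def _net(name, edges):
    net = SimilarityNetwork(name)
    for a, b, w in edges:
        net.add_edge(a, b, w)
    return net


def _aligned_fixture(scale=1.0):
    """4 patients, 2 query (q1,q2) + 2 background; one network whose edges
    follow the comembership target sign pattern."""
    edges = [("q1", "q2", 1.0 * scale),
             ("q1", "b1", 0.05 * scale), ("q2", "b2", 0.05 * scale)]
    return QueryContext(["q1", "q2"], ["b1", "b2"],
                        {"good": _net("good", edges)})


class TestComembershipTarget:
    def test_two_query_one_background(self):
        t = build_target_comembership(["q1", "q2"], ["b1"])
        assert t[("q1", "q2")] == 1.0
        assert sum(1 for v in t.values() if v == -1.0) == 2
        assert len(t) == 3

    def test_counts_match_combinatorics(self):
        for q, b in [(3, 2), (5, 4), (2, 7)]:
            qs = [f"q{i}" for i in range(q)]
            bs = [f"b{i}" for i in range(b)]
            t = build_target_comembership(qs, bs)
            assert sum(1 for v in t.values() if v == 1.0) == math.comb(q, 2)
            assert sum(1 for v in t.values() if v == -1.0) == q * b
            # background-background pairs excluded
            assert len(t) == math.comb(q, 2) + q * b

    def test_empty_background_raises(self):
        with pytest.raises(ValidationError):
            build_target_comembership(["q1", "q2"], [])

    def test_overlap_raises(self):
        with pytest.raises(ValidationError):
            build_target_comembership(["a", "b"], ["b", "c"])


class TestWeightSolving:
    def test_aligned_network_gets_positive_weight(self):
        fit = solve_network_weights(_aligned_fixture())
        assert fit.weights["good"] > 0

    def test_anti_aligned_network_clipped_to_zero(self):
        # strong edges across query/background, none within the query
        edges = [("q1", "b1", 1.0), ("q1", "b2", 1.0),
                 ("q2", "b1", 1.0), ("q2", "b2", 1.0)]
        ctx = QueryContext(["q1", "q2"], ["b1", "b2"],
                           {"bad": _net("bad", edges)})
        fit = solve_network_weights(ctx)
        assert fit.weights["bad"] == 0.0

    def test_identical_candidates_share_weight(self):
        ctx = _aligned_fixture()
        twin = _net("good2", [(a, b, w) for (a, b), w in
                              ctx.candidate_networks["good"].edges.items()])
        ctx2 = QueryContext(ctx.query_ids, ctx.background_ids,
                            {"good": ctx.candidate_networks["good"],
                             "good2": twin})
        fit = solve_network_weights(ctx2)
        assert fit.weights["good"] == pytest.approx(fit.weights["good2"])

    def test_scaling_networks_rescales_weights_inversely(self):
        w1 = solve_network_weights(_aligned_fixture(1.0)).weights["good"]
        w3 = solve_network_weights(_aligned_fixture(3.0)).weights["good"]
        assert w3 == pytest.approx(w1 / 3.0, rel=1e-10)

    def test_untouched_candidates_raise(self):
        lonely = _net("far", [("x1", "x2", 1.0)])
        ctx = QueryContext(["q1", "q2"], ["b1"], {"far": lonely})
        with pytest.raises(ValidationError, match="uninformative"):
            solve_network_weights(ctx)

    def test_closed_form_single_network_ridge(self):
        # one candidate: w = x'y / (x'x + ridge * x'x) for mean-diag scaling
        ctx = _aligned_fixture()
        t = build_target_comembership(ctx.query_ids, ctx.background_ids)
        net = ctx.candidate_networks["good"]
        x = np.array([net.weight(a, b) for (a, b) in t])
        y = np.array(list(t.values()))
        ridge = 1.0
        expected = float(x @ y) / (x @ x + ridge * (x @ x))
        fit = solve_network_weights(ctx, ridge=ridge)
        assert fit.weights["good"] == pytest.approx(max(expected, 0.0), rel=1e-10)


class TestCombine:
    def test_single_network_weight_one_is_identity(self):
        net = _net("a", [("x", "y", 0.4), ("y", "z", 0.2)])
        out = combine_networks({"a": 1.0}, {"a": net})
        assert out.edges == pytest.approx(net.edges)

    def test_convex_mix_of_identical_networks(self):
        net = _net("a", [("x", "y", 0.4)])
        twin = _net("b", [("x", "y", 0.4)])
        out = combine_networks({"a": 0.5, "b": 0.5}, {"a": net, "b": twin})
        assert out.weight("x", "y") == pytest.approx(0.4)

    def test_random_case_matches_brute_force(self, rng):
        ids = list("abcde")
        nets, weights = {}, {}
        for k in range(3):
            net = SimilarityNetwork(f"n{k}")
            for x, y in itertools.combinations(ids, 2):
                if rng.random() < 0.6:
                    net.add_edge(x, y, float(rng.random()))
            nets[f"n{k}"] = net
            weights[f"n{k}"] = float(rng.random())
        out = combine_networks(weights, nets)
        for x, y in itertools.combinations(ids, 2):
            expected = sum(weights[k] * nets[k].weight(x, y) for k in nets)
            assert out.weight(x, y) == pytest.approx(expected, abs=1e-12)

    def test_missing_weight_raises(self):
        net = _net("a", [("x", "y", 0.4)])
        with pytest.raises(ValidationError):
            combine_networks({}, {"a": net})


class TestPropagation:
    def test_edgeless_graph_returns_prior(self):
        net = SimilarityNetwork("empty", nodes={"a", "b", "c"})
        prior = {"a": 1.0, "b": 0.0, "c": 0.3}
        out = propagate_labels(net, prior)
        for k, v in prior.items():
            assert out.scores[k] == pytest.approx(v, abs=1e-10)

    def test_strong_edge_smooths_to_consensus(self):
        net = _net("two", [("a", "b", 1e8)])
        out = propagate_labels(net, {"a": 1.0, "b": 0.0})
        assert abs(out.scores["a"] - out.scores["b"]) < 1e-6

    def test_matches_dense_direct_solve(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 12))
            ids = [f"p{i}" for i in range(n)]
            net = SimilarityNetwork("g", nodes=set(ids))
            W = np.zeros((n, n))
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.5:
                    w = float(rng.random())
                    net.add_edge(ids[i], ids[j], w)
                    W[i, j] = W[j, i] = w
            prior = {ids[i]: float(rng.random() < 0.3) for i in range(n)}
            lam = float(rng.uniform(0.2, 3.0))
            L = np.diag(W.sum(axis=1)) - W
            f_dense = np.linalg.solve(np.eye(n) + lam * L,
                                      np.array([prior[i] for i in ids]))
            out = propagate_labels(net, prior, lam=lam)
            got = np.array([out.scores[i] for i in ids])
            assert np.allclose(got, f_dense, atol=1e-8)

    def test_maximum_principle(self, rng):
        ids = [f"p{i}" for i in range(8)]
        net = SimilarityNetwork("g", nodes=set(ids))
        for i, j in itertools.combinations(range(8), 2):
            if rng.random() < 0.6:
                net.add_edge(ids[i], ids[j], float(rng.random()))
        prior = {i: float(rng.random() < 0.5) for i in ids}
        out = propagate_labels(net, prior)
        lo, hi = min(prior.values()), max(prior.values())
        assert all(lo - 1e-8 <= v <= hi + 1e-8 for v in out.scores.values())

    def test_residual_to_prior_grows_with_lambda(self):
        net = _net("g", [("a", "b", 0.7), ("b", "c", 0.4), ("a", "d", 0.9)])
        prior = {"a": 1.0, "b": 0.0, "c": 0.0, "d": 0.0}
        prev = -1.0
        for lam in (0.1, 0.5, 1.0, 2.0, 4.0, 8.0):
            out = propagate_labels(net, prior, lam=lam)
            dist = sum((out.scores[k] - prior[k]) ** 2 for k in prior)
            assert dist >= prev - 1e-12
            prev = dist

    def test_prior_must_cover_nodes(self):
        net = _net("g", [("a", "b", 0.5)])
        with pytest.raises(ValidationError):
            propagate_labels(net, {"a": 1.0})
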