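import itertools
import math

import numpy as np
import pandas as pd
import pytest

from psnet import (
    ValidationError,
    binary_pathway_network,
    build_feature_networks,
    continuous_variable_network,
    pearson_profile_network,
    sparsify_network,
)
from psnet.similarity import SparsifyParams, read_edge_list, write_edge_list


def _pairwise_complete_pearson(x, y):
    """Brute-force oracle: Pearson r over indices observed in both."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return np.nan
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return np.nan
    return float(np.corrcoef(xs, ys)[0, 1])


class TestPearsonNetwork:
    def test_identical_profiles_weight_one(self):
        mat = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4, 5],
                            "c": [5, 4, 3, 2, 1.0]},
                           index=[f"g{k}" for k in range(5)])
        net = pearson_profile_network(mat, list(mat.index), "f")
        assert net.weight("a", "b") == pytest.approx(1.0)

    def test_anticorrelated_pair_has_no_edge(self):
        mat = pd.DataFrame({"a": [1, 2, 3.0], "b": [3, 2, 1.0]},
                           index=["g0", "g1", "g2"])
        net = pearson_profile_network(mat, list(mat.index), "f")
        assert ("a", "b") not in net.edges

    def test_missing_data_matches_pairwise_complete_oracle(self):
        mat = pd.DataFrame(
            {"a": [1.0, 2.0, 4.0, 3.0], "b": [2.0, np.nan, 3.0, 5.0],
             "c": [0.5, 1.0, 2.0, 0.0]},
            index=["g0", "g1", "g2", "g3"],
        )
        net = pearson_profile_network(mat, list(mat.index), "f")
        for x, y in itertools.combinations(mat.columns, 2):
            r = _pairwise_complete_pearson(mat[x].to_numpy(), mat[y].to_numpy())
            expected = max(r, 0.0) if np.isfinite(r) else 0.0
            assert net.weight(x, y) == pytest.approx(expected, abs=1e-12)

    def test_complete_data_matches_corrcoef(self, rng):
        mat = pd.DataFrame(rng.normal(size=(6, 5)),
                           index=[f"g{k}" for k in range(6)],
                           columns=list("abcde"))
        net = pearson_profile_network(mat, list(mat.index), "f")
        R = np.corrcoef(mat.to_numpy().T)
        for i, x in enumerate(mat.columns):
            for j in range(i + 1, 5):
                assert net.weight(x, mat.columns[j]) == pytest.approx(
                    max(R[i, j], 0.0), abs=1e-12
                )

    def test_small_group_raises_with_feature_name(self):
        mat = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["g0"])
        with pytest.raises(ValidationError, match="myfeat"):
            pearson_profile_network(mat, ["g0", "absent"], "myfeat")

    def test_patient_order_invariance(self, rng):
        mat = pd.DataFrame(rng.normal(size=(5, 6)),
                           index=[f"g{k}" for k in range(5)],
                           columns=list("abcdef"))
        net1 = pearson_profile_network(mat, list(mat.index), "f")
        net2 = pearson_profile_network(mat[list("fedcba")], list(mat.index), "f")
        assert net1.edges == pytest.approx(net2.edges)


class TestContinuousNetwork:
    def test_normdiff_worked_values(self):
        net = continuous_variable_network({"a": 0.0, "b": 5.0, "c": 10.0},
                                          "normdiff", "age")
        assert net.weight("a", "b") == pytest.approx(0.5)
        assert net.weight("a", "c") == pytest.approx(0.0)
        assert ("a", "c") not in net.edges  # zero weight -> no edge

    def test_equal_values_weight_one(self):
        net = continuous_variable_network({"a": 2.0, "b": 2.0, "c": 7.0},
                                          "normdiff", "age")
        assert net.weight("a", "b") == pytest.approx(1.0)

    def test_degenerate_range_raises(self):
        with pytest.raises(ValidationError):
            continuous_variable_network({"a": 1.0, "b": 1.0}, "normdiff", "x")

    def test_missing_values_omitted(self):
        net = continuous_variable_network(
            {"a": 0.0, "b": np.nan, "c": 4.0}, "normdiff", "x"
        )
        assert "b" not in net.nodes


class TestBinaryNetwork:
    def test_six_carriers_make_a_15_edge_clique(self):
        events = {f"P{i}": {"TP53"} for i in range(6)}
        events.update({f"Q{i}": {"OTHER"} for i in range(4)})
        net = binary_pathway_network(events, {"TP53", "BRCA1"}, "pw")
        assert net is not None
        assert net.n_edges == math.comb(6, 2) == 15
        assert all(w == 1.0 for w in net.edges.values())

    def test_five_carriers_below_default_floor(self):
        events = {f"P{i}": {"TP53"} for i in range(5)}
        assert binary_pathway_network(events, {"TP53"}, "pw") is None

    def test_no_carriers(self):
        assert binary_pathway_network({"P1": {"X"}}, {"Y"}, "pw") is None

    def test_floor_is_tunable(self):
        events = {f"P{i}": {"TP53"} for i in range(3)}
        net = binary_pathway_network(events, {"TP53"}, "pw", min_carriers=3)
        assert net is not None and net.n_edges == 3


class TestSparsify:
    def _complete4(self, weights):
        from psnet import SimilarityNetwork

        net = SimilarityNetwork("f")
        pairs = list(itertools.combinations("abcd", 2))
        for (x, y), w in zip(pairs, weights):
            net.add_edge(x, y, w)
        return net

    def test_identity_when_permissive(self):
        net = self._complete4([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        out = sparsify_network(net, SparsifyParams(min_weight=0.0, max_degree=3))
        assert out.edges == net.edges

    def test_max_degree_one_over_all_orderings(self):
        # each node keeps its strongest edge; union has between 2 and 4 edges
        for perm in itertools.permutations([0.1, 0.2, 0.3, 0.4, 0.5, 0.6]):
            net = self._complete4(perm)
            out = sparsify_network(net, SparsifyParams(0.0, 1))
            assert 2 <= out.n_edges <= 4
            for node in "abcd":
                best = max(w for e, w in net.edges.items() if node in e)
                kept = [w for e, w in out.edges.items() if node in e]
                assert best in kept

    def test_threshold_empties_network(self):
        net = self._complete4([0.1] * 6)
        out = sparsify_network(net, SparsifyParams(min_weight=0.5, max_degree=5))
        assert out.n_edges == 0 and out.nodes == net.nodes

    def test_idempotent(self):
        net = self._complete4([0.15, 0.25, 0.35, 0.45, 0.55, 0.65])
        p = SparsifyParams(min_weight=0.3, max_degree=2)
        once = sparsify_network(net, p)
        twice = sparsify_network(once, p)
        assert once.edges == twice.edges


class TestBuildFeatureNetworks:
    def test_composition_matches_per_metric_calls(self, tiny_two_layer):
        ds, rules, metrics = tiny_two_layer
        nets = build_feature_networks(ds, rules, metrics)
        direct = pearson_profile_network(
            ds.assays["expression"], rules["expression"]["expr_path"], "expr_path"
        )
        assert nets["expr_path"].edges == pytest.approx(direct.edges)
        row = ds.assays["clinical"].loc["age"]
        direct_clin = continuous_variable_network(
            {c: row[c] for c in ds.assays["clinical"].columns}, "normdiff", "age"
        )
        assert nets["age"].edges == pytest.approx(direct_clin.edges)

    def test_restrict_to_excludes_other_patients(self, tiny_two_layer):
        ds, rules, metrics = tiny_two_layer
        train = ds.ids[:6]
        nets = build_feature_networks(ds, rules, metrics, restrict_to=train)
        for net in nets.values():
            assert net.nodes <= set(train)

    def test_builtin_weights_are_bounded(self, tiny_two_layer):
        ds, rules, metrics = tiny_two_layer
        nets = build_feature_networks(ds, rules, metrics)
        for net in nets.values():
            assert all(0.0 <= w <= 1.0 for w in net.edges.values())

    def test_missing_metric_raises(self, tiny_two_layer):
        ds, rules, _ = tiny_two_layer
        with pytest.raises(ValidationError):
            build_feature_networks(ds, rules, {"expression": "pearson"})


def test_edge_list_round_trip(tmp_path, tiny_two_layer):
    ds, rules, metrics = tiny_two_layer
    net = build_feature_networks(ds, rules, metrics)["expr_path"]
    path = tmp_path / "expr_path.txt"
    write_edge_list(net, path)
    back = read_edge_list(path)
    assert back.name == "expr_path"
    assert set(back.edges) == set(net.edges)
    for e, w in net.edges.items():
        assert back.edges[e] == pytest.approx(w, rel=1e-5)
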