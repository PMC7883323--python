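import itertools
import math

import numpy as np
import pandas as pd
import pytest

from psnet import (
    PredictorConfig,
    SimilarityNetwork,
    call_feature_selection,
    cumulative_scores,
    label_bias,
    label_enrichment,
    score_features_one_split,
)
from psnet import generate_synthetic_dataset
from psnet.dataset import ValidationError


def _printed_table():
    """Feature x split scores as printed for the tumour-subtype example:
    three features scoring 2 in both splits, two scoring NA then 1."""
    return pd.DataFrame(
        {"Split1": [2, 2, 2, np.nan, np.nan], "Split2": [2, 2, 2, 1, 1]},
        index=["pwA", "pwB", "pwC", "age", "stage"],
    )


class TestConsensusCalling:
    def test_strict_consensus_selects_the_three_max_features(self):
        sel = call_feature_selection(_printed_table(), fs_cutoff=2, fs_pct_pass=1)
        assert sorted(sel) == ["pwA", "pwB", "pwC"]

    def test_permissive_any_split_selects_all_five(self):
        sel = call_feature_selection(_printed_table(), fs_cutoff=1, fs_pct_pass=0)
        assert sorted(sel) == ["age", "pwA", "pwB", "pwC", "stage"]

    def test_empty_table_empty_selection(self):
        tbl = pd.DataFrame(columns=["Split1"], dtype=float)
        assert call_feature_selection(tbl, 1, 0) == []

    def test_missing_entries_count_as_below_cutoff(self):
        tbl = pd.DataFrame({"Split1": [np.nan], "Split2": [2.0]}, index=["f"])
        assert call_feature_selection(tbl, 2, 1.0) == []
        assert call_feature_selection(tbl, 2, 0.5) == ["f"]


class TestLabelBias:
    def test_worked_values(self):
        labels = {f"c{i}": "case" for i in range(5)}
        labels.update({f"n{i}": "control" for i in range(5)})
        assert label_bias([f"c{i}" for i in range(5)], labels, "case") == 1.0
        assert label_bias([f"n{i}" for i in range(5)], labels, "case") == -1.0
        members = ["c0", "c1", "n0", "n1"]
        assert label_bias(members, labels, "case") == 0.0


def _clique(name, members):
    net = SimilarityNetwork(name, nodes=set(members))
    for a, b in itertools.combinations(sorted(members), 2):
        net.edges[(a, b)] = 1.0
    return net


def _enumerated_p(cohort, labels, members, positive):
    """Oracle: exhaustive enumeration of all distinct label placements."""
    pos = [c for c in cohort if labels[c] == positive]
    obs = label_bias(members, labels, positive)
    hits = total = 0
    for chosen in itertools.combinations(cohort, len(pos)):
        perm_labels = {c: (positive if c in chosen else "other") for c in cohort}
        total += 1
        if label_bias(members, perm_labels, positive) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestLabelEnrichment:
    def _cohort(self):
        labels = {f"c{i}": "case" for i in range(4)}
        labels.update({f"n{i}": "control" for i in range(4)})
        return labels

    def test_exact_mode_matches_exhaustive_enumeration(self):
        labels = self._cohort()
        cohort = sorted(labels)
        for members in [["c0", "c1", "c2", "c3"], ["c0", "c1", "n0", "n1"],
                        ["n0", "n1", "n2"], ["c0", "n0", "n1", "n2", "n3"]]:
            nets = {"net": _clique("net", members)}
            res = label_enrichment(nets, labels, "case", exact=True)["net"]
            oracle = _enumerated_p(cohort, labels, members, "case")
            assert res.p_value == pytest.approx(oracle, abs=1e-12)

    def test_monte_carlo_approaches_enumeration(self):
        labels = self._cohort()
        members = ["c0", "c1", "c2", "n0"]
        nets = {"net": _clique("net", members)}
        oracle = _enumerated_p(sorted(labels), labels, members, "case")
        res = label_enrichment(nets, labels, "case", num_perms=4000,
                               seed=11)["net"]
        assert res.p_value == pytest.approx(oracle, abs=0.03)

    def test_all_case_network_is_enriched(self):
        labels = self._cohort()
        nets = {"net": _clique("net", ["c0", "c1", "c2", "c3"])}
        res = label_enrichment(nets, labels, "case", num_perms=200, seed=1)["net"]
        assert res.bias == 1.0
        # only 1 of C(8,4)=70 placements reaches bias 1
        assert res.p_value < 0.07 and res.passed

    def test_p_never_zero(self):
        labels = self._cohort()
        nets = {"net": _clique("net", ["c0", "c1", "c2", "c3"])}
        res = label_enrichment(nets, labels, "case", num_perms=5, seed=2)["net"]
        assert res.p_value >= 1 / 6

    def test_null_p_values_are_super_uniform(self):
        """ECDF at 0.05 stays below the 0.07 working threshold under the null."""
        rng = np.random.default_rng(5)
        labels = {f"p{i}": ("case" if i < 10 else "control") for i in range(20)}
        cohort = sorted(labels)
        ps = []
        for _ in range(500):
            members = list(rng.choice(cohort, size=6, replace=False))
            nets = {"net": _clique("net", members)}
            res = label_enrichment(nets, labels, "case", exact=True)["net"]
            ps.append(res.p_value)
        assert np.mean(np.array(ps) <= 0.05) <= 0.07

    def test_empty_member_network_excluded_with_warning(self):
        labels = self._cohort()
        nets = {"ghost": SimilarityNetwork("ghost")}
        with pytest.warns(UserWarning, match="no labelled members"):
            res = label_enrichment(nets, labels, "case", num_perms=10, seed=0)
        assert "ghost" not in res


class TestCumulativeScores:
    def test_three_splits_of_three(self):
        cols = [{"pw": 3}, {"pw": 3}, {"pw": 3}]
        assert cumulative_scores(cols)["pw"] == 9

    def test_single_split_identity(self):
        assert cumulative_scores([{"pw": 2, "other": 0}]) == {"pw": 2, "other": 0}

    def test_maximum_attainable(self):
        cols = [{"pw": 10}] * 3
        assert cumulative_scores(cols)["pw"] == 30

    def test_missing_counts_as_zero(self):
        assert cumulative_scores([{"a": 1}, {"b": 2}]) == {"a": 1, "b": 2}


class TestScoreFeaturesOneSplit:
    def _cfg(self, fsm=3):
        return PredictorConfig(num_splits=1, feat_score_max=fsm,
                               feat_sel_cutoff=1)

    def test_planted_feature_dominates(self):
        wins = 0
        for seed in range(5):
            ds, rules, truth = generate_synthetic_dataset(
                n_patients=60,
                layers={"expression": {"n_features": 5, "group_size": 8,
                                       "metric": "pearson"}},
                effect_size=2.0, seed=seed,
            )
            scores = score_features_one_split(
                ds, rules, truth["metrics"], "case", self._cfg(), seed=seed
            )
            if scores[truth["discriminative"][0]] == 3:
                wins += 1
        assert wins >= 4

    def test_null_features_score_below_half_max(self):
        means = []
        for seed in range(5):
            ds, rules, truth = generate_synthetic_dataset(
                n_patients=60,
                layers={"expression": {"n_features": 5, "group_size": 8,
                                       "metric": "pearson"}},
                effect_size=0.0, seed=100 + seed,
            )
            scores = score_features_one_split(
                ds, rules, truth["metrics"], "case", self._cfg(), seed=seed
            )
            means.append(np.mean(list(scores.values())))
        assert np.mean(means) < 1.5  # feat_score_max / 2

    def test_scores_bounded_by_featscoremax(self, small_cohort):
        ds, rules, truth = small_cohort
        scores = score_features_one_split(
            ds, rules, truth["metrics"], "case", self._cfg(1), seed=0
        )
        assert set(scores.values()) <= {0, 1}

    def test_holdout_needs_enough_members(self, small_cohort):
        ds, rules, truth = small_cohort
        cfg = PredictorConfig(num_splits=1, feat_score_max=50, feat_sel_cutoff=1)
        with pytest.raises(ValidationError):
            score_features_one_split(ds, rules, truth["metrics"], "case",
                                     cfg, seed=0)
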