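"""Pathway feature extraction, boosted classifier and the validation rule."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cnpath.datatypes import PathwayDefinition
from cnpath.network import CommunityPartition, CorrelationNetwork
from cnpath.pathway_ml import (
    FEATURE_NAMES,
    PathwayActivityClassifier,
    PathwayFeatureExtractor,
    PredictionRecord,
    TrainingSet,
    attach_sensitivity,
    build_training_set,
    map_pathway,
    predict_pathways,
    select_features,
    sensitivity_analysis,
    train_classifier,
    validate_and_compare,
)


def _edge(g, a, b, r=0.9):
    g.add_edge(a, b, r=r, p=1e-6, q=1e-4, sign=1 if r >= 0 else -1)


@pytest.fixture
def line_network():
    """Path graph a-b-c-d-e plus isolated node f."""
    g = nx.Graph()
    g.add_nodes_from("abcdef")
    for u, v in zip("abcd", "bcde"):
        _edge(g, u, v)
    net = CorrelationNetwork(g)
    part = CommunityPartition({n: 1 for n in "abcde"} | {"f": 2}, 0.1)
    return net, part


class TestMapping:
    def test_full_subset(self, line_network):
        net, _ = line_network
        pw = PathwayDefinition("p", "p", frozenset("abc"))
        assert map_pathway(net, pw) == frozenset("abc")

    def test_no_members_unmappable(self, line_network):
        net, _ = line_network
        pw = PathwayDefinition("p", "p", frozenset(["x", "y", "z"]))
        assert map_pathway(net, pw) is None

    def test_partial_mapping_fraction(self, line_network):
        net, part = line_network
        pw = PathwayDefinition("p", "p", frozenset(["a", "b", "c", "d", "x", "y"]))
        ext = PathwayFeatureExtractor(net, part)
        feats, skipped = ext.transform([pw])
        assert not skipped
        assert feats.loc["p", "mapped_fraction"] == pytest.approx(4 / 6, abs=1e-3)
        assert feats.loc["p", "mapped_count"] == 4

    def test_below_min_mapped_skipped(self, line_network):
        net, part = line_network
        pw = PathwayDefinition("p", "p", frozenset(["a", "b", "x"]))
        feats, skipped = PathwayFeatureExtractor(net, part).transform([pw])
        assert skipped == ["p"]


class TestFeatures:
    def test_positive_clique(self):
        g = nx.Graph()
        for i, u in enumerate("abcd"):
            for v in "abcd"[i + 1:]:
                _edge(g, u, v, r=0.95)
        net = CorrelationNetwork(g)
        part = CommunityPartition({n: 1 for n in "abcd"}, 0.0)
        vec = PathwayFeatureExtractor(net, part).features(frozenset("abcd"))
        assert vec["subgraph_density"] == 1.0
        assert vec["positive_edge_fraction"] == 1.0
        assert vec["largest_component_fraction"] == 1.0
        assert vec["mean_abs_r"] == pytest.approx(0.95)
        assert vec["same_community_fraction"] == 1.0
        assert vec["mean_pairwise_distance"] == 1.0

    def test_non_adjacent_members_distances_match_bfs(self, line_network):
        net, part = line_network
        vec = PathwayFeatureExtractor(net, part).features(frozenset("ace"))
        assert vec["subgraph_density"] == 0.0
        assert vec["mean_abs_r"] == 0.0
        # BFS distances: a-c=2, a-e=4, c-e=2
        assert vec["mean_pairwise_distance"] == pytest.approx((2 + 4 + 2) / 3)

    def test_unreachable_pairs_use_diameter_plus_one(self, line_network):
        net, part = line_network
        vec = PathwayFeatureExtractor(net, part).features(frozenset(["a", "b", "f"]))
        # diameter 4 (a..e); a-f and b-f unreachable -> 5; a-b = 1
        assert vec["mean_pairwise_distance"] == pytest.approx((1 + 5 + 5) / 3)
        assert vec["n_components_norm"] == pytest.approx(2 / 3)

    def test_permutation_and_relabel_invariance(self, bench_network):
        _, net, part = bench_network
        members = sorted(net.nodes)[10:18]
        ext = PathwayFeatureExtractor(net, part)
        v1 = ext.features(frozenset(members))
        v2 = ext.features(frozenset(reversed(members)))
        pd.testing.assert_series_equal(v1, v2)
        # relabel every node: features of the relabelled pathway are identical
        mapping = {n: f"x_{n}" for n in net.graph.nodes}
        g2 = nx.relabel_nodes(net.graph, mapping)
        part2 = CommunityPartition(
            {mapping[n]: c for n, c in part.membership.items()}, part.modularity
        )
        ext2 = PathwayFeatureExtractor(CorrelationNetwork(g2), part2)
        v3 = ext2.features(frozenset(mapping[m] for m in members))
        assert np.allclose(v1.to_numpy(), v3.to_numpy(), equal_nan=True)

    def test_planted_pathway_concentrated_in_one_community(
        self, bench_study, bench_network
    ):
        _, (_, _, pathways, _) = bench_study
        _, net, part = bench_network
        ext = PathwayFeatureExtractor(net, part)
        pos = [p for p in pathways if p.label == "positive"]
        feats, _ = ext.transform(pos)
        assert (feats["same_community_fraction"] >= 0.8).mean() > 0.8


@pytest.fixture(scope="module")
def bench_training(bench_study, bench_network):
    _, (_, _, pathways, truth) = bench_study
    _, net, part = bench_network
    pos = [p for p in pathways if p.label == "positive"]
    neg = [p for p in pathways if p.label == "negative"]
    ts = build_training_set(net, part, pos, neg, n_random_negatives=0, seed=1)
    return ts


class TestTrainingSet:
    def test_default_counts(self, bench_training):
        assert (bench_training.labels == 1).sum() == 38
        assert (bench_training.labels == 2).sum() == 38

    def test_random_negatives_size_matched_and_deterministic(
        self, bench_study, bench_network
    ):
        _, (_, _, pathways, _) = bench_study
        _, net, part = bench_network
        pos = [p for p in pathways if p.label == "positive"]
        ts1 = build_training_set(net, part, pos, [], n_random_negatives=10, seed=3)
        ts2 = build_training_set(net, part, pos, [], n_random_negatives=10, seed=3)
        pd.testing.assert_frame_equal(ts1.features, ts2.features)
        rand_sizes = ts1.features.loc[ts1.provenance == "random", "mapped_count"]
        pos_sizes = ts1.features.loc[ts1.provenance == "consensus", "mapped_count"]
        assert set(rand_sizes) <= set(pos_sizes)

    def test_insufficient_positives_rejected(self, bench_network):
        _, net, part = bench_network
        few = [
            PathwayDefinition(f"p{i}", "p", frozenset(sorted(net.nodes)[:4]))
            for i in range(3)
        ]
        with pytest.raises(ValueError, match="larger pathway database"):
            build_training_set(net, part, few, [], 0, seed=0)

    def test_bad_labels_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError):
            TrainingSet(X, pd.Series([1, 3], index=X.index), pd.Series("x", index=X.index))


def _separable_set(n_per_class=20, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "signal": np.concatenate(
                [rng.uniform(0.8, 1.0, n_per_class), rng.uniform(0.0, 0.2, n_per_class)]
            ),
            "noise": rng.normal(size=2 * n_per_class),
        }
    )
    y = pd.Series([1] * n_per_class + [2] * n_per_class)
    return TrainingSet(X, y, pd.Series("toy", index=X.index))


class TestFeatureSelection:
    def test_perfect_separator_ranks_first(self):
        ts = _separable_set()
        assert select_features(ts, top_k=1)[0] == "signal"

    def test_top_k_all_is_identity(self, bench_training):
        feats = select_features(bench_training, top_k=len(FEATURE_NAMES))
        assert set(feats) <= set(FEATURE_NAMES)

    def test_constant_features_excluded(self):
        ts = _separable_set()
        ts.features["flat"] = 1.0
        assert "flat" not in select_features(ts, top_k=2)

    def test_selection_stability_across_seeds(self, bench_training):
        tops = [
            tuple(sorted(select_features(bench_training, top_k=2, seed=s)))
            for s in range(10)
        ]
        most_common = max(set(tops), key=tops.count)
        assert tops.count(most_common) >= 8


class TestClassifier:
    def test_separable_toy_perfect_cv(self):
        ts = _separable_set()
        clf = train_classifier(ts, n_folds=5)
        assert clf.cv_auc_ == 1.0
        assert clf.cv_accuracy_ == 1.0

    def test_single_class_rejected(self):
        X = pd.DataFrame({"f": np.arange(10.0)})
        clf = PathwayActivityClassifier(n_folds=2)
        with pytest.raises(ValueError, match="single class"):
            clf.fit(X, pd.Series([1] * 10, index=X.index))

    def test_accuracy_consistent_with_confusion(self, bench_training):
        clf = train_classifier(bench_training, seed=1)
        tp, fp = clf.cv_confusion_[0]
        fn, tn = clf.cv_confusion_[1]
        assert clf.cv_accuracy_ == pytest.approx((tp + tn) / (tp + fp + fn + tn))
        assert tp + fp + fn + tn == len(bench_training.labels)

    def test_auc_equals_pair_counting_oracle(self, bench_training):
        clf = train_classifier(bench_training, seed=1)
        scores = clf.oof_prediction_
        pos = scores[bench_training.labels == 1].to_numpy()
        neg = scores[bench_training.labels == 2].to_numpy()
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert clf.cv_auc_ == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_label_permutation_gives_chance_auc(self, bench_training):
        rng = np.random.default_rng(0)
        aucs = []
        for s in range(20):
            y = pd.Series(
                rng.permutation(bench_training.labels.to_numpy()),
                index=bench_training.labels.index,
            )
            clf = PathwayActivityClassifier(random_state=s)
            clf.fit(bench_training.features, y)
            aucs.append(clf.cv_auc_)
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_memorizes_separable_training_pathways(self):
        ts = _separable_set()
        clf = train_classifier(ts, n_folds=5)
        proba = clf.predict_proba(ts.features)[:, 0]
        assert (proba[ts.labels.to_numpy() == 1] > 0.5).all()

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        clf = PathwayActivityClassifier(n_folds=3, random_state=7)
        clone(clf)  # get_params/set_params round-trip
        ts = _separable_set()
        clf.fit(ts.features, ts.labels)
        assert list(clf.classes_) == [1, 2]
        preds = clf.predict(ts.features)
        assert set(preds) <= {1, 2}


class TestSensitivityAndValidation:
    def test_full_fraction_zero_variance(self, bench_training):
        clf = train_classifier(bench_training, seed=1)
        test_X = bench_training.features.iloc[:5]
        sens = sensitivity_analysis(
            clf, bench_training.features, bench_training.labels, test_X,
            reps=2, frac=1.0, seed=0,
        )
        assert np.allclose(sens["sensitivity_variance"], 0.0)

    def test_validation_rule(self):
        assert PredictionRecord("p", 0.96, 0.94).validated
        assert not PredictionRecord("p", 0.74, 0.45).validated
        assert not PredictionRecord("p", 0.40, 0.90).validated
        assert not PredictionRecord("p", 0.74, None).validated

    def test_sensitivity_close_to_original_prediction(
        self, bench_study, bench_network, bench_training
    ):
        cfg, (_, _, _, truth) = bench_study
        _, net, part = bench_network
        from cnpath.simulate import sample_community_pathways

        clf = train_classifier(bench_training, seed=1)
        ext = PathwayFeatureExtractor(net, part)
        test = sample_community_pathways(truth, 15, cfg.pathway_size_range, 99)
        records, _ = predict_pathways(clf, ext, test)
        feats, _ = ext.transform(test)
        sens = sensitivity_analysis(
            clf, bench_training.features, bench_training.labels, feats,
            reps=25, frac=0.8, seed=1,
        )
        attach_sensitivity(records, sens)
        close = [
            abs(r.prediction - r.sensitivity_mean) <= 0.15 for r in records
        ]
        assert np.mean(close) >= 0.8

    def test_compare_identity_and_specificity(self):
        a = [PredictionRecord("p1", 0.9, 0.9), PredictionRecord("p2", 0.9, 0.9)]
        b = [PredictionRecord("p1", 0.9, 0.9), PredictionRecord("p2", 0.2, 0.1)]
        out = validate_and_compare(a, b)
        assert out["shared"] == {"p1"}
        assert out["a_specific"] == {"p2"}
        assert out["b_specific"] == set()
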