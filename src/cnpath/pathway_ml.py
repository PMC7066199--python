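"""Pathway-activity prediction from correlation-network topology.

A metabolic pathway whose reactions are active leaves a footprint in a
compound correlation network: its members correlate, co-cluster and sit
close together. Each pathway is summarised as a fixed-order vector of 11
topological descriptors of its mapped members, and a gradient-boosted tree
classifier is trained on known-active ("positive", label 1) versus
random/foreign ("negative", label 2) pathways with 10-fold cross
validation. Predictions are validated by a subsampling sensitivity
analysis: a pathway counts as validly predicted only when the original
model's probability and the mean probability over models retrained on
repeated 80% subsamples of the training instances both reach 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .datatypes import PathwayDefinition
from .network import CommunityPartition, CorrelationNetwork

POSITIVE_LABEL = 1
NEGATIVE_LABEL = 2

FEATURE_NAMES = (
    "mapped_fraction",
    "mapped_count",
    "subgraph_density",
    "mean_abs_r",
    "positive_edge_fraction",
    "largest_component_fraction",
    "n_components_norm",
    "same_community_fraction",
    "mean_member_degree",
    "mean_member_clustering",
    "mean_pairwise_distance",
)

_XGB_DEFAULTS = dict(
    max_depth=3,
    learning_rate=0.1,
    n_estimators=200,
    objective="binary:logistic",
    eval_metric="logloss",
    n_jobs=1,
    tree_method="exact",
)


def map_pathway(
    net: CorrelationNetwork, pw: PathwayDefinition, min_mapped: int = 3
) -> frozenset[str] | None:
    """Members of ``pw`` present in the network; None when unmappable.

    A pathway is unmappable when fewer than ``min_mapped`` members map: a
    two-node footprint has degenerate subgraph statistics.
    """
    mapped = frozenset(pw.members) & frozenset(net.graph.nodes)
    return mapped if len(mapped) >= min_mapped else None


class PathwayFeatureExtractor:
    """Computes pathway feature vectors against one network + partition.

    Shortest-path structure of the full network is computed once at
    construction and reused for every pathway.
    """

    def __init__(self, net: CorrelationNetwork, partition: CommunityPartition,
                 min_mapped: int = 3):
        self.net = net
        self.partition = partition
        self.min_mapped = min_mapped
        self._clustering = nx.clustering(net.graph)
        self._sp = dict(nx.all_pairs_shortest_path_length(net.graph))
        finite = [
            d for src in self._sp.values() for d in src.values()
        ]
        self.diameter_ = max(finite) if finite else 0

    def features(self, mapped: frozenset[str]) -> pd.Series:
        """The 11-descriptor vector for one mapped member set."""
        g = self.net.graph
        members = sorted(mapped)
        m = len(members)
        sub = g.subgraph(members)
        n_pairs = m * (m - 1) // 2
        n_sub_edges = sub.number_of_edges()
        rs = [abs(d["r"]) for _, _, d in sub.edges(data=True)]
        signs = [d["sign"] for _, _, d in sub.edges(data=True)]
        comps = list(nx.connected_components(sub))
        same_comm = sum(
            1
            for i in range(m)
            for j in range(i + 1, m)
            if self.partition.same_community(members[i], members[j])
        )
        dists = []
        unreachable_dist = self.diameter_ + 1
        for i in range(m):
            row = self._sp.get(members[i], {})
            for j in range(i + 1, m):
                dists.append(row.get(members[j], unreachable_dist))
        return pd.Series(
            {
                "mapped_fraction": np.nan,  # filled by caller who knows |members|
                "mapped_count": float(m),
                "subgraph_density": n_sub_edges / n_pairs,
                "mean_abs_r": float(np.mean(rs)) if rs else 0.0,
                "positive_edge_fraction": (
                    sum(1 for s in signs if s > 0) / len(signs) if signs else 0.0
                ),
                "largest_component_fraction": max(len(c) for c in comps) / m,
                "n_components_norm": len(comps) / m,
                "same_community_fraction": same_comm / n_pairs,
                "mean_member_degree": float(np.mean([g.degree(v) for v in members])),
                "mean_member_clustering": float(
                    np.mean([self._clustering[v] for v in members])
                ),
                "mean_pairwise_distance": float(np.mean(dists)),
            }
        )[list(FEATURE_NAMES)]

    def transform(self, pathways: list[PathwayDefinition]) -> tuple[pd.DataFrame, list[str]]:
        """Feature matrix for all mappable pathways; ids of skipped ones."""
        rows, skipped = {}, []
        for pw in pathways:
            mapped = map_pathway(self.net, pw, self.min_mapped)
            if mapped is None:
                skipped.append(pw.id)
                continue
            vec = self.features(mapped)
            vec["mapped_fraction"] = len(mapped) / len(pw.members)
            rows[pw.id] = vec
        features = pd.DataFrame(rows).T
        if not features.empty:
            features = features[list(FEATURE_NAMES)]
        return features, skipped


def compute_pathway_features(
    net: CorrelationNetwork,
    partition: CommunityPartition,
    mapped: frozenset[str],
    total_members: int | None = None,
) -> pd.Series:
    """One pathway's feature vector (functional form of the extractor)."""
    extractor = PathwayFeatureExtractor(net, partition)
    vec = extractor.features(mapped)
    vec["mapped_fraction"] = len(mapped) / (total_members or len(mapped))
    return vec


# ---------------------------------------------------------------------------
# training set

@dataclass
class TrainingSet:
    features: pd.DataFrame      # instances x FEATURE_NAMES
    labels: pd.Series           # 1 = positive, 2 = negative
    provenance: pd.Series       # consensus / foreign / random

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {POSITIVE_LABEL, NEGATIVE_LABEL}
        if bad:
            raise ValueError(f"labels must be 1/2, found {sorted(bad)}")


def build_training_set(
    net: CorrelationNetwork,
    partition: CommunityPartition,
    positives: list[PathwayDefinition],
    foreign_negatives: list[PathwayDefinition],
    n_random_negatives: int,
    seed: int,
    sizes: list[int] | None = None,
    min_mapped: int = 3,
    min_positives: int = 10,
) -> TrainingSet:
    """Features + labels for positives, foreign negatives and random subsets.

    Random negative subsets are drawn uniformly from the network's node
    universe with sizes matched to the mapped-positive size distribution
    (or to explicit ``sizes``), so the classifier cannot key on size alone.
    """
    extractor = PathwayFeatureExtractor(net, partition, min_mapped=min_mapped)
    pos_feat, pos_skipped = extractor.transform(positives)
    if len(pos_feat) < min_positives:
        raise ValueError(
            f"only {len(pos_feat)} mappable positive pathways "
            f"(skipped {pos_skipped}); provide a larger pathway database"
        )
    neg_feat, _ = extractor.transform(foreign_negatives)

    rng = np.random.default_rng(seed)
    nodes = sorted(net.graph.nodes)
    if sizes is None:
        sizes = pos_feat["mapped_count"].astype(int).tolist()
    rand_pathways = []
    for i in range(1, n_random_negatives + 1):
        size = int(rng.choice(sizes))
        members = frozenset(rng.choice(nodes, size=size, replace=False))
        rand_pathways.append(
            PathwayDefinition(f"rand_{i:03d}", f"random subset {i}", members,
                              label="negative")
        )
    rand_feat, _ = extractor.transform(rand_pathways)

    features = pd.concat([pos_feat, neg_feat, rand_feat])
    labels = pd.Series(
        [POSITIVE_LABEL] * len(pos_feat)
        + [NEGATIVE_LABEL] * (len(neg_feat) + len(rand_feat)),
        index=features.index,
    )
    provenance = pd.Series(
        ["consensus"] * len(pos_feat)
        + ["foreign"] * len(neg_feat)
        + ["random"] * len(rand_feat),
        index=features.index,
    )
    return TrainingSet(features, labels, provenance)


# ---------------------------------------------------------------------------
# classifier

def select_features(ts: TrainingSet, top_k: int = 6, seed: int = 0) -> list[str]:
    """Rank features by total split gain of a preliminary boosted model."""
    X = ts.features
    keep = [c for c in X.columns if X[c].nunique() > 1]
    if top_k >= len(keep):
        return keep
    model = xgb.XGBClassifier(random_state=seed, **_XGB_DEFAULTS)
    model.fit(X[keep], (ts.labels == POSITIVE_LABEL).astype(int))
    booster = model.get_booster()
    gains = booster.get_score(importance_type="total_gain")
    ranked = sorted(keep, key=lambda c: (-gains.get(c, 0.0), keep.index(c)))
    return ranked[:top_k]


class PathwayActivityClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted pathway-presence classifier with internal CV metrics.

    Shallow boosted trees (depth <= 3, learning rate 0.1, at most
    ``n_estimators`` rounds with early stopping on the held-out fold's
    log-loss) are cross-validated with stratified ``n_folds`` folds; AUC,
    the 2x2 confusion matrix at ``threshold`` and accuracy are computed
    from out-of-fold probabilities, then a final model is refit on all
    instances. Class labels are 1 (positive pathway) and 2 (negative).

    Fitted attributes: ``selected_features_``, ``cv_auc_``,
    ``cv_confusion_`` (rows = predicted class, columns = actual class, in
    label order 1, 2), ``cv_accuracy_``, ``oof_prediction_``, ``model_``.
    """

    def __init__(
        self,
        n_folds: int = 10,
        top_k_features: int = 6,
        max_depth: int = 3,
        learning_rate: float = 0.1,
        n_estimators: int = 200,
        early_stopping_rounds: int = 20,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.n_folds = n_folds
        self.top_k_features = top_k_features
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.n_estimators = n_estimators
        self.early_stopping_rounds = early_stopping_rounds
        self.threshold = threshold
        self.random_state = random_state

    def _params(self) -> dict:
        p = dict(_XGB_DEFAULTS)
        p.update(
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            n_estimators=self.n_estimators,
        )
        return p

    def fit(self, X, y, provenance=None):
        X = pd.DataFrame(X).copy()
        y = pd.Series(np.asarray(y), index=X.index)
        classes = set(y.unique())
        if classes - {POSITIVE_LABEL, NEGATIVE_LABEL}:
            raise ValueError("labels must be 1 (positive) / 2 (negative)")
        if len(classes) < 2:
            raise ValueError("training set contains a single class")
        self.classes_ = np.array([POSITIVE_LABEL, NEGATIVE_LABEL])

        ts = TrainingSet(
            X, y,
            provenance if provenance is not None
            else pd.Series("unknown", index=X.index),
        )
        self.selected_features_ = select_features(
            ts, top_k=self.top_k_features, seed=self.random_state
        )
        Xs = X[self.selected_features_]
        y01 = (y == POSITIVE_LABEL).astype(int).to_numpy()

        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        oof = np.empty(len(y01))
        best_rounds = []
        for train_idx, test_idx in skf.split(Xs, y01):
            model = xgb.XGBClassifier(
                random_state=self.random_state,
                early_stopping_rounds=self.early_stopping_rounds,
                **self._params(),
            )
            model.fit(
                Xs.iloc[train_idx],
                y01[train_idx],
                eval_set=[(Xs.iloc[test_idx], y01[test_idx])],
                verbose=False,
            )
            oof[test_idx] = model.predict_proba(Xs.iloc[test_idx])[:, 1]
            best_rounds.append(model.best_iteration + 1)

        self.oof_prediction_ = pd.Series(oof, index=X.index)
        self.cv_auc_ = float(roc_auc_score(y01, oof))
        pred_pos = oof >= self.threshold
        actual_pos = y01 == 1
        tp = int(np.sum(pred_pos & actual_pos))
        fp = int(np.sum(pred_pos & ~actual_pos))
        fn = int(np.sum(~pred_pos & actual_pos))
        tn = int(np.sum(~pred_pos & ~actual_pos))
        # rows = predicted class (1, 2); columns = actual class (1, 2)
        self.cv_confusion_ = np.array([[tp, fp], [fn, tn]])
        self.cv_accuracy_ = (tp + tn) / len(y01)

        self.final_n_estimators_ = max(1, int(np.median(best_rounds)))
        params = self._params()
        params["n_estimators"] = self.final_n_estimators_
        self.model_ = xgb.XGBClassifier(random_state=self.random_state, **params)
        self.model_.fit(Xs, y01)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        Xs = pd.DataFrame(X)[self.selected_features_]
        p_pos = self.model_.predict_proba(Xs)[:, 1]
        return np.column_stack([p_pos, 1.0 - p_pos])

    def predict(self, X):
        p_pos = self.predict_proba(X)[:, 0]
        return np.where(p_pos >= self.threshold, POSITIVE_LABEL, NEGATIVE_LABEL)

    def confusion_table(self) -> pd.DataFrame:
        check_is_fitted(self, "cv_confusion_")
        return pd.DataFrame(
            self.cv_confusion_,
            index=pd.Index([1, 2], name="predicted"),
            columns=pd.Index([1, 2], name="actual"),
        )


def train_classifier(
    ts: TrainingSet,
    selected_features: list[str] | None = None,
    n_folds: int = 10,
    seed: int = 0,
    **kwargs,
) -> PathwayActivityClassifier:
    """Fit a :class:`PathwayActivityClassifier` on a training set."""
    clf = PathwayActivityClassifier(n_folds=n_folds, random_state=seed, **kwargs)
    if selected_features is not None:
        clf.top_k_features = len(selected_features)
    clf.fit(ts.features, ts.labels, provenance=ts.provenance)
    return clf


# ---------------------------------------------------------------------------
# prediction, sensitivity analysis, validation

@dataclass
class PredictionRecord:
    pathway_id: str
    prediction: float
    sensitivity_mean: float | None = None
    sensitivity_variance: float | None = None
    threshold: float = 0.5

    @property
    def validated(self) -> bool:
        return (
            self.prediction >= self.threshold
            and self.sensitivity_mean is not None
            and self.sensitivity_mean >= self.threshold
        )


def predict_pathways(
    clf: PathwayActivityClassifier,
    extractor: PathwayFeatureExtractor,
    pathways: list[PathwayDefinition],
    threshold: float = 0.5,
) -> tuple[list[PredictionRecord], list[str]]:
    """Per-pathway activity probability; unmappable pathways are skipped."""
    features, skipped = extractor.transform(pathways)
    records = []
    if not features.empty:
        probs = clf.predict_proba(features)[:, 0]
        records = [
            PredictionRecord(pid, float(p), threshold=threshold)
            for pid, p in zip(features.index, probs)
        ]
    return records, skipped


def sensitivity_analysis(
    clf: PathwayActivityClassifier,
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_test: pd.DataFrame,
    reps: int = 100,
    frac: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Retrain on stratified ``frac`` subsamples; mean/variance per pathway.

    Each repetition keeps ``round(frac * n)`` instances per class (so no
    class can vanish), refits a model with the final model's settings, and
    predicts every test pathway. Returns a table indexed by pathway id with
    ``sensitivity_mean`` and ``sensitivity_variance`` columns.
    """
    check_is_fitted(clf, "model_")
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    y01 = (pd.Series(np.asarray(y_train), index=X_train.index) == POSITIVE_LABEL
           ).astype(int)
    Xs = X_train[clf.selected_features_]
    Xt = X_test[clf.selected_features_]
    params = clf._params()
    params["n_estimators"] = clf.final_n_estimators_
    by_class = {c: np.nonzero(y01.to_numpy() == c)[0] for c in (0, 1)}
    preds = np.empty((reps, len(X_test)))
    for rep in range(reps):
        keep = np.concatenate(
            [
                rng.choice(idx, size=max(1, round(frac * len(idx))), replace=False)
                for idx in by_class.values()
            ]
        )
        model = xgb.XGBClassifier(random_state=clf.random_state, **params)
        model.fit(Xs.iloc[keep], y01.iloc[keep])
        preds[rep] = model.predict_proba(Xt)[:, 1]
    return pd.DataFrame(
        {
            "sensitivity_mean": preds.mean(axis=0),
            "sensitivity_variance": preds.var(axis=0, ddof=0),
        },
        index=X_test.index,
    )


def attach_sensitivity(
    records: list[PredictionRecord], sens: pd.DataFrame
) -> list[PredictionRecord]:
    for rec in records:
        if rec.pathway_id in sens.index:
            rec.sensitivity_mean = float(sens.loc[rec.pathway_id, "sensitivity_mean"])
            rec.sensitivity_variance = float(
                sens.loc[rec.pathway_id, "sensitivity_variance"]
            )
    return records


def validate_and_compare(
    records_a: list[PredictionRecord], records_b: list[PredictionRecord]
) -> dict[str, set[str]]:
    """Partition validated pathways into shared / a-specific / b-specific."""
    valid_a = {r.pathway_id for r in records_a if r.validated}
    valid_b = {r.pathway_id for r in records_b if r.validated}
    return {
        "shared": valid_a & valid_b,
        "a_specific": valid_a - valid_b,
        "b_specific": valid_b - valid_a,
    }
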