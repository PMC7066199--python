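"""End-to-end orchestration: simulate -> preprocess -> network -> ML -> GA.

Each stage draws its randomness from a seed derived by stable hashing of
the stage name and the one global seed, so any stage can be reproduced in
isolation. Stored values keep full precision; presentation rounding (2
decimals for ratios and densities) happens only in the report layer.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import CompoundMatrix, ExpressionMatrix, PathwayDefinition, write_pathway_db
from .ga import GAConfig, run_ga
from .network import (
    CorrelationNetwork,
    build_network,
    correlate_all_pairs,
    detect_communities,
    export_network,
    network_set_ops,
    network_stats,
)
from .pathway_ml import (
    PathwayFeatureExtractor,
    attach_sensitivity,
    build_training_set,
    predict_pathways,
    sensitivity_analysis,
    train_classifier,
    validate_and_compare,
)
from .preprocess import anova_bonferroni, anova_table, impute_missing, log_transform, pca
from .simulate import (
    SyntheticConfig,
    sample_community_pathways,
    sample_random_subsets,
    simulate_study,
)

log = logging.getLogger("cnpath")


def derive_seed(stage: str, seed: int) -> int:
    """Stable per-stage seed below 2^31."""
    return zlib.crc32(f"{stage}:{seed}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """All stage parameters of an end-to-end run."""

    seed: int = 0
    # input paths; when compounds_tsv is None the simulate stage runs
    compounds_tsv: str | None = None
    expression_tsv: str | None = None
    pathway_db: str | None = None
    # synthetic generator overrides (merged into SyntheticConfig)
    synthetic: dict = field(default_factory=dict)
    # preprocessing
    impute_rank: int = 3
    # network
    r_min: float = 0.8
    q_max: float = 0.05
    walktrap_steps: int = 4
    # pathway ML
    min_mapped: int = 3
    n_folds: int = 10
    top_k_features: int = 6
    prediction_threshold: float = 0.5
    sensitivity_reps: int = 100
    sensitivity_frac: float = 0.8
    n_test_positive: int = 20
    n_test_random: int = 20
    # genetic algorithm
    ga_enabled: bool = True
    ga_pathway: str | None = None  # default: the planted module's target pathway
    ga_max_candidates: int = 300
    ga: dict = field(default_factory=dict)
    # which two accessions to compare
    accessions: tuple[str, str] | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True),
            encoding="utf-8",
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if isinstance(data.get("accessions"), list):
            data["accessions"] = tuple(data["accessions"])
        return cls(**data)


def _round2(x: float) -> float:
    return float(round(x, 2))


def _stats_block(stats) -> dict:
    d = stats.to_dict()
    d["pe_ne_ratio_2dp"] = (
        "inf" if d["pe_ne_ratio"] == "inf" else _round2(stats.pe_ne_ratio)
    )
    d["edge_density_2dp"] = _round2(stats.edge_density)
    return d


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and write artifacts + a summary JSON.

    Any stage failure raises with the stage name; artifacts written before
    the failure remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "versions": {"cnpath": __version__, "python": platform.python_version()},
        "seeds": {"global": config.seed},
    }
    stage = "setup"
    try:
        # -- simulate / load ------------------------------------------------
        stage = "simulate"
        truth = None
        if config.compounds_tsv is None:
            syn = SyntheticConfig(
                **{"seed": derive_seed("simulate", config.seed), **config.synthetic}
            )
            summary["seeds"]["simulate"] = syn.seed
            compounds, expression, pathways, truth = simulate_study(syn)
            compounds.to_tsv(outdir / "compounds.tsv")
            expression.to_tsv(outdir / "expression.tsv")
            write_pathway_db(pathways, outdir / "pathways.json")
        else:
            compounds = CompoundMatrix.from_tsv(config.compounds_tsv)
            expression = (
                ExpressionMatrix.from_tsv(config.expression_tsv)
                if config.expression_tsv
                else None
            )
            if config.pathway_db is None:
                raise ValueError("a pathway database is required")
            from .datatypes import read_pathway_db

            pathways = read_pathway_db(config.pathway_db)
            syn = None
        if config.ga_enabled and expression is None:
            raise ValueError("GA stage enabled but no expression matrix given")

        # -- preprocess -----------------------------------------------------
        stage = "preprocess"
        processed = impute_missing(log_transform(compounds), n_components=config.impute_rank)
        processed.to_tsv(outdir / "processed_compounds.tsv")
        anova = anova_table(anova_bonferroni(processed))
        anova.to_csv(outdir / "anova.tsv", sep="\t")
        pca_res = pca(processed.values, n_components=min(5, processed.n_samples - 1))
        pca_res.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        summary["preprocess"] = {
            "n_samples": int(processed.n_samples),
            "n_compounds": int(processed.values.shape[1]),
            "n_missing_imputed": int(compounds.missing_mask.to_numpy().sum()),
            "n_significant_compounds": int(anova["significant"].sum()),
            "pc1_variance_fraction": float(pca_res.explained_variance_ratio[0]),
        }

        # -- per-accession networks ----------------------------------------
        stage = "network"
        acc_labels = (
            list(config.accessions)
            if config.accessions
            else list(processed.samples["accession"].unique())[:2]
        )
        if len(acc_labels) < 2:
            raise ValueError("need two accessions to compare")
        nets: dict[str, CorrelationNetwork] = {}
        partitions = {}
        summary["networks"] = {}
        for acc in acc_labels:
            sub = processed.subset_samples(
                (processed.samples["accession"] == acc).to_numpy()
            )
            tables = correlate_all_pairs(sub)
            net = build_network(sub, tables, r_min=config.r_min, q_max=config.q_max)
            part = detect_communities(net, steps=config.walktrap_steps)
            nets[acc], partitions[acc] = net, part
            export_network(net, outdir / f"network_{acc}.edges.tsv", "edge-tsv")
            export_network(net, outdir / f"network_{acc}.graphml", "graphml", part)
            summary["networks"][acc] = {
                **_stats_block(network_stats(net)),
                "n_communities": part.n_communities,
                "modularity": part.modularity,
            }

        stage = "network-set-ops"
        a, b = acc_labels[0], acc_labels[1]
        ops = network_set_ops(nets[a], nets[b])
        setops = {name: net.n_edges for name, net in ops.items()}
        assert setops["intersection"] + setops["a_minus_b"] == nets[a].n_edges
        assert setops["intersection"] + setops["b_minus_a"] == nets[b].n_edges
        assert setops["symmetric_difference"] == setops["a_minus_b"] + setops["b_minus_a"]
        summary["set_ops"] = {"a": a, "b": b, **setops}

        # -- pathway ML -----------------------------------------------------
        stage = "pathway-ml"
        ml_seed = derive_seed("pathway-ml", config.seed)
        summary["seeds"]["pathway_ml"] = ml_seed
        positives = [p for p in pathways if p.label == "positive"]
        negatives = [p for p in pathways if p.label == "negative"]
        if truth is not None:
            test_seed = derive_seed("test-pathways", config.seed)
            summary["seeds"]["test_pathways"] = test_seed
            test_pathways = sample_community_pathways(
                truth, config.n_test_positive, syn.pathway_size_range, test_seed
            ) + sample_random_subsets(
                truth, config.n_test_random, syn.pathway_size_range, test_seed + 1
            )
        else:
            test_pathways = [p for p in pathways if p.label is None]
        summary["pathway_ml"] = {}
        records_by_acc = {}
        for acc in acc_labels:
            ts = build_training_set(
                nets[acc],
                partitions[acc],
                positives,
                negatives,
                n_random_negatives=0,
                seed=ml_seed,
                min_mapped=config.min_mapped,
            )
            clf = train_classifier(
                ts,
                n_folds=config.n_folds,
                seed=ml_seed,
                top_k_features=config.top_k_features,
                threshold=config.prediction_threshold,
            )
            extractor = PathwayFeatureExtractor(
                nets[acc], partitions[acc], min_mapped=config.min_mapped
            )
            records, skipped = predict_pathways(
                clf, extractor, test_pathways, threshold=config.prediction_threshold
            )
            feats, _ = extractor.transform(test_pathways)
            sens = sensitivity_analysis(
                clf,
                ts.features,
                ts.labels,
                feats,
                reps=config.sensitivity_reps,
                frac=config.sensitivity_frac,
                seed=ml_seed,
            )
            attach_sensitivity(records, sens)
            records_by_acc[acc] = records
            summary["pathway_ml"][acc] = {
                "n_train_positive": int((ts.labels == 1).sum()),
                "n_train_negative": int((ts.labels == 2).sum()),
                "selected_features": list(clf.selected_features_),
                "cv_auc": clf.cv_auc_,
                "cv_accuracy": clf.cv_accuracy_,
                "cv_confusion": clf.cv_confusion_.tolist(),
                "n_test_skipped": len(skipped),
                "n_validated": sum(r.validated for r in records),
            }
            pd.DataFrame(
                [
                    {
                        "pathway": r.pathway_id,
                        "prediction": r.prediction,
                        "sensitivity_mean": r.sensitivity_mean,
                        "sensitivity_variance": r.sensitivity_variance,
                        "validated": r.validated,
                    }
                    for r in records
                ]
            ).to_csv(outdir / f"predictions_{acc}.tsv", sep="\t", index=False)

        compared = validate_and_compare(records_by_acc[a], records_by_acc[b])
        summary["pathway_comparison"] = {
            k: sorted(v) for k, v in compared.items()
        }

        # -- genetic algorithm ---------------------------------------------
        if config.ga_enabled:
            stage = "ga"
            ga_seed = derive_seed("ga", config.seed)
            summary["seeds"]["ga"] = ga_seed
            target_id = config.ga_pathway or (
                truth.module_target_pathway if truth is not None else None
            )
            if target_id is None:
                raise ValueError("no GA target pathway configured")
            members = next(p.members for p in pathways if p.id == target_id)
            members = sorted(set(members) & set(processed.values.columns))
            target_pc1 = pca(processed.values[members], n_components=1).pc1()
            candidates = _prescreen_candidates(
                expression.values, target_pc1.to_numpy(), config.ga_max_candidates
            )
            ga_cfg = GAConfig(**{"seed": ga_seed, **config.ga})
            result = run_ga(
                expression,
                processed,
                members,
                config=ga_cfg,
                candidate_genes=candidates,
            )
            pd.Series(sorted(result.genes), name="gene").to_csv(
                outdir / "ga_genes.tsv", sep="\t", index=False
            )
            summary["ga"] = {
                "target_pathway": target_id,
                "n_candidate_genes": len(candidates),
                "n_selected_genes": len(result.genes),
                "objective": result.objective,
                "n_generations": result.n_generations,
            }
            (outdir / "ga_result.json").write_text(
                json.dumps(
                    {
                        "genes": sorted(result.genes),
                        "objective": result.objective,
                        "trajectory": result.fitness_trajectory,
                    },
                    indent=1,
                ),
                encoding="utf-8",
            )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary


def _prescreen_candidates(
    expr_values: pd.DataFrame, target: np.ndarray, max_candidates: int
) -> list[str]:
    """Top genes by |Pearson r| with the target score vector.

    A light stand-in for restricting the GA to one co-expression module:
    genes marginally unrelated to the pathway signal are dropped before the
    subset search.
    """
    if expr_values.shape[1] <= max_candidates:
        return list(expr_values.columns)
    X = expr_values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    t = target - target.mean()
    sd = Xc.std(axis=0)
    sd[sd == 0] = np.inf
    cors = np.abs(Xc.T @ t) / (len(t) * sd * t.std())
    order = np.argsort(-cors)[:max_candidates]
    return [expr_values.columns[i] for i in sorted(order)]
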