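"""Synthetic multi-omics study generator.

Emulates a two-accession cold/freezing stress design: 2 accessions x 3
treatments x 3 replicates = 18 samples, ~139 metabolites + ~195 lipids with
planted block-correlation structure, ~4.4% missing values, small pathway
databases, and a gene-expression matrix with one planted module whose first
principal component tracks a target pathway's compound PC1.

The compound model is a latent-factor model: each community c has one
standard-normal factor per sample, and member j of community c is

    log x[s, j] = loading * f[c, s] + noise_sd * eps[s, j] + shift[j, cell(s)]

exponentiated to natural scale (so the downstream natural-log transform
recovers it exactly). Treatment/accession responses are planted per
compound in two regimes: mild responders (below the ANOVA detection floor,
leaving their community correlations intact) and strong responders (large
fold changes that a Bonferroni-corrected ANOVA flags reliably). Missing
entries are inserted completely at random with an exact cell count of
``round(missing_rate * n_cells)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CompoundMatrix, ExpressionMatrix, PathwayDefinition

_METABOLITE_CLASSES = ("sugar", "amino acid", "organic acid", "amine",
                       "fatty acid", "unknown")
_LIPID_CLASSES = ("TAG", "DAG", "PC", "PE", "PG", "PI", "PS",
                  "MGDG", "DGDG", "SQDG")

#: fraction of compounds given a planted treatment/accession response
_RESPONSIVE_FRACTION = 0.10
#: mild responders (two thirds): one accession x treatment cell shifted by
#: U(2, 3.9) x noise_sd -- an accession-specific response below the
#: Bonferroni detection floor
_MILD_SHIFT_RANGE = (2.0, 3.9)
#: strong responders (one third): a whole treatment (both accessions)
#: shifted by U(60, 80) x noise_sd -- large fold changes that survive
#: imputation smearing and are flagged essentially always
_STRONG_SHIFT_RANGE = (60.0, 80.0)


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters of the synthetic generator."""

    n_accessions: int = 2
    treatments: tuple[str, ...] = ("control", "cold", "freezing")
    n_reps: int = 3
    n_metabolites: int = 139
    n_lipids: int = 195
    n_communities: int = 5
    community_loading: float = 0.9
    noise_sd: float = 0.15
    missing_rate: float = 0.044
    n_genes: int = 2000
    planted_module_size: int = 75
    planted_module_rho: float = 0.9
    n_pos_pathways: int = 38
    n_neg_pathways: int = 38
    pathway_size_range: tuple[int, int] = (4, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_accessions": self.n_accessions,
            "n_reps": self.n_reps,
            "n_metabolites": self.n_metabolites,
            "n_lipids": self.n_lipids,
            "n_communities": self.n_communities,
            "n_genes": self.n_genes,
            "planted_module_size": self.planted_module_size,
            "n_pos_pathways": self.n_pos_pathways,
            "n_neg_pathways": self.n_neg_pathways,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if len(self.treatments) < 1:
            raise ValueError("at least one treatment required")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 < self.community_loading <= 1:
            raise ValueError("community_loading must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 < self.planted_module_rho <= 1:
            raise ValueError("planted_module_rho must be in (0, 1]")
        if self.n_metabolites + self.n_lipids < self.n_communities * 2:
            raise ValueError("need at least 2 compounds per community")
        lo, hi = self.pathway_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid pathway_size_range")

    @property
    def n_samples(self) -> int:
        return self.n_accessions * len(self.treatments) * self.n_reps

    @property
    def n_compounds(self) -> int:
        return self.n_metabolites + self.n_lipids


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, for downstream validation."""

    community_of: dict[str, int]
    shifts: dict[str, tuple[str, float]]  # compound -> (design cell, log shift)
    pathway_members: dict[str, frozenset[str]] = field(default_factory=dict)
    positive_ids: set[str] = field(default_factory=set)
    negative_ids: set[str] = field(default_factory=set)
    module_genes: set[str] = field(default_factory=set)
    module_target_pathway: str | None = None

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for comp, c in self.community_of.items():
            out.setdefault(c, []).append(comp)
        return out


def _design_table(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for a in range(1, config.n_accessions + 1):
        for t in config.treatments:
            for r in range(1, config.n_reps + 1):
                rows.append((f"acc{a}", t, r))
    samples = pd.DataFrame(rows, columns=["accession", "treatment", "replicate"])
    samples.index = pd.Index(
        [f"{a}_{t}_{r}" for a, t, r in rows], name="sample"
    )
    return samples


def _assign_communities(config: SyntheticConfig) -> tuple[list[str], pd.Series, dict[str, int]]:
    """Compound ids, class annotations and community labels.

    Defaults mirror one metabolite community plus lipid communities:
    all metabolites go to community 1, lipids split evenly over the rest.
    With a single community everything shares it.
    """
    met_ids = [f"met_{i:03d}" for i in range(1, config.n_metabolites + 1)]
    lip_ids = [f"lip_{i:03d}" for i in range(1, config.n_lipids + 1)]
    classes = pd.Series(
        [_METABOLITE_CLASSES[i % len(_METABOLITE_CLASSES)] for i in range(len(met_ids))]
        + [_LIPID_CLASSES[i % len(_LIPID_CLASSES)] for i in range(len(lip_ids))],
        index=met_ids + lip_ids,
    )
    community_of: dict[str, int] = {}
    if config.n_communities == 1:
        for cid in met_ids + lip_ids:
            community_of[cid] = 1
    else:
        for cid in met_ids:
            community_of[cid] = 1
        n_lipid_comms = config.n_communities - 1
        if config.n_lipids < 2 * n_lipid_comms or config.n_metabolites < 2:
            # fall back to even contiguous blocks over all compounds
            all_ids = met_ids + lip_ids
            bounds = np.linspace(0, len(all_ids), config.n_communities + 1).astype(int)
            for c in range(config.n_communities):
                for cid in all_ids[bounds[c]:bounds[c + 1]]:
                    community_of[cid] = c + 1
        else:
            bounds = np.linspace(0, len(lip_ids), n_lipid_comms + 1).astype(int)
            for c in range(n_lipid_comms):
                for cid in lip_ids[bounds[c]:bounds[c + 1]]:
                    community_of[cid] = c + 2
    sizes = pd.Series(list(community_of.values())).value_counts()
    if (sizes < 2).any():
        raise ValueError("configuration yields a community with fewer than 2 members")
    return met_ids + lip_ids, classes, community_of


def generate_compound_profiles(
    config: SyntheticConfig,
) -> tuple[CompoundMatrix, PlantedTruth]:
    """Generate the natural-scale compound abundance matrix with planted truth.

    A pure function of ``config`` (including its seed): repeated calls give
    byte-identical results.
    """
    rng = np.random.default_rng([config.seed, 11])
    samples = _design_table(config)
    compound_ids, classes, community_of = _assign_communities(config)
    n, p = config.n_samples, config.n_compounds

    factors = rng.standard_normal((n, config.n_communities))
    noise = rng.standard_normal((n, p))
    comm_idx = np.array([community_of[c] - 1 for c in compound_ids])
    log_values = (
        config.community_loading * factors[:, comm_idx]
        + config.noise_sd * noise
    )

    # planted treatment/accession responses: per responsive compound, one
    # design cell is shifted; mild shifts stay below the ANOVA detection
    # floor, strong shifts are large fold changes flagged reliably
    cells = samples["accession"] + ":" + samples["treatment"]
    cell_labels = cells.unique()
    n_responsive = int(round(_RESPONSIVE_FRACTION * p))
    responsive = rng.choice(p, size=n_responsive, replace=False)
    shifts: dict[str, tuple[str, float]] = {}
    for k, j in enumerate(sorted(responsive)):
        strong = k % 3 == 2
        lo, hi = _STRONG_SHIFT_RANGE if strong else _MILD_SHIFT_RANGE
        delta = rng.uniform(lo, hi) * config.noise_sd * rng.choice([-1.0, 1.0])
        if strong:
            treatment = rng.choice(np.asarray(config.treatments))
            hit = (samples["treatment"] == treatment).to_numpy()
            cell = f"*:{treatment}"
        else:
            cell = str(rng.choice(cell_labels))
            hit = cells.to_numpy() == cell
        log_values[:, j] += np.where(hit, delta, 0.0)
        shifts[compound_ids[j]] = (cell, float(delta))

    values = np.exp(log_values)

    n_missing = int(config.missing_rate * n * p)  # whole cells only
    if n_missing:
        flat = rng.choice(n * p, size=n_missing, replace=False)
        values.flat[flat] = np.nan

    matrix = CompoundMatrix(
        pd.DataFrame(values, index=samples.index, columns=compound_ids),
        samples,
        classes,
    )
    return matrix, PlantedTruth(community_of=community_of, shifts=shifts)


def generate_pathway_db(
    config: SyntheticConfig, truth: PlantedTruth
) -> list[PathwayDefinition]:
    """Plant labelled training pathways and record them in ``truth``.

    Positives are compound subsets concentrated inside single planted
    communities ("active" pathways whose members co-fluctuate). Negatives
    split in half: random subsets spanning the whole compound universe, and
    deliberately low-connectivity sets built round-robin across communities.
    """
    rng = np.random.default_rng([config.seed, 23])
    communities = truth.communities()
    universe = sorted(truth.community_of)
    lo, hi = config.pathway_size_range
    if hi > len(universe):
        raise ValueError("pathway_size_range exceeds compound universe")

    pathways: list[PathwayDefinition] = []
    for i in range(1, config.n_pos_pathways + 1):
        comm = communities[rng.choice(sorted(communities))]
        size = min(int(rng.integers(lo, hi + 1)), len(comm))
        members = frozenset(rng.choice(comm, size=size, replace=False))
        pathways.append(
            PathwayDefinition(
                id=f"pos_{i:03d}",
                name=f"planted active pathway {i}",
                members=members,
                label="positive",
            )
        )

    n_random = config.n_neg_pathways // 2
    n_spread = config.n_neg_pathways - n_random
    for i in range(1, n_random + 1):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(universe, size=size, replace=False))
        pathways.append(
            PathwayDefinition(
                id=f"negr_{i:03d}",
                name=f"random compound set {i}",
                members=members,
                label="negative",
            )
        )
    comm_keys = sorted(communities)
    for i in range(1, n_spread + 1):
        size = int(rng.integers(lo, hi + 1))
        picked: set[str] = set()
        k = int(rng.integers(0, len(comm_keys)))
        while len(picked) < size:
            comm = communities[comm_keys[k % len(comm_keys)]]
            cand = comm[int(rng.integers(0, len(comm)))]
            picked.add(cand)
            k += 1
        pathways.append(
            PathwayDefinition(
                id=f"negl_{i:03d}",
                name=f"cross-community set {i}",
                members=frozenset(picked),
                label="negative",
            )
        )

    truth.pathway_members = {pw.id: pw.members for pw in pathways}
    truth.positive_ids = {pw.id for pw in pathways if pw.label == "positive"}
    truth.negative_ids = {pw.id for pw in pathways if pw.label == "negative"}
    return pathways


def sample_community_pathways(
    truth: PlantedTruth,
    n: int,
    size_range: tuple[int, int],
    seed: int,
    prefix: str = "test_pos",
) -> list[PathwayDefinition]:
    """Draw fresh single-community compound sets (held-out planted positives)."""
    rng = np.random.default_rng(seed)
    communities = truth.communities()
    lo, hi = size_range
    out = []
    for i in range(1, n + 1):
        comm = communities[rng.choice(sorted(communities))]
        size = min(int(rng.integers(lo, hi + 1)), len(comm))
        members = frozenset(rng.choice(comm, size=size, replace=False))
        out.append(
            PathwayDefinition(f"{prefix}_{i:03d}", f"held-out active set {i}",
                              members, label="positive")
        )
    return out


def sample_random_subsets(
    truth: PlantedTruth,
    n: int,
    size_range: tuple[int, int],
    seed: int,
    prefix: str = "test_rand",
) -> list[PathwayDefinition]:
    """Draw fresh uniform random compound subsets (held-out negatives)."""
    rng = np.random.default_rng(seed)
    universe = sorted(truth.community_of)
    lo, hi = size_range
    out = []
    for i in range(1, n + 1):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(universe, size=size, replace=False))
        out.append(
            PathwayDefinition(f"{prefix}_{i:03d}", f"held-out random set {i}",
                              members, label="negative")
        )
    return out


def generate_expression_profiles(
    config: SyntheticConfig,
    compounds: CompoundMatrix,
    truth: PlantedTruth,
) -> ExpressionMatrix:
    """Generate normalised expression with one planted gene module.

    The module's genes are noisy affine copies of the target pathway's
    compound PC1. The per-gene noise scale is calibrated by bisection
    against the actually drawn noise so the realised
    |cor(PC1(module), PC1(pathway))| matches ``planted_module_rho`` closely
    (a closed-form calibration fails here: with far fewer samples than
    module genes the sample PC1 loses a weak planted factor entirely).
    Background genes are independent log-normal noise. All values are
    nonnegative.
    """
    if truth.module_target_pathway is None:
        if not truth.positive_ids:
            raise ValueError(
                "generate_pathway_db must run before expression generation"
            )
        truth.module_target_pathway = sorted(truth.positive_ids)[0]
    target = truth.pathway_members[truth.module_target_pathway]

    rng = np.random.default_rng([config.seed, 37])
    n = compounds.n_samples
    if config.planted_module_size > config.n_genes:
        raise ValueError("planted_module_size exceeds n_genes")

    sub = np.log(compounds.values[sorted(target)].to_numpy(dtype=float))
    col_means = np.nanmean(sub, axis=0)
    holes = np.isnan(sub)
    sub[holes] = np.broadcast_to(col_means, sub.shape)[holes]
    centered = sub - sub.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    z = u[:, 0] * s[0]
    z = z / z.std(ddof=0)

    m = config.planted_module_size
    rho = config.planted_module_rho

    gene_ids = [f"gene_{i:05d}" for i in range(1, config.n_genes + 1)]
    module_idx = rng.choice(config.n_genes, size=m, replace=False)
    values = np.empty((n, config.n_genes))
    background = np.exp(rng.normal(loc=2.0, scale=1.0, size=(n, config.n_genes)))
    values[:] = background
    scales = np.exp(rng.normal(scale=0.25, size=m))
    eps = rng.standard_normal((n, m))

    def realized(tau: float) -> float:
        mod = scales * (z[:, None] + tau * eps)
        modc = mod - mod.mean(axis=0)
        uu, ss, _ = np.linalg.svd(modc, full_matrices=False)
        score = uu[:, 0]
        return float(abs(np.corrcoef(score, z)[0, 1]))

    if rho >= 1.0:
        tau = 0.0
    else:
        lo, hi = 0.0, 1.0
        while realized(hi) > rho and hi < 1e4:
            hi *= 2.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if realized(mid) > rho:
                lo = mid
            else:
                hi = mid
        tau = 0.5 * (lo + hi)
    values[:, module_idx] = scales * (z[:, None] + tau * eps)

    floor = values.min()
    if floor < 0:
        values = values - floor  # global affine shift, correlations unchanged

    truth.module_genes = {gene_ids[i] for i in module_idx}
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=compounds.values.index, columns=gene_ids),
        compounds.samples.copy(),
    )
    return expr


def simulate_study(
    config: SyntheticConfig,
) -> tuple[CompoundMatrix, ExpressionMatrix, list[PathwayDefinition], PlantedTruth]:
    """Run the full generator: compounds, pathway database, expression."""
    compounds, truth = generate_compound_profiles(config)
    pathways = generate_pathway_db(config, truth)
    expression = generate_expression_profiles(config, compounds, truth)
    return compounds, expression, pathways, truth
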