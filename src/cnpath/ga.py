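"""Genetic algorithm linking gene expression to pathway metabolite profiles.

The objective is ARGMAX over gene subsets C of

    |cor( PC1(Expr[:, C]), PC1(Pr[:, M]) )|

where Expr is the normalised expression matrix, Pr the processed (log,
imputed) compound matrix, M the compound set of a metabolic pathway, PC1
the first principal component of a centred (unscaled) matrix and cor the
Pearson correlation. Negative correlations count through the absolute
value. A binary-chromosome GA with tournament selection, uniform
crossover, per-bit mutation and elitism searches the subset space; an
optional per-gene penalty presses toward small, interpretable gene sets
(set it to 0 for the pure ARGMAX).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datatypes import CompoundMatrix, ExpressionMatrix
from .preprocess import pca


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    generations: int = 200
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # None -> 1 / n_candidate_genes
    tournament_size: int = 3
    elitism_count: int = 2
    init_rate: float = 0.05
    target_subset_penalty: float = 0.0005  # fitness cost per selected gene
    stagnation_patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        for name in ("crossover_rate", "init_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.target_subset_penalty < 0:
            raise ValueError("target_subset_penalty must be >= 0")


@dataclass
class GAResult:
    genes: set[str]
    objective: float
    fitness_trajectory: list[float]
    config: GAConfig
    n_generations: int

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("GA returned an empty gene set")


def _as_frame(obj) -> pd.DataFrame:
    return obj.values if hasattr(obj, "values") and not isinstance(obj, pd.DataFrame) else pd.DataFrame(obj)


def ga_objective(
    expr: ExpressionMatrix | pd.DataFrame,
    genes,
    compounds: CompoundMatrix | pd.DataFrame,
    members,
) -> float:
    """|Pearson cor| between PC1 of the gene subset and PC1 of the pathway.

    Both PC1s use the package's centred, unscaled PCA; the absolute value
    makes the result invariant to PC sign flips. Raises on zero-variance
    (constant) subsets.
    """
    expr_vals = _as_frame(expr)
    comp_vals = _as_frame(compounds)
    genes = sorted(set(genes))
    members = sorted(set(members))
    if not genes or not members:
        raise ValueError("gene subset and compound subset must be non-empty")
    if expr_vals.shape[0] != comp_vals.shape[0]:
        raise ValueError("sample rows of Expr and Pr are not aligned")
    if expr_vals.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    g_scores = pca(expr_vals[genes], n_components=1).pc1().to_numpy()
    m_scores = pca(comp_vals[members], n_components=1).pc1().to_numpy()
    return float(abs(np.corrcoef(g_scores, m_scores)[0, 1]))


def _pc1_scores(Xc: np.ndarray) -> np.ndarray:
    """PC1 score vector of an already column-centred matrix (sign-arbitrary)."""
    gram = Xc @ Xc.T
    w, v = np.linalg.eigh(gram)
    return v[:, -1] * np.sqrt(max(w[-1], 0.0))


class _Engine:
    """Shared GA core maximizing |cor(PC1(Expr[:, C]), target)|."""

    def __init__(self, expr_vals: pd.DataFrame, target: np.ndarray,
                 candidates: list[str], config: GAConfig):
        if len(candidates) < 2:
            raise ValueError("need at least 2 candidate genes")
        self.candidates = list(candidates)
        self.config = config
        self.Xc = expr_vals[self.candidates].to_numpy(dtype=float)
        self.Xc = self.Xc - self.Xc.mean(axis=0)
        t = np.asarray(target, dtype=float)
        self.target = t - t.mean()
        if self.target.std() == 0:
            raise ValueError("target score vector is constant")
        self._cache: dict[bytes, float] = {}

    def objective(self, chromosome: np.ndarray) -> float:
        key = chromosome.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        sub = self.Xc[:, chromosome]
        if not np.any(sub):
            val = 0.0  # constant subset: no signal
        else:
            s = _pc1_scores(sub)
            denom = s.std() * self.target.std()
            val = 0.0 if denom == 0 else float(
                abs(np.dot(s - s.mean(), self.target) / (len(s) * denom))
            )
        self._cache[key] = val
        return val

    def fitness(self, chromosome: np.ndarray) -> float:
        return self.objective(chromosome) - (
            self.config.target_subset_penalty * int(chromosome.sum())
        )

    def run(self) -> tuple[np.ndarray, list[float], int]:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n = len(self.candidates)
        mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n

        pop = rng.random((cfg.population_size, n)) < cfg.init_rate
        for ch in pop:
            if not ch.any():
                ch[rng.integers(n)] = True
        fits = np.array([self.fitness(ch) for ch in pop])

        best_idx = int(np.argmax(fits))
        best, best_fit = pop[best_idx].copy(), float(fits[best_idx])
        trajectory = [best_fit]
        stagnant = 0
        gen = 0
        for gen in range(1, cfg.generations + 1):
            order = np.argsort(-fits)
            elite = pop[order[: cfg.elitism_count]].copy()
            children = list(elite)
            while len(children) < cfg.population_size:
                p1 = self._tournament(pop, fits, rng)
                p2 = self._tournament(pop, fits, rng)
                if rng.random() < cfg.crossover_rate:
                    mask = rng.random(n) < 0.5
                    c1 = np.where(mask, p1, p2)
                    c2 = np.where(mask, p2, p1)
                else:
                    c1, c2 = p1.copy(), p2.copy()
                for c in (c1, c2):
                    flips = rng.random(n) < mut
                    c ^= flips
                    if not c.any():
                        c[rng.integers(n)] = True
                    children.append(c)
            pop = np.array(children[: cfg.population_size])
            fits = np.array([self.fitness(ch) for ch in pop])
            gen_best = int(np.argmax(fits))
            if fits[gen_best] > best_fit + 1e-15:
                best, best_fit = pop[gen_best].copy(), float(fits[gen_best])
                stagnant = 0
            else:
                stagnant += 1
            trajectory.append(best_fit)
            if stagnant >= cfg.stagnation_patience:
                break
        return best, trajectory, gen

    def _tournament(self, pop, fits, rng) -> np.ndarray:
        idx = rng.integers(len(pop), size=self.config.tournament_size)
        return pop[idx[np.argmax(fits[idx])]].copy()


def run_ga(
    expr: ExpressionMatrix | pd.DataFrame,
    compounds: CompoundMatrix | pd.DataFrame,
    members,
    config: GAConfig = GAConfig(),
    candidate_genes=None,
) -> GAResult:
    """Optimize the gene subset for one pathway's compound set.

    ``candidate_genes`` restricts the search space (e.g. to one
    co-expression module); by default every gene is a candidate. The
    returned objective is re-evaluated through :func:`ga_objective` on the
    winning subset, so it is exactly the quantity the equation defines.
    """
    expr_vals = _as_frame(expr)
    comp_vals = _as_frame(compounds)
    candidates = (
        list(expr_vals.columns) if candidate_genes is None
        else [g for g in expr_vals.columns if g in set(candidate_genes)]
    )
    members = sorted(set(members))
    target = pca(comp_vals[members], n_components=1).pc1().to_numpy()
    engine = _Engine(expr_vals, target, candidates, config)
    best, trajectory, n_gen = engine.run()
    genes = {c for c, on in zip(candidates, best) if on}
    objective = ga_objective(expr_vals, genes, comp_vals, members)
    if abs(objective - engine.objective(best)) > 1e-8:
        raise AssertionError("objective re-evaluation mismatch")
    return GAResult(genes, objective, trajectory, config, n_gen)


def exhaustive_best_subset(
    expr: ExpressionMatrix | pd.DataFrame,
    compounds: CompoundMatrix | pd.DataFrame,
    members,
    candidate_genes,
    penalty: float = 0.0,
) -> tuple[set[str], float]:
    """Enumerate every non-empty candidate subset (oracle for small spaces)."""
    expr_vals = _as_frame(expr)
    candidates = list(candidate_genes)
    if len(candidates) > 20:
        raise ValueError("exhaustive enumeration limited to 20 candidates")
    best_genes: set[str] = set()
    best_fit = -np.inf
    best_obj = 0.0
    for mask in range(1, 2 ** len(candidates)):
        genes = {candidates[i] for i in range(len(candidates)) if mask >> i & 1}
        obj = ga_objective(expr_vals, genes, compounds, members)
        fit = obj - penalty * len(genes)
        if fit > best_fit:
            best_genes, best_fit, best_obj = genes, fit, obj
    return best_genes, best_obj


class GeneSubsetSelector(BaseEstimator):
    """sklearn-style selector: genes whose PC1 tracks a target score vector.

    ``fit(X, y)`` takes a samples x genes expression table and a target
    score vector (typically the PC1 of a pathway's compound profiles) and
    runs the GA. Fitted attributes: ``support_`` (boolean mask over
    columns), ``gene_ids_``, ``objective_``, ``trajectory_``.
    """

    def __init__(
        self,
        population_size: int = 100,
        generations: int = 200,
        crossover_rate: float = 0.8,
        mutation_rate: float | None = None,
        tournament_size: int = 3,
        elitism_count: int = 2,
        target_subset_penalty: float = 0.0005,
        stagnation_patience: int = 30,
        random_state: int = 0,
    ):
        self.population_size = population_size
        self.generations = generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.tournament_size = tournament_size
        self.elitism_count = elitism_count
        self.target_subset_penalty = target_subset_penalty
        self.stagnation_patience = stagnation_patience
        self.random_state = random_state

    def _config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            tournament_size=self.tournament_size,
            elitism_count=self.elitism_count,
            target_subset_penalty=self.target_subset_penalty,
            stagnation_patience=self.stagnation_patience,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X = pd.DataFrame(X)
        engine = _Engine(X, np.asarray(y, dtype=float), list(X.columns),
                         self._config())
        best, trajectory, _ = engine.run()
        self.support_ = np.asarray(best, dtype=bool)
        self.gene_ids_ = [c for c, on in zip(X.columns, best) if on]
        self.objective_ = engine.objective(best)
        self.trajectory_ = trajectory
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        return pd.DataFrame(X).loc[:, self.support_]
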