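"""Transformation, imputation and univariate screening of compound tables.

The processing order is: natural-log transform, iterative low-rank (SVD)
imputation of missing cells, one-factor ANOVA per compound over the
accession x treatment design cells with Bonferroni correction, Tukey HSD
post-hoc tests summarised as compact letter displays, and centred
(unscaled) PCA. The PCA conventions here (centre, no scaling, sign fixed so
each loading column's largest-magnitude entry is positive) are shared by
every PC1 used elsewhere in the package, including the gene-module
objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import CompoundMatrix


# ---------------------------------------------------------------------------
# log transform

def log_transform(matrix: CompoundMatrix) -> CompoundMatrix:
    """Natural-log transform every observed value; missing cells untouched."""
    vals = matrix.values
    bad = (vals <= 0) & vals.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        cell = (vals.index[rows[0]], vals.columns[cols[0]])
        raise ValueError(f"nonpositive value at sample={cell[0]!r}, compound={cell[1]!r}")
    return matrix.copy_with(np.log(vals))


# ---------------------------------------------------------------------------
# imputation

class SVDImputer(BaseEstimator, TransformerMixin):
    """Iterative rank-k SVD completion of missing values.

    Missing cells start at their column means; the matrix is then
    alternately reconstructed at rank ``n_components`` and the missing cells
    replaced by the reconstruction, until the largest change in an imputed
    cell falls below ``tol`` or ``max_iter`` is reached. Observed cells are
    never altered.

    Parameters
    ----------
    n_components : rank of the reconstruction (default 3).
    max_iter : iteration cap (default 200).
    tol : convergence threshold on imputed-cell change (default 1e-6).
    """

    def __init__(self, n_components: int = 3, max_iter: int = 200, tol: float = 1e-6):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        self.n_features_in_ = X.shape[1]
        self.n_iter_ = 0
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        arr = np.asarray(X, dtype=float).copy()
        mask = np.isnan(arr)
        if not mask.any():
            return arr
        if mask.all(axis=0).any():
            j = int(np.nonzero(mask.all(axis=0))[0][0])
            raise ValueError(f"column {j} is entirely missing; cannot impute")
        if mask.mean(axis=0).max() >= 0.5:
            j = int(np.argmax(mask.mean(axis=0)))
            raise ValueError(f"column {j} is >= 50% missing; refusing to impute")
        col_means = np.nanmean(arr, axis=0)
        arr[mask] = np.broadcast_to(col_means, arr.shape)[mask]
        k = min(self.n_components, min(arr.shape) - 1) if min(arr.shape) > 1 else 1
        for it in range(self.max_iter):
            mu = arr.mean(axis=0)
            u, s, vt = np.linalg.svd(arr - mu, full_matrices=False)
            recon = (u[:, :k] * s[:k]) @ vt[:k] + mu
            delta = np.abs(recon[mask] - arr[mask]).max()
            arr[mask] = recon[mask]
            if delta < self.tol:
                break
        self.n_iter_ = it + 1
        return arr

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


def impute_missing(
    matrix: CompoundMatrix,
    n_components: int = 3,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> CompoundMatrix:
    """Impute missing cells of a (log-transformed) compound matrix."""
    imputer = SVDImputer(n_components=n_components, max_iter=max_iter, tol=tol)
    filled = imputer.fit_transform(matrix.values.to_numpy())
    return matrix.copy_with(
        pd.DataFrame(filled, index=matrix.values.index, columns=matrix.values.columns)
    )


# ---------------------------------------------------------------------------
# ANOVA + Bonferroni

@dataclass(frozen=True)
class AnovaResult:
    compound: str
    f_statistic: float
    p_value: float
    p_adjusted: float
    significant: bool


def anova_bonferroni(matrix: CompoundMatrix, alpha: float = 0.05) -> list[AnovaResult]:
    """One-factor ANOVA per compound over accession x treatment cells.

    p-values are Bonferroni-adjusted over all compounds tested; a compound
    is significant when its adjusted p is at most ``alpha``. Degenerate
    compounds (all group means equal with zero within-group variance) get
    F = 0, p = 1.
    """
    groups = matrix.groups()
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need at least 2 design cells for ANOVA")
    idx = {g: np.nonzero((groups == g).to_numpy())[0] for g in labels}
    if min(len(v) for v in idx.values()) < 2:
        raise ValueError("need at least 2 replicates per design cell")
    if matrix.values.isna().to_numpy().any():
        raise ValueError("impute missing values before ANOVA")

    n_tests = matrix.values.shape[1]
    results = []
    for compound in matrix.values.columns:
        col = matrix.values[compound].to_numpy()
        cells = [col[i] for i in idx.values()]
        means = [c.mean() for c in cells]
        ss_within = sum(((c - c.mean()) ** 2).sum() for c in cells)
        if np.ptp(means) == 0.0:
            f, p = 0.0, 1.0
        elif ss_within == 0.0:
            f, p = np.inf, 0.0
        else:
            f, p = stats.f_oneway(*cells)
        p_adj = min(1.0, float(p) * n_tests)
        results.append(
            AnovaResult(compound, float(f), float(p), p_adj, p_adj <= alpha)
        )
    return results


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound": [r.compound for r in results],
            "F": [r.f_statistic for r in results],
            "p": [r.p_value for r in results],
            "p_bonferroni": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
        }
    ).set_index("compound")


# ---------------------------------------------------------------------------
# Tukey HSD + compact letter display

@dataclass(frozen=True)
class TukeyGroups:
    compound: str
    group_means: dict[str, float]
    letters: dict[str, str]
    nonsignificant_pairs: frozenset[frozenset]


def _compact_letters(
    order: list[str], nonsig: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``order`` lists groups sorted by mean (ascending); two groups may share
    a letter only if their pair is in ``nonsig``. Each letter set is a
    maximal clique of the non-significance graph covering every group.
    """
    columns: list[set[str]] = [set(order)]
    for a_i, a in enumerate(order):
        for b in order[a_i + 1:]:
            if frozenset((a, b)) in nonsig:
                continue
            new_columns: list[set[str]] = []
            for col in columns:
                if a in col and b in col:
                    col_a = col - {b}
                    col_b = col - {a}
                    new_columns.extend([col_a, col_b])
                else:
                    new_columns.append(col)
            # absorb: drop columns contained in another
            columns = []
            for col in new_columns:
                if any(col < other for other in new_columns if other is not col) or any(
                    col == other for other in columns
                ):
                    continue
                columns.append(col)
    # stable letter assignment: order columns by first member in mean order
    pos = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda col: min(pos[g] for g in col))
    letters = {g: "" for g in order}
    for i, col in enumerate(columns):
        ch = chr(ord("a") + i) if i < 26 else f"z{i}"
        for g in order:
            if g in col:
                letters[g] += ch
    return letters


def tukey_cld(
    matrix: CompoundMatrix, compound: str, alpha: float = 0.05
) -> TukeyGroups:
    """Tukey HSD over design cells with a compact letter display.

    Two design cells share a letter iff their pairwise Tukey test is
    non-significant at ``alpha``. Groups are sorted by mean (ascending)
    before lettering, so "a" marks the lowest-mean clique.
    """
    groups = matrix.groups()
    labels = list(groups.unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for Tukey HSD")
    col = matrix.values[compound]
    if col.isna().any():
        raise ValueError("impute missing values before Tukey HSD")
    samples = [col.to_numpy()[(groups == g).to_numpy()] for g in labels]
    res = stats.tukey_hsd(*samples)
    nonsig: set[frozenset] = set()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if res.pvalue[i, j] > alpha:
                nonsig.add(frozenset((labels[i], labels[j])))
    means = {g: float(s.mean()) for g, s in zip(labels, samples)}
    order = sorted(labels, key=lambda g: (means[g], labels.index(g)))
    letters = _compact_letters(order, nonsig)
    return TukeyGroups(compound, means, letters, frozenset(nonsig))


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PcaResult:
    """Centred, unscaled PCA with a deterministic sign convention."""

    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # variables x components, unit-norm columns
    explained_variance_ratio: np.ndarray
    column_means: pd.Series

    def pc1(self) -> pd.Series:
        return self.scores.iloc[:, 0]


def pca(table: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """Centred (not scaled) PCA via SVD.

    Sign convention: in each loading column the entry of largest magnitude
    is made positive, so results are reproducible across SVD backends.
    """
    X = np.asarray(table, dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA input must be complete")
    k_max = min(X.shape)
    k = k_max if n_components is None else n_components
    if not 1 <= k <= k_max:
        raise ValueError(f"n_components must be in [1, {k_max}]")
    mu = X.mean(axis=0)
    Xc = X - mu
    total_var = (Xc**2).sum()
    if total_var == 0:
        raise ValueError("constant matrix: zero total variance")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # sign fix on loading columns
    for j in range(len(s)):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    comp = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((u[:, :k] * s[:k]), index=table.index, columns=comp)
    loadings = pd.DataFrame(vt[:k].T, index=table.columns, columns=comp)
    evr = (s**2) / total_var
    return PcaResult(scores, loadings, evr[:k], pd.Series(mu, index=table.columns))


def top_variable_columns(table: pd.DataFrame, n: int = 500) -> pd.DataFrame:
    """Keep the ``n`` highest-variance columns (e.g. most variable genes)."""
    variances = table.var(axis=0, ddof=1)
    keep = variances.sort_values(ascending=False).index[:n]
    return table[keep]
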