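"""Exploratory statistics: correlation structure and PCA.

Two preliminary views of the matrix before integration:

* a Spearman correlation matrix over all variable pairs, computed on
  pairwise-complete observations, with columns arranged by the angular
  order of the eigenvectors (AOE) so that correlated groups of variables
  sit next to each other;
* a principal component analysis fitted with NIPALS, the iterative
  alternating-regression algorithm that tolerates missing cells, with
  loadings and the fraction of variance each component explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import OmicsMatrix

NIPALS_TOL = 1e-6
NIPALS_MAX_ITER = 500


@dataclass
class CorrelationResult:
    corr: np.ndarray          # (p, p), symmetric, unit diagonal
    n_pairs: np.ndarray       # (p, p) pairwise non-missing counts
    order: np.ndarray         # permutation of 0..p-1
    variable_names: list[str]


@dataclass
class PcaModel:
    loadings: np.ndarray      # (p, H), unit-norm columns
    scores: np.ndarray        # (n, H)
    explained_variance_fraction: np.ndarray  # (H,)
    n_iterations: list[int]
    variable_names: list[str]
    gene_ids: list[str]


def spearman_matrix(m: OmicsMatrix, min_pairs: int = 3) -> CorrelationResult:
    """Spearman correlation between every pair of variables.

    Each pair uses the rows where both variables are observed, with
    average ranks for ties (i.e. Pearson correlation of mid-ranks on the
    pairwise-complete subset). Pairs with fewer than ``min_pairs``
    complete rows are rejected.
    """
    X = m.values
    p = m.n_variables
    present = ~np.isnan(X)
    corr = np.eye(p)
    n_pairs = np.empty((p, p), dtype=int)
    np.fill_diagonal(n_pairs, present.sum(axis=0))
    for i in range(p):
        for j in range(i + 1, p):
            both = present[:, i] & present[:, j]
            n = int(both.sum())
            n_pairs[i, j] = n_pairs[j, i] = n
            if n < min_pairs:
                raise ValueError(
                    f"variables {m.variables[i].name!r} and {m.variables[j].name!r} "
                    f"share only {n} complete rows (need >= {min_pairs})"
                )
            rho = stats.spearmanr(X[both, i], X[both, j]).statistic
            corr[i, j] = corr[j, i] = rho
    order = aoe_order(corr)
    return CorrelationResult(corr, n_pairs, order, m.variable_names)


def aoe_order(corr: np.ndarray | CorrelationResult) -> np.ndarray:
    """Angular order of the eigenvectors.

    Project every variable onto the plane of the correlation matrix's two
    leading eigenvectors, take its angle atan2(e2_i, e1_i) mapped into
    [0, 2*pi), and sort ascending (ties broken by original index). With
    fewer than two variables the identity permutation is returned.
    """
    C = corr.corr if isinstance(corr, CorrelationResult) else np.asarray(corr, float)
    p = C.shape[0]
    if p < 2:
        return np.arange(p)
    # a diagonal matrix has no angular structure: keep the input order
    if np.abs(C - np.diag(np.diag(C))).max() < 1e-12:
        return np.arange(p)
    eigval, eigvec = np.linalg.eigh(C)  # ascending
    e1, e2 = eigvec[:, -1], eigvec[:, -2]
    angles = np.mod(np.arctan2(e2, e1), 2 * np.pi)
    return np.argsort(angles, kind="stable")


def pca_nipals(m: OmicsMatrix, n_components: int = 2,
               tol: float = NIPALS_TOL, max_iter: int = NIPALS_MAX_ITER) -> PcaModel:
    """PCA by NIPALS, skipping missing cells in every inner regression.

    Expects a centered and scaled matrix. Each component alternates
    score/loading least-squares updates over observed cells until the
    score vector stabilises, then deflates the observed cells. On complete
    data the result coincides with SVD-based PCA up to sign; the sign is
    fixed so the largest-|loading| entry of each component is positive.
    """
    X = m.values.copy()
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError(f"n_components {n_components} exceeds min(n, p) = {min(n, p)}")
    present = ~np.isnan(X)
    X0 = np.where(present, X, 0.0)
    total_ss = float((X0 ** 2).sum())
    if total_ss == 0:
        raise ValueError("matrix has zero total sum of squares")

    loadings = np.zeros((p, n_components))
    scores = np.zeros((n, n_components))
    evf = np.zeros(n_components)
    iters: list[int] = []
    R = np.where(present, X, 0.0)  # residual, zeros at missing cells

    for h in range(n_components):
        ss_before = float((R ** 2).sum())
        t = R[:, int(np.argmax((R ** 2).sum(axis=0)))].copy()
        if not np.any(t):
            raise ValueError(f"residual rank exhausted before component {h + 1}")
        converged = False
        for it in range(1, max_iter + 1):
            # p_j = sum_i r_ij t_i / sum_{i: obs ij} t_i^2
            denom_p = present.T @ (t ** 2)
            with np.errstate(invalid="ignore", divide="ignore"):
                a = np.where(denom_p > 0, (R.T @ t) / denom_p, 0.0)
            norm_a = np.linalg.norm(a)
            if norm_a == 0:
                raise ValueError(f"degenerate loading in component {h + 1}")
            a /= norm_a
            denom_t = present @ (a ** 2)
            with np.errstate(invalid="ignore", divide="ignore"):
                t_new = np.where(denom_t > 0, (R @ a) / denom_t, 0.0)
            delta = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
            t = t_new
            if delta < tol:
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"NIPALS did not converge for component {h + 1} "
                f"within {max_iter} iterations (last relative change {delta:.2e})"
            )
        # sign: largest-|a| entry positive
        k = int(np.argmax(np.abs(a)))
        if a[k] < 0:
            a, t = -a, -t
        loadings[:, h], scores[:, h] = a, t
        iters.append(it)
        R = np.where(present, R - np.outer(t, a), 0.0)
        evf[h] = (ss_before - float((R ** 2).sum())) / total_ss

    return PcaModel(loadings, scores, evf, iters, m.variable_names, list(m.gene_ids))
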