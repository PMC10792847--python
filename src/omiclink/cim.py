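"""Denoising and clustered image maps for multi-block PLS fits.

"Denoising" keeps, for every block, only the part of the data explained
by the block's latent variates: X_hat = T (T'T)^{-1} T' X, the orthogonal
projection of the block onto the span of its variates (equal to the
components-times-regression-loadings product, since own-variate deflation
makes the variates orthogonal). The residual R = X - X_hat collects the
variability specific to single genes or single variables; X_hat + R
reconstructs X exactly.

The clustered image map (CIM) concatenates the blocks, optionally after
denoising, re-centering/scaling ('scale2') and clamping into [-2, 2]
('cutoff'), and orders genes and variables by hierarchical clustering
with Euclidean distance and Ward linkage. Cutting the gene dendrogram
into k groups yields gene typologies whose per-variable mean profiles
summarise the methylation-expression interplay of each group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .block_pls import BlockPlsModel
from .datamodel import BlockSet, OmicsMatrix


@dataclass
class CimOptions:
    denoise: bool = True
    scale2: bool = True
    cutoff: bool = True
    k_groups: int = 4

    def __post_init__(self) -> None:
        if self.k_groups < 1:
            raise ValueError("k_groups must be >= 1")


@dataclass
class CimResult:
    matrix: OmicsMatrix                  # transformed, original row/col order
    row_order: np.ndarray                # leaf order of the gene dendrogram
    col_order: np.ndarray                # leaf order of the variable dendrogram
    row_tree: np.ndarray                 # scipy linkage matrices
    col_tree: np.ndarray
    clusters: pd.Series                  # gene_id -> group in 1..k
    options: CimOptions

    def ordered_frame(self) -> pd.DataFrame:
        df = self.matrix.to_frame()
        return df.iloc[self.row_order, self.col_order]


def denoise(bs: BlockSet, model: BlockPlsModel) -> tuple[BlockSet, BlockSet]:
    """Split every block into its variate-span projection and residual.

    Returns ``(denoised, residuals)`` with ``denoised + residuals``
    reconstructing the input exactly. Blocks must be complete.
    """
    if bs.gene_ids != model.gene_ids:
        raise ValueError("model was fitted on different genes than the block set")
    den: dict[str, OmicsMatrix] = {}
    res: dict[str, OmicsMatrix] = {}
    for name, b in bs:
        if np.isnan(b.values).any():
            raise ValueError(f"block {name!r} contains missing values")
        T = model.variates[name]
        gram = T.T @ T
        if np.linalg.matrix_rank(gram) < gram.shape[0]:
            raise np.linalg.LinAlgError(
                f"variates of block {name!r} are rank deficient; cannot project"
            )
        X = b.values
        X_hat = T @ np.linalg.solve(gram, T.T @ X)
        den[name] = b.with_values(X_hat)
        res[name] = b.with_values(X - X_hat)
    return BlockSet(den), BlockSet(res)


def _center_scale_array(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    if (std == 0).any():
        raise ValueError("zero-variance column after denoising; cannot re-scale")
    return (X - mean) / std


def transform_blocks(bs: BlockSet, model: BlockPlsModel | None, opt: CimOptions) -> BlockSet:
    """Apply the CIM transforms in fixed order: denoise -> scale2 -> cutoff."""
    out = bs
    if opt.denoise:
        if model is None:
            raise ValueError("denoise=True requires a fitted model")
        out, _ = denoise(out, model)
    if opt.scale2:
        out = out.map_values(_center_scale_array)
    if opt.cutoff:
        out = out.map_values(lambda X: np.clip(X, -2.0, 2.0))
    return out


def ward_linkage(X: np.ndarray) -> np.ndarray:
    """Ward agglomeration on Euclidean distances between the rows of X."""
    return hierarchy.linkage(pdist(X, metric="euclidean"), method="ward")


def cut_tree_k(tree: np.ndarray, k: int, n_leaves: int) -> np.ndarray:
    """Cut a dendrogram into exactly k groups, labelled 1..k by first
    appearance in leaf-index order."""
    raw = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        raise ValueError(f"cannot cut tree of {n_leaves} leaves into {k} groups")
    relabel: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return labels


def build_cim(
    bs: BlockSet, model: BlockPlsModel | None = None, opt: CimOptions | None = None
) -> CimResult:
    """Clustered image map of the (transformed) concatenated blocks."""
    opt = opt or CimOptions()
    transformed = transform_blocks(bs, model, opt)
    m = transformed.concatenate()
    if opt.k_groups > m.n_genes:
        raise ValueError(f"k_groups {opt.k_groups} exceeds {m.n_genes} genes")
    if np.isnan(m.values).any():
        raise ValueError("CIM input contains missing values")

    row_tree = ward_linkage(m.values)
    col_tree = ward_linkage(m.values.T)
    row_order = hierarchy.leaves_list(row_tree)
    col_order = hierarchy.leaves_list(col_tree)
    labels = cut_tree_k(row_tree, opt.k_groups, m.n_genes)
    clusters = pd.Series(labels, index=pd.Index(m.gene_ids, name="gene_id"), name="group")
    return CimResult(m, row_order, col_order, row_tree, col_tree, clusters, opt)


def cluster_profiles(res: CimResult) -> pd.DataFrame:
    """Mean transformed value per gene group and variable.

    Rows are the k groups (with an ``n_genes`` size column), columns the
    variables, on the same transformed scale as the heatmap.
    """
    df = res.matrix.to_frame()
    grouped = df.groupby(res.clusters.to_numpy())
    profiles = grouped.mean()
    profiles.index.name = "group"
    profiles.insert(0, "n_genes", grouped.size())
    return profiles
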