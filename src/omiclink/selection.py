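"""Master-driver candidate selection and denoised/raw comparison.

A "master driver" is a gene whose methylation-expression interplay holds
in every population: on the standardized scale, all methylation values
above a threshold (default +1) and all expression values below a
threshold (default -1), i.e. consistently hypermethylated and lowly
expressed. Candidate sets extracted before and after denoising are
compared as a Venn partition, and the effect of denoising on individual
cells is quantified with MA (Bland-Altman) statistics: M = denoised -
raw (a log2 fold change, since the values are on a log2-derived scale)
against A, the mean of the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import OmicsMatrix


@dataclass
class GeneSet:
    ids: list[str]
    provenance: str = ""                 # e.g. "non_denoised" / "denoised"
    meth_min: float = 1.0
    expr_max: float = -1.0

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("gene set contains duplicate IDs")

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.ids)


def select_extreme(
    m: OmicsMatrix,
    meth_min: float = 1.0,
    expr_max: float = -1.0,
    provenance: str = "",
) -> GeneSet:
    """Genes with every methylation cell > meth_min and every expression
    cell < expr_max (strict inequalities).

    The rule quantifies over all cells, so the matrix must be complete;
    it is meant to run on the centered/scaled (optionally denoised and
    re-scaled) matrix, where the thresholds are z-scores.
    """
    if np.isnan(m.values).any():
        raise ValueError("extreme-profile selection requires a complete matrix")
    meth = m.columns_of("methylation")
    expr = m.columns_of("expression")
    if meth.size == 0 or expr.size == 0:
        raise ValueError("selection needs both methylation and expression variables")
    keep = (m.values[:, meth] > meth_min).all(axis=1) & (
        m.values[:, expr] < expr_max
    ).all(axis=1)
    ids = [m.gene_ids[i] for i in np.flatnonzero(keep)]
    return GeneSet(ids, provenance=provenance, meth_min=meth_min, expr_max=expr_max)


def compare_sets(a: GeneSet, b: GeneSet) -> dict[str, list[str]]:
    """Venn partition of two gene sets: only_a / shared / only_b.

    The three lists are disjoint, their union is a ∪ b, and each list
    preserves the order of the set it came from.
    """
    sa, sb = set(a.ids), set(b.ids)
    return {
        "only_a": [g for g in a.ids if g not in sb],
        "shared": [g for g in a.ids if g in sb],
        "only_b": [g for g in b.ids if g not in sa],
    }


def venn_counts(a: GeneSet, b: GeneSet) -> pd.Series:
    parts = compare_sets(a, b)
    return pd.Series({k: len(v) for k, v in parts.items()}, name="n_genes")


def ma_compare(raw: OmicsMatrix, den: OmicsMatrix, cutoff: float = 1.0) -> pd.DataFrame:
    """Per-cell MA comparison of denoised vs non-denoised matrices.

    Returns one row per (gene, variable) with A = (den + raw) / 2,
    M = den - raw, and ``flagged`` where |M| > cutoff. Inputs must share
    genes and variables in identical order and be on the same (log2)
    scale.
    """
    if raw.shape != den.shape:
        raise ValueError(f"shape mismatch: raw {raw.shape} vs denoised {den.shape}")
    if raw.gene_ids != den.gene_ids:
        raise ValueError("gene IDs differ between raw and denoised matrices")
    if raw.variable_names != den.variable_names:
        raise ValueError("variables differ between raw and denoised matrices")
    n, p = raw.shape
    genes = np.repeat(raw.gene_ids, p)
    variables = np.tile(raw.variable_names, n)
    r = raw.values.ravel()
    d = den.values.ravel()
    M = d - r
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "variable": variables,
            "A": (d + r) / 2.0,
            "M": M,
            "flagged": np.abs(M) > cutoff,
        }
    )
    return out


def ma_summary(ma: pd.DataFrame) -> pd.DataFrame:
    """Flag counts per variable from an MA table."""
    return (
        ma.groupby("variable", sort=False)["flagged"]
        .agg(n_cells="size", n_flagged="sum")
        .assign(fraction_flagged=lambda t: t.n_flagged / t.n_cells)
    )
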