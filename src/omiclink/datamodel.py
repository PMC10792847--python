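"""Core data model for gene-centric multi-omics matrices.

The central object is an :class:`OmicsMatrix`: genes in rows, omics
variables in columns. Each column carries a :class:`VariableDescriptor`
stating what it measures — normalized gene expression, or DNA methylation
in one cytosine context (CG / CHG / CHH) aggregated over one gene feature
(promoter or gene body) — and for which population (individual) it was
measured. A matrix can be partitioned column-wise into a :class:`BlockSet`
(one block per omics kind), and a symmetric :class:`DesignMatrix` of
non-negative weights states how strongly each pair of blocks should be
linked during multi-block integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

OMIC_TYPES = ("expression", "methylation")
FEATURES = ("promoter", "gene_body", "none")
CONTEXTS = ("CG", "CHG", "CHH", "none")

#: canonical variable kinds: expression plus {feature} x {context}
VARIABLE_KINDS = (
    "expression",
    "promoter_CG",
    "promoter_CHG",
    "promoter_CHH",
    "gene_body_CG",
    "gene_body_CHG",
    "gene_body_CHH",
)


@dataclass(frozen=True)
class VariableDescriptor:
    """Metadata of one matrix column.

    Expression columns have no feature/context (both "none"); methylation
    columns must state both the gene feature and the cytosine context.
    """

    name: str
    omic_type: str
    feature: str = "none"
    context: str = "none"
    population: str = ""

    def __post_init__(self) -> None:
        if self.omic_type not in OMIC_TYPES:
            raise ValueError(f"unknown omic_type {self.omic_type!r} for {self.name!r}")
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r} for {self.name!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r} for {self.name!r}")
        if self.omic_type == "expression":
            if self.feature != "none" or self.context != "none":
                raise ValueError(
                    f"expression variable {self.name!r} must have feature=none and context=none"
                )
        else:
            if self.feature == "none" or self.context == "none":
                raise ValueError(
                    f"methylation variable {self.name!r} needs a gene feature and a context"
                )

    @property
    def kind(self) -> str:
        """Canonical kind label ('expression' or '<feature>_<context>')."""
        if self.omic_type == "expression":
            return "expression"
        return f"{self.feature}_{self.context}"


@dataclass
class OmicsMatrix:
    """Genes x variables matrix with missing values encoded as NaN.

    ``values`` is a float array of shape (n_genes, n_variables); missing
    cells hold NaN and are mirrored in :attr:`missing_mask`. Gene IDs are
    opaque unique strings, column descriptors are
    :class:`VariableDescriptor` objects in column order.
    """

    values: np.ndarray
    gene_ids: list[str]
    variables: list[VariableDescriptor]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.variables)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.variables)} variables"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.values).any():
                raise ValueError("values must be finite or NaN")
        all_missing = np.isnan(self.values).all(axis=0)
        if self.n_genes and all_missing.any():
            bad = [names[j] for j in np.flatnonzero(all_missing)]
            raise ValueError(f"all-missing column(s): {bad}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    # -- views ----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.variable_names,
        )

    def take_genes(self, idx: np.ndarray | list[int]) -> "OmicsMatrix":
        idx = np.asarray(idx)
        return OmicsMatrix(
            self.values[idx], [self.gene_ids[i] for i in idx], list(self.variables)
        )

    def take_variables(self, idx: Iterable[int]) -> "OmicsMatrix":
        idx = list(idx)
        return OmicsMatrix(
            self.values[:, idx], list(self.gene_ids), [self.variables[i] for i in idx]
        )

    def with_values(self, values: np.ndarray) -> "OmicsMatrix":
        return OmicsMatrix(values, list(self.gene_ids), list(self.variables))

    def columns_of(self, omic_type: str) -> np.ndarray:
        """Column indices of a given omic type."""
        return np.array(
            [j for j, v in enumerate(self.variables) if v.omic_type == omic_type],
            dtype=int,
        )


@dataclass
class BlockSet:
    """Ordered column-partition of one OmicsMatrix into named blocks.

    All blocks share gene IDs in identical order; block names are unique.
    """

    blocks: dict[str, OmicsMatrix]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("empty block set")
        ref = None
        for name, b in self.blocks.items():
            if b.n_variables == 0:
                raise ValueError(f"block {name!r} has no variables")
            if ref is None:
                ref = b.gene_ids
            elif b.gene_ids != ref:
                raise ValueError(f"block {name!r} gene IDs differ from first block")

    @property
    def names(self) -> list[str]:
        return list(self.blocks)

    @property
    def gene_ids(self) -> list[str]:
        return next(iter(self.blocks.values())).gene_ids

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def __getitem__(self, name: str) -> OmicsMatrix:
        return self.blocks[name]

    def __iter__(self):
        return iter(self.blocks.items())

    def __len__(self) -> int:
        return len(self.blocks)

    def concatenate(self) -> OmicsMatrix:
        """Column-wise concatenation of the blocks, in block order."""
        values = np.hstack([b.values for b in self.blocks.values()])
        variables = [v for b in self.blocks.values() for v in b.variables]
        return OmicsMatrix(values, list(self.gene_ids), variables)

    def map_values(self, fn: Callable[[np.ndarray], np.ndarray]) -> "BlockSet":
        return BlockSet({n: b.with_values(fn(b.values)) for n, b in self})


@dataclass
class DesignMatrix:
    """Symmetric block-link weights c_jk in [0, 1] with zero diagonal.

    c_jk multiplies the covariance between the latent variates of blocks j
    and k in the multi-block objective; 0 on the diagonal means no block is
    linked to itself.
    """

    weights: np.ndarray
    block_names: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        J = len(self.block_names)
        if self.weights.shape != (J, J):
            raise ValueError("design matrix shape does not match block names")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("design matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("design matrix diagonal must be zero")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("design weights must lie in [0, 1]")

    def weight(self, a: str, b: str) -> float:
        i, j = self.block_names.index(a), self.block_names.index(b)
        return float(self.weights[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.block_names, columns=self.block_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DesignMatrix":
        names = [str(c) for c in df.columns]
        if [str(i) for i in df.index] != names:
            raise ValueError("design matrix rows and columns must carry the same names")
        return cls(df.to_numpy(dtype=float), names)


def default_design(
    block_names: Iterable[str],
    expression_block: str = "expression",
    meth_expr_weight: float = 1.0,
    meth_meth_weight: float = 0.1,
) -> DesignMatrix:
    """Design used for methylome-on-transcriptome integration.

    Weight 1 links every methylation block to the expression block, 0.1
    links methylation blocks among themselves, 0 sits on the diagonal.
    """
    names = list(block_names)
    if expression_block not in names:
        raise ValueError(f"expression block {expression_block!r} not among {names}")
    J = len(names)
    W = np.full((J, J), meth_meth_weight)
    e = names.index(expression_block)
    W[e, :] = meth_expr_weight
    W[:, e] = meth_expr_weight
    np.fill_diagonal(W, 0.0)
    return DesignMatrix(W, names)


def split_blocks(
    m: OmicsMatrix,
    grouping: Callable[[VariableDescriptor], str] | Mapping[str, str] | None = None,
) -> BlockSet:
    """Partition a matrix column-wise into named blocks.

    The default grouping assigns each variable to its canonical kind,
    giving one expression block plus {promoter, gene_body} x {CG, CHG, CHH}
    methylation blocks, each holding all populations' columns of that kind.
    Gene order is preserved; block order follows first appearance in
    :data:`VARIABLE_KINDS` then column order.
    """
    if grouping is None:
        keyfn = lambda v: v.kind
    elif callable(grouping):
        keyfn = grouping
    else:
        keyfn = lambda v: grouping[v.name]

    assignment: dict[str, list[int]] = {}
    for j, v in enumerate(m.variables):
        assignment.setdefault(keyfn(v), []).append(j)
    for name, cols in assignment.items():
        if not cols:
            raise ValueError(f"block {name!r} is empty")

    canon = [k for k in VARIABLE_KINDS if k in assignment]
    extra = [k for k in assignment if k not in VARIABLE_KINDS]
    ordered = canon + extra
    return BlockSet({name: m.take_variables(assignment[name]) for name in ordered})
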