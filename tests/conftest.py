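import numpy as np
import pytest

from omiclink.datamodel import BlockSet, OmicsMatrix, VariableDescriptor, split_blocks
from omiclink.simulate import SimConfig, simulate_dataset


def make_descriptors(n_expr: int, n_meth: int, kind: str = "gene_body_CG"):
    """n_expr expression + n_meth methylation descriptors of one kind."""
    feature, context = kind.rsplit("_", 1)
    out = [
        VariableDescriptor(f"expr_{i}", "expression", population=f"p{i}")
        for i in range(n_expr)
    ]
    out += [
        VariableDescriptor(f"meth_{i}", "methylation", feature, context, f"p{i}")
        for i in range(n_meth)
    ]
    return out


def make_matrix(values, n_expr=None, variables=None) -> OmicsMatrix:
    """OmicsMatrix from a 2-D array; first n_expr columns are expression
    (default: half), the rest gene-body CG methylation."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if variables is None:
        if n_expr is None:
            n_expr = p // 2
        variables = make_descriptors(n_expr, p - n_expr)
    gene_ids = [f"g{i + 1}" for i in range(n)]
    return OmicsMatrix(values, gene_ids, variables)


def standardize(X: np.ndarray) -> np.ndarray:
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def random_blockset(rng, n=30, widths=(5, 4), kinds=("gene_body_CG", "promoter_CG")) -> BlockSet:
    """Complete, standardized blocks with some shared structure."""
    u = rng.normal(size=n)
    blocks = {}
    for w, kind in zip(widths, kinds):
        X = rng.normal(size=(n, w)) + np.outer(u, rng.normal(size=w))
        feature, context = kind.rsplit("_", 1)
        variables = [
            VariableDescriptor(f"{kind}_{j}", "methylation", feature, context, f"p{j}")
            for j in range(w)
        ]
        blocks[kind] = OmicsMatrix(
            standardize(X), [f"g{i}" for i in range(n)], variables
        )
    return BlockSet(blocks)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared across tests (fast, complete)."""
    cfg = SimConfig(n_genes=300, n_drivers=8, missing_rate=0.0, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_blocks(small_sim):
    from omiclink.preprocess import center_scale

    m, _ = small_sim
    ms, _ = center_scale(m)
    return split_blocks(ms)
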