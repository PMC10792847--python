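"""Synthetic methylome + transcriptome matrices with known ground truth.

The generator emulates the structure of a population-level poplar-style
dataset: for each of P populations, one normalized expression variable
and six methylation variables ({promoter, gene body} x {CG, CHG, CHH}),
all on a log2-like scale. Genes fall into four typologies of
methylation-expression interplay:

1. high expression, low methylation everywhere;
2. low expression, low CG gene-body methylation, moderate promoter and
   non-CG gene-body methylation;
3. high methylation in all features/contexts, moderate-to-low expression;
4. high expression and high CG gene-body methylation, moderate elsewhere.

On top of the typologies, a small number of "master-driver" genes carry
an extreme, population-consistent profile: all methylation kinds shifted
up and expression shifted down by ``driver_effect`` standard units.

Populations of the same variable kind are strongly correlated: the noise
of a gene/kind cell splits into a component shared by all populations
(fraction ``population_correlation`` of the noise variance) and an
idiosyncratic per-population remainder. The gene-level shared component
of promoter methylation is heavy-tailed (scaled Student t), so a few
genes carry extreme promoter values across all populations; expression
has a point mass at zero for weakly expressed cells; missing values are
concentrated in a subset of genes (drivers stay complete so the
all-populations selection rule remains well defined on the truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .datamodel import OmicsMatrix, VariableDescriptor, VARIABLE_KINDS
from .selection import GeneSet

_METH_KINDS = VARIABLE_KINDS[1:]
_PROMOTER_KINDS = ("promoter_CG", "promoter_CHG", "promoter_CHH")

#: typology mean offsets (standard units) per variable kind
TYPOLOGY_TEMPLATES: dict[int, dict[str, float]] = {
    1: {"expression": 1.0, "promoter_CG": -1.0, "promoter_CHG": -1.0,
        "promoter_CHH": -1.0, "gene_body_CG": -1.0, "gene_body_CHG": -1.0,
        "gene_body_CHH": -1.0},
    2: {"expression": -2.0, "promoter_CG": 0.3, "promoter_CHG": 0.3,
        "promoter_CHH": 0.3, "gene_body_CG": -1.0, "gene_body_CHG": 0.3,
        "gene_body_CHH": 0.3},
    3: {"expression": -0.5, "promoter_CG": 1.0, "promoter_CHG": 1.0,
        "promoter_CHH": 1.0, "gene_body_CG": 1.0, "gene_body_CHG": 1.0,
        "gene_body_CHH": 1.0},
    4: {"expression": 1.0, "promoter_CG": 0.3, "promoter_CHG": 0.3,
        "promoter_CHH": 0.3, "gene_body_CG": 1.0, "gene_body_CHG": 0.3,
        "gene_body_CHH": 0.3},
}

#: typology that the planted drivers' profile is an extreme version of
DRIVER_TYPOLOGY = 3


@dataclass
class SimConfig:
    n_genes: int = 2000
    n_populations: int = 10
    typology_proportions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_drivers: int = 30
    driver_effect: float = 2.5
    population_correlation: float = 0.9
    missing_rate: float = 0.05
    missing_gene_fraction: float = 0.35
    expression_zero_fraction: float = 0.3
    promoter_tail_df: float = 3.0
    baseline: float = 3.0
    gene_effect_sd: float = 0.2
    noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.typology_proportions) - 1.0) > 1e-9:
            raise ValueError("typology proportions must sum to 1")
        if len(self.typology_proportions) != 4:
            raise ValueError("exactly four typology proportions are required")
        for attr in ("population_correlation", "missing_rate",
                     "missing_gene_fraction", "expression_zero_fraction"):
            v = getattr(self, attr)
            if not 0 <= v <= 1:
                raise ValueError(f"{attr} must lie in [0, 1]")
        if self.population_correlation >= 1:
            raise ValueError("population_correlation must be < 1")
        if self.n_drivers > self.n_genes:
            raise ValueError("n_drivers cannot exceed n_genes")
        if self.promoter_tail_df <= 2:
            raise ValueError("promoter_tail_df must be > 2 (finite variance)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class SimTruth:
    typology: pd.Series         # gene_id -> 1..4
    is_driver: pd.Series        # gene_id -> bool
    latent_means: pd.DataFrame  # genes x variable kinds

    @property
    def driver_ids(self) -> list[str]:
        return list(self.is_driver.index[self.is_driver])


def _variable_layout(n_populations: int) -> list[VariableDescriptor]:
    pops = [f"pop{p + 1:02d}" for p in range(n_populations)]
    variables = []
    for kind in VARIABLE_KINDS:
        for pop in pops:
            if kind == "expression":
                variables.append(VariableDescriptor(
                    name=f"expression_{pop}", omic_type="expression", population=pop))
            else:
                feature, context = kind.rsplit("_", 1)
                variables.append(VariableDescriptor(
                    name=f"{kind}_{pop}", omic_type="methylation",
                    feature=feature, context=context, population=pop))
    return variables


def simulate_dataset(
    cfg: SimConfig | None = None, raw_scale: bool = False
) -> tuple[OmicsMatrix, SimTruth]:
    """Draw one synthetic dataset plus its ground truth.

    With ``raw_scale=True`` the matrix holds 2**v - 1 (TPM-like positive
    values) so the log2(1 + x) transform can be exercised; by default the
    log2-like values are emitted directly. A fixed config (including its
    seed) yields bit-identical output.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n, P = cfg.n_genes, cfg.n_populations
    K = len(VARIABLE_KINDS)
    gene_ids = [f"gene{i + 1:05d}" for i in range(n)]
    variables = _variable_layout(P)

    typology = rng.choice(
        np.arange(1, 5), size=n, p=np.asarray(cfg.typology_proportions))
    driver_idx = rng.choice(n, size=cfg.n_drivers, replace=False)
    is_driver = np.zeros(n, dtype=bool)
    is_driver[driver_idx] = True
    typology[driver_idx] = DRIVER_TYPOLOGY

    # latent mean per gene x kind
    offsets = np.array(
        [[TYPOLOGY_TEMPLATES[t][k] for k in VARIABLE_KINDS] for t in range(1, 5)])
    mu = cfg.baseline + offsets[typology - 1]
    driver_shift = np.array(
        [-cfg.driver_effect] + [cfg.driver_effect] * (K - 1))
    mu[driver_idx] = cfg.baseline + driver_shift

    # noise: shared across populations within a gene/kind + idiosyncratic
    rho, sd = cfg.population_correlation, cfg.noise_sd
    gene_effect = rng.normal(0.0, cfg.gene_effect_sd, size=(n, 1, 1))
    shared_sd = np.sqrt(rho) * sd
    shared = rng.normal(0.0, shared_sd, size=(n, K, 1))
    idio_sd = np.sqrt(1.0 - rho) * sd
    idio = rng.normal(0.0, idio_sd, size=(n, K, P))
    # heavy-tailed gene-level component for promoter methylation: a few
    # genes carry extreme values consistently across populations
    df = cfg.promoter_tail_df
    t_scale = shared_sd / np.sqrt(df / (df - 2.0))
    for kind in _PROMOTER_KINDS:
        k = VARIABLE_KINDS.index(kind)
        shared[:, k, 0] = rng.standard_t(df, size=n) * t_scale

    values = mu[:, :, None] + gene_effect + shared + idio
    values = np.maximum(values, 0.0)  # log2(1+x) scale is non-negative

    # zero inflation: weakly expressed cells drop to exact zero
    expr_k = VARIABLE_KINDS.index("expression")
    weak = values[:, expr_k, :] < 1.0
    zeroed = weak & (rng.random((n, P)) < cfg.expression_zero_fraction)
    values[:, expr_k, :] = np.where(zeroed, 0.0, values[:, expr_k, :])

    # missingness concentrated in a subset of non-driver genes
    if cfg.missing_rate > 0 and cfg.missing_gene_fraction > 0:
        candidates = np.flatnonzero(~is_driver)
        n_affected = int(round(cfg.missing_gene_fraction * n))
        n_affected = min(n_affected, candidates.size)
        affected = rng.choice(candidates, size=n_affected, replace=False)
        cell_rate = min(1.0, cfg.missing_rate / cfg.missing_gene_fraction)
        holes = rng.random((n_affected, K, P)) < cell_rate
        values[affected] = np.where(holes, np.nan, values[affected])

    flat = values.reshape(n, K * P)  # kind-major, matching _variable_layout
    if raw_scale:
        flat = np.exp2(flat) - 1.0

    matrix = OmicsMatrix(flat, gene_ids, variables)
    idx = pd.Index(gene_ids, name="gene_id")
    truth = SimTruth(
        typology=pd.Series(typology, index=idx, name="typology"),
        is_driver=pd.Series(is_driver, index=idx, name="is_driver"),
        latent_means=pd.DataFrame(mu, index=idx, columns=list(VARIABLE_KINDS)),
    )
    return matrix, truth


def scoreboard(
    truth: SimTruth,
    selected: GeneSet | list[str] | None = None,
    clusters: pd.Series | None = None,
) -> dict[str, float]:
    """Score predictions against the simulated truth.

    * ``sensitivity``: fraction of planted drivers present in ``selected``.
    * ``false_discovery_proportion``: fraction of ``selected`` that are
      not drivers (0 for an empty selection).
    * ``adjusted_rand_index``: ARI between planted typologies and
      ``clusters`` (restricted to the clustered genes).
    """
    out: dict[str, float] = {}
    if selected is not None:
        ids = selected.ids if isinstance(selected, GeneSet) else list(selected)
        unknown = [g for g in ids if g not in truth.is_driver.index]
        if unknown:
            raise ValueError(f"selected gene(s) not in truth: {unknown[:5]}")
        chosen = set(ids)
        drivers = set(truth.driver_ids)
        tp = len(chosen & drivers)
        out["sensitivity"] = tp / len(drivers) if drivers else float("nan")
        out["false_discovery_proportion"] = (
            (len(chosen) - tp) / len(chosen) if chosen else 0.0
        )
    if clusters is not None:
        common = clusters.index.intersection(truth.typology.index)
        if len(common) == 0:
            raise ValueError("clusters share no genes with the truth")
        out["adjusted_rand_index"] = float(
            adjusted_rand_score(
                truth.typology.loc[common].to_numpy(),
                clusters.loc[common].to_numpy(),
            )
        )
    return out
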