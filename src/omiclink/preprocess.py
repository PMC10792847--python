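"""Preprocessing of the gene x variable matrix.

Filters remove genes with too little information (no expression or no
methylation measurement at all, or more than a tolerated fraction of
missing cells); a log2(1 + x) transform tames the long right tails typical
of normalized expression (TPM-derived) and methylation density values;
centering/scaling puts all variables on a comparable z-scale; clamping
truncates extreme z-scores for display and selection.

The filters compose in a fixed order — minimum-per-omic-class first, then
the missing-fraction cut — and the missing-fraction cut is applied per
gene (fraction of that gene's cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import OmicsMatrix


@dataclass
class PreprocessConfig:
    pseudo_count: float = 1.0
    log_base: float = 2.0
    max_missing_fraction: float = 0.10
    clamp_bounds: tuple[float, float] = (-2.0, 2.0)
    require_complete: bool = False

    def __post_init__(self) -> None:
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be > 0")
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must lie in [0, 1]")
        lo, hi = self.clamp_bounds
        if not lo < hi:
            raise ValueError("clamp lower bound must be below upper bound")


@dataclass
class ScalingRecord:
    """Per-column mean and sample (n-1) standard deviation used to scale."""

    variable_names: list[str]
    mean: np.ndarray
    std: np.ndarray


def filter_min_per_class(m: OmicsMatrix) -> OmicsMatrix:
    """Keep genes with >=1 non-missing expression AND >=1 non-missing
    methylation value; gene order preserved."""
    expr = m.columns_of("expression")
    meth = m.columns_of("methylation")
    if expr.size == 0 or meth.size == 0:
        raise ValueError("matrix needs at least one expression and one methylation variable")
    present = ~m.missing_mask
    keep = present[:, expr].any(axis=1) & present[:, meth].any(axis=1)
    return m.take_genes(np.flatnonzero(keep))


def filter_missing_fraction(m: OmicsMatrix, max_frac: float = 0.10) -> OmicsMatrix:
    """Keep genes whose fraction of missing cells is <= ``max_frac``.

    ``max_frac = 0`` is the complete-case filter.
    """
    if not 0 <= max_frac <= 1:
        raise ValueError("max_frac must lie in [0, 1]")
    frac = m.missing_mask.mean(axis=1)
    return m.take_genes(np.flatnonzero(frac <= max_frac))


def log_transform(m: OmicsMatrix, cfg: PreprocessConfig | None = None) -> OmicsMatrix:
    """x -> log_base(pseudo_count + x) on non-missing cells.

    Monotone, so within-column ranks are preserved; with the defaults
    (pseudo count 1, base 2) zero maps to zero.
    """
    cfg = cfg or PreprocessConfig()
    values = m.values
    neg = values < 0  # NaN compares False
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"negative value {values[i, j]} at gene {m.gene_ids[i]!r}, "
            f"variable {m.variables[j].name!r}; log transform needs x >= 0"
        )
    out = np.log(cfg.pseudo_count + values) / np.log(cfg.log_base)
    return m.with_values(out)


def center_scale(m: OmicsMatrix) -> tuple[OmicsMatrix, ScalingRecord]:
    """Center and scale each column to mean 0, sample sd 1.

    Statistics are computed on non-missing cells only; missing cells stay
    missing. Columns with fewer than two observations or zero variance are
    rejected.
    """
    values = m.values
    n_obs = (~np.isnan(values)).sum(axis=0)
    if (n_obs < 2).any():
        bad = [m.variables[j].name for j in np.flatnonzero(n_obs < 2)]
        raise ValueError(f"column(s) with <2 observations: {bad}")
    mean = np.nanmean(values, axis=0)
    std = np.nanstd(values, axis=0, ddof=1)
    if (std == 0).any() or np.isnan(std).any():
        bad = [m.variables[j].name for j in np.flatnonzero((std == 0) | np.isnan(std))]
        raise ValueError(f"zero-variance column(s): {bad}")
    scaled = (values - mean) / std
    record = ScalingRecord(m.variable_names, mean, std)
    return m.with_values(scaled), record


def clamp(m: OmicsMatrix, bounds: tuple[float, float] = (-2.0, 2.0)) -> OmicsMatrix:
    """Clip values into [lower, upper]; idempotent, NaN passes through."""
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("clamp lower bound must be below upper bound")
    return m.with_values(np.clip(m.values, lo, hi))
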