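"""Plotting helpers: correlation map, PCA loading plot, CIM heatmap, MA plot.

All functions write straight to a file path and use a non-interactive
backend; the color scale of the heatmap is pinned to the clamp bounds
[-2, 2] (blue = low, red = high).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .cim import CimResult
from .explore import CorrelationResult, PcaModel


def correlation_heatmap(res: CorrelationResult, path: str | Path) -> None:
    order = res.order
    names = [res.variable_names[i] for i in order]
    df = pd.DataFrame(res.corr[np.ix_(order, order)], index=names, columns=names)
    fig, ax = plt.subplots(figsize=(max(6, len(names) * 0.14),) * 2)
    sns.heatmap(df, vmin=-1, vmax=1, cmap="RdBu", square=True, ax=ax,
                xticklabels=False, yticklabels=False,
                cbar_kws={"label": "Spearman correlation"})
    ax.set_title("Variable correlation (AOE order)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def loading_plot(model: PcaModel, path: str | Path,
                 colors: list[str] | None = None) -> None:
    x, y = model.loadings[:, 0], model.loadings[:, 1]
    evf = model.explained_variance_fraction
    fig, ax = plt.subplots(figsize=(7, 6))
    ax.scatter(x, y, s=18, c=colors)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"PC1 ({evf[0] * 100:.1f}% of variance)")
    ax.set_ylabel(f"PC2 ({evf[1] * 100:.1f}% of variance)")
    ax.set_title("PCA loading plot")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def cim_heatmap(res: CimResult, path: str | Path) -> None:
    df = res.ordered_frame()
    fig, ax = plt.subplots(figsize=(max(6, df.shape[1] * 0.12), 8))
    sns.heatmap(df, vmin=-2, vmax=2, cmap="RdBu_r", ax=ax,
                xticklabels=False, yticklabels=False,
                cbar_kws={"label": "standardized value"})
    ax.set_title(
        f"Clustered image map (denoise={res.options.denoise}, "
        f"k={res.options.k_groups})"
    )
    ax.set_xlabel("variables")
    ax.set_ylabel("genes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ma_plot(ma: pd.DataFrame, path: str | Path, cutoff: float = 1.0,
            title: str = "MA plot: denoised vs non-denoised") -> None:
    fig, ax = plt.subplots(figsize=(7, 5))
    flagged = ma["flagged"].to_numpy()
    ax.scatter(ma.loc[~flagged, "A"], ma.loc[~flagged, "M"], s=4, c="black",
               alpha=0.4, label="|M| <= cutoff")
    ax.scatter(ma.loc[flagged, "A"], ma.loc[flagged, "M"], s=6, c="red",
               label=f"|M| > {cutoff:g}")
    ax.axhline(cutoff, color="red", lw=0.6, ls="--")
    ax.axhline(-cutoff, color="red", lw=0.6, ls="--")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("A (mean of denoised and non-denoised)")
    ax.set_ylabel("M (denoised - non-denoised)")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
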