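"""End-to-end orchestration of the integration workflow.

The pipeline runs the stages in a fixed order — preprocess, explore,
integrate, clustered image maps without and with denoising, candidate
selection / set comparison / MA quantification — writing each stage's
artifacts into an output directory, logging gene counts after every
filter, and finishing with a manifest listing every produced file with a
SHA-256 checksum (so that a rerun with identical inputs can be audited
for determinism).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as olio
from . import viz
from .block_pls import BlockPlsConfig, explained_variance, fit_block_pls
from .cim import CimOptions, build_cim, cluster_profiles, transform_blocks
from .datamodel import OmicsMatrix, default_design, split_blocks
from .explore import pca_nipals, spearman_matrix
from .preprocess import (PreprocessConfig, center_scale, filter_min_per_class,
                         filter_missing_fraction, log_transform)
from .selection import compare_sets, ma_compare, ma_summary, select_extreme, venn_counts
from .simulate import SimConfig, simulate_dataset

logger = logging.getLogger("omiclink")


@dataclass
class PipelineConfig:
    matrix: str | None = None
    metadata: str | None = None
    out_dir: str = "omiclink_run"
    simulate: bool = False
    sim: SimConfig = field(default_factory=SimConfig)
    apply_log: bool = True                # log2(1+x) transform of the input
    max_missing_fraction: float = 0.10
    n_components: int = 2
    scheme: str = "horst"
    meth_expr_weight: float = 1.0
    meth_meth_weight: float = 0.1
    k_groups: int = 4
    meth_min: float = 1.0
    expr_max: float = -1.0
    ma_cutoff: float = 1.0
    run_explore: bool = True
    make_plots: bool = True

    def validate(self) -> None:
        if not self.simulate:
            if self.matrix is None or self.metadata is None:
                raise ValueError("matrix and metadata paths are required unless simulate=True")
            for p in (self.matrix, self.metadata):
                if not Path(p).is_file():
                    raise FileNotFoundError(f"input file not found: {p}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat ``key = value`` text file; keys mirror the CLI flags and
        ``sim.*`` keys address the simulator config."""
        kwargs: dict = {}
        sim_kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"cannot parse config line: {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            target, tkey = (sim_kwargs, key[4:]) if key.startswith("sim.") else (kwargs, key)
            target[tkey] = value
        cfg = cls()
        for f in fields(cls):
            if f.name in kwargs:
                setattr(cfg, f.name, _coerce(kwargs.pop(f.name), getattr(cfg, f.name)))
        if kwargs:
            raise ValueError(f"unknown config key(s): {sorted(kwargs)}")
        if sim_kwargs:
            sim_fields = {f.name: f for f in fields(SimConfig)}
            sim_args = {}
            for k, v in sim_kwargs.items():
                if k not in sim_fields:
                    raise ValueError(f"unknown simulator key: sim.{k}")
                sim_args[k] = _coerce(v, getattr(SimConfig(), k))
            cfg.sim = SimConfig(**sim_args)
        return cfg


def _coerce(text: str, default):
    if isinstance(default, bool):
        if text.lower() in ("1", "true", "yes"):
            return True
        if text.lower() in ("0", "false", "no"):
            return False
        raise ValueError(f"cannot parse boolean {text!r}")
    if isinstance(default, int):
        return int(text)
    if isinstance(default, float):
        return float(text)
    if isinstance(default, tuple):
        return tuple(float(x) for x in text.split(","))
    return text


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Artifacts:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.paths: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.out_dir / name
        self.paths.append(p)
        return p

    def manifest(self) -> pd.DataFrame:
        rows = [
            {"file": str(p.relative_to(self.out_dir)), "sha256": _sha256(p)}
            for p in self.paths if p.is_file()
        ]
        return pd.DataFrame(rows).set_index("file")


def run_pipeline(cfg: PipelineConfig) -> pd.DataFrame:
    """Run all stages; returns the artifact manifest (file -> checksum)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    art = _Artifacts(out)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "load"
    try:
        # ---- input ---------------------------------------------------
        if cfg.simulate:
            m, truth = simulate_dataset(cfg.sim, raw_scale=cfg.apply_log)
            olio.write_matrix(m, art.path("input_matrix.tsv"))
            olio.write_metadata(m.variables, art.path("input_metadata.tsv"))
            truth_table = pd.concat([truth.typology, truth.is_driver], axis=1)
            olio.write_table(truth_table, art.path("sim_truth.tsv"))
            olio.write_table(truth.latent_means, art.path("sim_latent_means.tsv"))
        else:
            m = olio.load_matrix(cfg.matrix, cfg.metadata)
        counts = {"input": m.n_genes}
        logger.info("loaded matrix: %d genes x %d variables", *m.shape)

        # ---- preprocess ----------------------------------------------
        stage = "preprocess"
        if cfg.apply_log:
            m = log_transform(m)
        m_min = filter_min_per_class(m)
        counts["min_per_class"] = m_min.n_genes
        m_frac = filter_missing_fraction(m_min, cfg.max_missing_fraction)
        counts["missing_fraction"] = m_frac.n_genes
        m_complete = filter_missing_fraction(m_frac, 0.0)
        counts["complete_cases"] = m_complete.n_genes
        logger.info(
            "gene counts: %s", " -> ".join(f"{k}={v}" for k, v in counts.items())
        )
        pd.Series(counts, name="n_genes").rename_axis("stage").to_frame().to_csv(
            art.path("filter_counts.tsv"), sep="\t"
        )
        ms, record = center_scale(m_complete)
        olio.write_matrix(ms, art.path("preprocessed_matrix.tsv"))
        olio.write_table(
            pd.DataFrame(
                {"mean": record.mean, "std": record.std},
                index=pd.Index(record.variable_names, name="variable"),
            ),
            art.path("scaling_record.tsv"),
        )

        # ---- explore --------------------------------------------------
        if cfg.run_explore:
            stage = "explore"
            corr = spearman_matrix(m_complete)
            names = corr.variable_names
            olio.write_table(
                pd.DataFrame(corr.corr, index=pd.Index(names, name="variable"),
                             columns=names),
                art.path("correlation_matrix.tsv"),
            )
            olio.write_table(
                pd.DataFrame(
                    {"variable": [names[i] for i in corr.order]},
                    index=pd.Index(range(1, len(names) + 1), name="position"),
                ),
                art.path("correlation_order.tsv"),
            )
            m_pca, _ = center_scale(m_frac)
            pca = pca_nipals(m_pca, n_components=cfg.n_components)
            olio.write_table(
                pd.DataFrame(pca.loadings, index=pd.Index(names, name="variable"),
                             columns=[f"PC{h+1}" for h in range(pca.loadings.shape[1])]),
                art.path("pca_loadings.tsv"),
            )
            olio.write_table(
                pd.Series(pca.explained_variance_fraction,
                          index=pd.Index([f"PC{h+1}" for h in
                                          range(len(pca.explained_variance_fraction))],
                                         name="component"),
                          name="explained_variance_fraction"),
                art.path("pca_explained_variance.tsv"),
            )
            if cfg.make_plots:
                viz.correlation_heatmap(corr, art.path("correlation_heatmap.png"))
                viz.loading_plot(pca, art.path("pca_loading_plot.png"))

        # ---- integrate ------------------------------------------------
        stage = "integrate"
        bs = split_blocks(ms)
        design = default_design(
            bs.names, meth_expr_weight=cfg.meth_expr_weight,
            meth_meth_weight=cfg.meth_meth_weight,
        )
        olio.write_table(design.to_frame().rename_axis("block"), art.path("design_matrix.tsv"))
        model = fit_block_pls(
            bs, BlockPlsConfig(n_components=cfg.n_components, design=design,
                               scheme=cfg.scheme),
        )
        for name in model.block_names:
            comp_cols = [f"comp{h+1}" for h in range(model.n_components)]
            olio.write_table(
                pd.DataFrame(model.loadings[name],
                             index=pd.Index(bs[name].variable_names, name="variable"),
                             columns=comp_cols),
                art.path(f"loadings_{name}.tsv"),
            )
            olio.write_table(
                pd.DataFrame(model.variates[name],
                             index=pd.Index(model.gene_ids, name="gene_id"),
                             columns=comp_cols),
                art.path(f"variates_{name}.tsv"),
            )
        ev = explained_variance(model, bs)
        olio.write_table(
            pd.DataFrame(ev, index=pd.Index(
                [f"comp{h+1}" for h in range(model.n_components)], name="component")).T
            .rename_axis("block"),
            art.path("explained_variance.tsv"),
        )
        olio.write_table(
            pd.DataFrame({"iterations": model.n_iterations,
                          "converged": model.converged},
                         index=pd.Index(range(1, model.n_components + 1),
                                        name="component")),
            art.path("convergence.tsv"),
        )
        logger.info("block-PLS fitted: %s components, iterations %s",
                    model.n_components, model.n_iterations)

        # ---- clustered image maps -------------------------------------
        stage = "cim"
        results = {}
        for label, opt in (
            ("non_denoised", CimOptions(denoise=False, scale2=False, cutoff=True,
                                        k_groups=cfg.k_groups)),
            ("denoised", CimOptions(denoise=True, scale2=True, cutoff=True,
                                    k_groups=cfg.k_groups)),
        ):
            res = build_cim(bs, model, opt)
            results[label] = res
            olio.write_matrix(res.matrix, art.path(f"cim_matrix_{label}.tsv"))
            olio.write_table(res.clusters.to_frame(), art.path(f"clusters_{label}.tsv"))
            olio.write_table(cluster_profiles(res).rename_axis("group"),
                             art.path(f"cluster_profiles_{label}.tsv"))
            if cfg.make_plots:
                viz.cim_heatmap(res, art.path(f"cim_heatmap_{label}.png"))
            logger.info("CIM (%s): %d genes cut into %d groups",
                        label, res.matrix.n_genes, opt.k_groups)

        # ---- selection / comparison / MA ------------------------------
        stage = "select"
        denoised_scaled = transform_blocks(
            bs, model, CimOptions(denoise=True, scale2=True, cutoff=False,
                                  k_groups=cfg.k_groups)
        ).concatenate()
        sel_raw = select_extreme(ms, cfg.meth_min, cfg.expr_max, "non_denoised")
        sel_den = select_extreme(denoised_scaled, cfg.meth_min, cfg.expr_max, "denoised")
        olio.write_gene_set(sel_raw.ids, art.path("candidates_non_denoised.txt"))
        olio.write_gene_set(sel_den.ids, art.path("candidates_denoised.txt"))
        olio.write_table(venn_counts(sel_raw, sel_den).to_frame().rename_axis("part"),
                         art.path("venn_counts.tsv"))
        logger.info("candidates: non-denoised %d, denoised %d",
                    len(sel_raw), len(sel_den))

        denoised_plain = transform_blocks(
            bs, model, CimOptions(denoise=True, scale2=False, cutoff=False,
                                  k_groups=cfg.k_groups)
        ).concatenate()
        ma = ma_compare(ms, denoised_plain, cutoff=cfg.ma_cutoff)
        summ = ma_summary(ma)
        olio.write_table(summ.rename_axis("variable"), art.path("ma_summary.tsv"))
        olio.write_table(ma[ma.flagged].set_index("gene_id"),
                         art.path("ma_flagged_cells.tsv"))
        if cfg.make_plots:
            viz.ma_plot(ma, art.path("ma_plot.png"), cutoff=cfg.ma_cutoff)

        # ---- manifest --------------------------------------------------
        stage = "manifest"
        manifest = art.manifest()
        manifest.to_csv(out / "manifest.tsv", sep="\t")
        logger.info("wrote %d artifacts to %s", len(manifest), out)
        return manifest
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
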