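"""Design-weighted multi-block PLS.

Several omics blocks X_1..X_J (same genes in rows, centered and scaled,
no missing values) are summarised by one latent variate per block and
component, t_j = X_j a_j, chosen so that the design-weighted sum of
covariances  sum_{j<k} c_jk * g(cov(t_j, t_k))  is large. The symmetric
design matrix c_jk states which pairs of blocks should be linked; the
scheme fixes g (horst: identity, centroid: absolute value, factorial:
square). Components are extracted sequentially; after each component
every block is deflated on its own variate, which makes the variates of a
block mutually orthogonal.

The fit is the classical inner loop of generalized canonical correlation
/ multi-block PLS: starting from each block's leading right singular
vector, the loadings are repeatedly updated against the design-weighted
combination of the other blocks' variates until they stabilise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import BlockSet, DesignMatrix

SCHEMES = ("horst", "centroid", "factorial")


@dataclass
class BlockPlsConfig:
    n_components: int = 2
    design: DesignMatrix | None = None
    scheme: str = "horst"
    tol: float = 1e-6
    max_iter: int = 100
    mode: str = "regression"
    #: response block for regression-mode deflation; with None every block
    #: is deflated on its own variate (the operative convention here)
    response_block: str | None = None

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.mode not in ("regression", "canonical"):
            raise ValueError("mode must be 'regression' or 'canonical'")


@dataclass
class BlockPlsModel:
    block_names: list[str]
    loadings: dict[str, np.ndarray]        # p_j x H, unit-norm columns (on deflated data)
    variates: dict[str, np.ndarray]        # n x H, t_j^(h) = X_j^(h-1) a_j^(h)
    deflated: dict[str, np.ndarray]        # final residual blocks
    n_iterations: list[int]                # per component
    converged: list[bool]                  # per component
    objective_trace: list[list[float]]     # per component, per inner iteration
    gene_ids: list[str]
    config: BlockPlsConfig

    @property
    def n_components(self) -> int:
        return next(iter(self.variates.values())).shape[1]


def _scheme_weight(tj: np.ndarray, tk: np.ndarray, scheme: str) -> float:
    cov = float(tj @ tk)
    if scheme == "horst":
        return 1.0
    if scheme == "centroid":
        return float(np.sign(cov)) if cov != 0 else 0.0
    return cov  # factorial


def _scheme_g(cov: float, scheme: str) -> float:
    if scheme == "horst":
        return cov
    if scheme == "centroid":
        return abs(cov)
    return cov * cov  # factorial


def _first_right_singular_vector(X: np.ndarray) -> np.ndarray:
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    return vt[0]


def fit_block_pls(bs: BlockSet, cfg: BlockPlsConfig | None = None) -> BlockPlsModel:
    """Fit the multi-block PLS model.

    Blocks must be complete (no NaN) and already centered and scaled.
    Components are extracted one by one: loadings are initialised from
    each block's leading right singular vector, updated against the
    design-weighted inner target until the largest loading change falls
    below ``tol``, and every block is then deflated on its own variate.
    Non-convergence of a component is recorded on the model (with a
    warning), not fatal; a block whose design row is all zero has no
    inner target and is rejected.
    """
    cfg = cfg or BlockPlsConfig()
    names = bs.names
    if cfg.design is None:
        raise ValueError("BlockPlsConfig.design is required")
    if set(cfg.design.block_names) != set(names):
        raise ValueError("design matrix block names do not match the block set")
    # design indexed in block order
    C = cfg.design.to_frame().loc[names, names].to_numpy()
    for j, name in enumerate(names):
        if not C[j].any():
            raise ValueError(f"block {name!r} is isolated: all its design weights are zero")

    X = {}
    for name, b in bs:
        if np.isnan(b.values).any():
            raise ValueError(f"block {name!r} contains missing values; filter upstream")
        X[name] = b.values.astype(float).copy()

    J = len(names)
    n = bs.n_genes
    H = cfg.n_components
    loadings = {name: np.zeros((X[name].shape[1], H)) for name in names}
    variates = {name: np.zeros((n, H)) for name in names}
    n_iter: list[int] = []
    converged: list[bool] = []
    traces: list[list[float]] = []

    for h in range(H):
        a = {name: _first_right_singular_vector(X[name]) for name in names}
        t = {name: X[name] @ a[name] for name in names}
        trace: list[float] = []
        ok = False
        for it in range(1, cfg.max_iter + 1):
            max_delta = 0.0
            for j, name in enumerate(names):
                omega = np.zeros(n)
                for k, other in enumerate(names):
                    if C[j, k] == 0:
                        continue
                    omega += C[j, k] * _scheme_weight(t[name], t[other], cfg.scheme) * t[other]
                new_a = X[name].T @ omega
                norm = np.linalg.norm(new_a)
                if norm == 0:
                    raise ValueError(
                        f"all-zero inner target for block {name!r} in component {h + 1}"
                    )
                new_a /= norm
                # the optimum is sign-invariant; compare against the closer sign
                delta = min(
                    np.max(np.abs(new_a - a[name])), np.max(np.abs(new_a + a[name]))
                )
                max_delta = max(max_delta, delta)
                a[name] = new_a
                t[name] = X[name] @ new_a
            obj = sum(
                C[j, k] * _scheme_g(float(t[names[j]] @ t[names[k]]), cfg.scheme)
                for j in range(J) for k in range(j + 1, J)
            )
            trace.append(obj)
            if max_delta < cfg.tol:
                ok = True
                break
        if not ok:
            warnings.warn(
                f"component {h + 1} did not converge in {cfg.max_iter} iterations "
                f"(last max loading change {max_delta:.2e})",
                RuntimeWarning,
            )
        n_iter.append(it)
        converged.append(ok)
        traces.append(trace)

        for name in names:
            # sign: largest-|a| entry positive, ties to the lowest index
            k = int(np.argmax(np.abs(a[name])))
            if a[name][k] < 0:
                a[name] = -a[name]
                t[name] = -t[name]
            loadings[name][:, h] = a[name]
            variates[name][:, h] = t[name]

        def _project_out(M: np.ndarray, v: np.ndarray) -> np.ndarray:
            vv = float(v @ v)
            return M - np.outer(v, (v @ M) / vv) if vv > 0 else M

        resp = cfg.response_block
        if cfg.mode == "regression" and resp is not None:
            if resp not in names:
                raise ValueError(f"response block {resp!r} not in block set")
            for name in names:
                if name == resp:
                    # average of deflations on every predictor variate
                    X[name] = np.mean(
                        [_project_out(X[name], t[o]) for o in names if o != resp],
                        axis=0,
                    )
                else:
                    X[name] = _project_out(X[name], t[name])
        else:
            for name in names:
                X[name] = _project_out(X[name], t[name])

    return BlockPlsModel(
        block_names=names,
        loadings=loadings,
        variates=variates,
        deflated=X,
        n_iterations=n_iter,
        converged=converged,
        objective_trace=traces,
        gene_ids=list(bs.gene_ids),
        config=cfg,
    )


def explained_variance(model: BlockPlsModel, bs: BlockSet) -> dict[str, np.ndarray]:
    """Fraction of each block's sum of squares captured per component.

    For block X with variates t_1..t_H (mutually orthogonal by own-variate
    deflation), component h captures ||t_h (t_h' X) / (t_h' t_h)||_F^2 of
    ||X||_F^2; the per-block fractions sum to <= 1 over components.
    """
    out: dict[str, np.ndarray] = {}
    for name in model.block_names:
        Xb = bs[name].values
        total = float((Xb ** 2).sum())
        T = model.variates[name]
        fracs = np.zeros(T.shape[1])
        for h in range(T.shape[1]):
            t = T[:, h]
            tt = float(t @ t)
            if tt == 0:
                continue
            proj = np.outer(t, (t @ Xb) / tt)
            fracs[h] = float((proj ** 2).sum()) / total
        out[name] = fracs
    return out
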