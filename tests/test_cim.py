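"""Denoising decomposition and the clustered image map."""

import numpy as np
import pandas as pd
import pytest

from omiclink.block_pls import BlockPlsConfig, fit_block_pls
from omiclink.cim import (CimOptions, build_cim, cluster_profiles, cut_tree_k,
                          denoise, transform_blocks, ward_linkage)
from omiclink.datamodel import (BlockSet, DesignMatrix, OmicsMatrix,
                                VariableDescriptor, default_design)
from omiclink.simulate import SimConfig, scoreboard, simulate_dataset

from conftest import make_matrix, random_blockset, standardize


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(21)
    bs = random_blockset(rng, n=40, widths=(5, 4))
    design = DesignMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), bs.names)
    model = fit_block_pls(bs, BlockPlsConfig(n_components=2, design=design))
    return bs, model


class TestDenoise:
    def test_exact_decomposition(self, fitted):
        bs, model = fitted
        den, res = denoise(bs, model)
        for name, b in bs:
            recon = den[name].values + res[name].values
            assert np.abs(recon - b.values).max() == pytest.approx(0.0, abs=1e-12)
            assert np.linalg.matrix_rank(den[name].values, tol=1e-8) <= 2

    def test_projection_idempotent(self, fitted):
        bs, model = fitted
        den, _ = denoise(bs, model)
        den2, res2 = denoise(den, model)
        for name in bs.names:
            assert np.abs(den2[name].values - den[name].values).max() < 1e-10
            assert np.abs(res2[name].values).max() < 1e-10

    def test_full_rank_variates_leave_no_residual(self):
        # rank-2 blocks, H=2 components spanning the column space
        rng = np.random.default_rng(22)
        n = 30
        T = rng.normal(size=(n, 2))
        X1 = standardize(T @ rng.normal(size=(2, 4)))
        X2 = standardize(T @ rng.normal(size=(2, 3)))
        mk = lambda X, kind: OmicsMatrix(
            X, [f"g{i}" for i in range(n)],
            [VariableDescriptor(f"{kind}{j}", "methylation", *kind.rsplit("_", 1), f"p{j}")
             for j in range(X.shape[1])])
        bs = BlockSet({"gene_body_CG": mk(X1, "gene_body_CG"),
                       "promoter_CG": mk(X2, "promoter_CG")})
        design = DesignMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), bs.names)
        model = fit_block_pls(bs, BlockPlsConfig(n_components=2, design=design))
        _, res = denoise(bs, model)
        for name in bs.names:
            assert np.abs(res[name].values).max() < 1e-8

    def test_identical_blocks_reduce_to_svd_truncation(self):
        # with two copies of the same block and c=1 the fit is the block's
        # PCA, so denoising at H=1 is the rank-1 SVD truncation
        rng = np.random.default_rng(23)
        X = standardize(rng.normal(size=(25, 4)) + np.outer(rng.normal(size=25),
                                                            rng.normal(size=4)))
        mk = lambda kind: OmicsMatrix(
            X.copy(), [f"g{i}" for i in range(25)],
            [VariableDescriptor(f"{kind}{j}", "methylation", *kind.rsplit("_", 1), f"p{j}")
             for j in range(4)])
        bs = BlockSet({"gene_body_CG": mk("gene_body_CG"),
                       "promoter_CG": mk("promoter_CG")})
        design = DesignMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), bs.names)
        model = fit_block_pls(bs, BlockPlsConfig(n_components=1, design=design,
                                                 tol=1e-10, max_iter=2000))
        den, _ = denoise(bs, model)
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        rank1 = s[0] * np.outer(u[:, 0], vt[0])
        assert np.abs(den["gene_body_CG"].values - rank1).max() < 1e-6


def ward_oracle(X):
    """Brute-force Ward agglomeration via the Lance-Williams update on
    squared Euclidean distances; returns (merge member-sets, heights)."""
    n = X.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    D2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            D2[(i, j)] = float(((X[i] - X[j]) ** 2).sum())
    get = lambda a, b: D2[(min(a, b), max(a, b))]
    merges, heights = [], []
    nxt = n
    active = list(range(n))
    while len(active) > 1:
        best = min(
            ((get(a, b), a, b) for idx, a in enumerate(active)
             for b in active[idx + 1:]),
        )
        d2, s, t = best
        merges.append(clusters[s] | clusters[t])
        heights.append(np.sqrt(d2))
        for v in active:
            if v in (s, t):
                continue
            nv, ns, nt = sizes[v], sizes[s], sizes[t]
            D2[(min(v, nxt), max(v, nxt))] = (
                (nv + ns) * get(v, s) + (nv + nt) * get(v, t) - nv * d2
            ) / (nv + ns + nt)
        clusters[nxt] = clusters[s] | clusters[t]
        sizes[nxt] = sizes[s] + sizes[t]
        active = [v for v in active if v not in (s, t)] + [nxt]
        nxt += 1
    return merges, np.array(heights)


class TestWardClustering:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_lance_williams_oracle_on_8_rows(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 4))
        tree = ward_linkage(X)
        merges, heights = ward_oracle(X)
        # reconstruct member sets from the scipy linkage
        members = {i: frozenset([i]) for i in range(8)}
        for step, (a, b, h, _) in enumerate(tree):
            merged = members[int(a)] | members[int(b)]
            members[8 + step] = merged
            assert merged == merges[step], f"step {step}"
            assert h == pytest.approx(heights[step], rel=1e-10)

    def test_tree_heights_non_decreasing(self, small_sim):
        from omiclink.preprocess import center_scale
        m, _ = small_sim
        ms, _ = center_scale(m)
        tree = ward_linkage(ms.values[:100])
        assert (np.diff(tree[:, 2]) >= -1e-10).all()

    def test_cut_extremes(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        tree = ward_linkage(X)
        assert set(cut_tree_k(tree, 1, 10)) == {1}
        assert sorted(cut_tree_k(tree, 10, 10)) == list(range(1, 11))


class TestBuildCim:
    def test_no_transforms_returns_reordered_input(self, fitted):
        bs, model = fitted
        res = build_cim(bs, model, CimOptions(denoise=False, scale2=False,
                                              cutoff=False, k_groups=2))
        np.testing.assert_array_equal(res.matrix.values, bs.concatenate().values)
        assert sorted(res.row_order.tolist()) == list(range(bs.n_genes))

    def test_k_groups_exceeding_genes_rejected(self, fitted):
        bs, model = fitted
        with pytest.raises(ValueError, match="k_groups"):
            build_cim(bs, model, CimOptions(k_groups=1000))

    def test_cluster_labels_stable_under_gene_permutation(self, fitted):
        bs, model = fitted
        opt = CimOptions(denoise=True, scale2=True, cutoff=True, k_groups=3)
        res = build_cim(bs, model, opt)
        rng = np.random.default_rng(77)
        perm = rng.permutation(bs.n_genes)
        bs_p = BlockSet({name: b.take_genes(perm) for name, b in bs})
        model_p = fit_block_pls(bs_p, model.config)
        res_p = build_cim(bs_p, model_p, opt)
        from sklearn.metrics import adjusted_rand_score
        joined = pd.concat([res.clusters.rename("a"), res_p.clusters.rename("b")],
                           axis=1)
        assert adjusted_rand_score(joined.a, joined.b) == pytest.approx(1.0)

    def test_planted_typologies_recovered_at_k4(self):
        cfg = SimConfig(n_genes=600, n_drivers=10, missing_rate=0.0, seed=31)
        m, truth = simulate_dataset(cfg)
        from omiclink.preprocess import center_scale
        from omiclink.datamodel import split_blocks
        ms, _ = center_scale(m)
        bs = split_blocks(ms)
        model = fit_block_pls(bs, BlockPlsConfig(design=default_design(bs.names)))
        res = build_cim(bs, model, CimOptions(k_groups=4))
        score = scoreboard(truth, clusters=res.clusters)
        assert score["adjusted_rand_index"] >= 0.9


class TestClusterProfiles:
    def test_single_gene_group_profile_is_the_row(self, fitted):
        bs, model = fitted
        res = build_cim(bs, model, CimOptions(denoise=False, scale2=False,
                                              cutoff=False, k_groups=bs.n_genes))
        profiles = cluster_profiles(res)
        df = res.matrix.to_frame()
        for gene, group in res.clusters.items():
            np.testing.assert_allclose(
                profiles.loc[group].drop("n_genes").to_numpy(),
                df.loc[gene].to_numpy())

    def test_two_gene_group_averages(self):
        m = make_matrix(np.array([[0.0, 2.0], [2.0, 0.0]]), n_expr=1)
        clusters = pd.Series([1, 1], index=pd.Index(m.gene_ids, name="gene_id"))
        from omiclink.cim import CimResult
        res = CimResult(m, np.arange(2), np.arange(2), np.empty((0, 4)),
                        np.empty((0, 4)), clusters, CimOptions(k_groups=1))
        profiles = cluster_profiles(res)
        np.testing.assert_allclose(profiles.loc[1, ["expr_0", "meth_0"]], [1.0, 1.0])
        assert profiles.loc[1, "n_genes"] == 2

    def test_planted_pattern_signs_recovered(self):
        # group mean profiles on 4-typology data show the planted contrast:
        # the driver-free typology-1 group has high expression / low
        # methylation and typology-3 the reverse
        cfg = SimConfig(n_genes=400, n_drivers=0, missing_rate=0.0, seed=13)
        m, truth = simulate_dataset(cfg)
        from omiclink.preprocess import center_scale
        from omiclink.datamodel import split_blocks
        ms, _ = center_scale(m)
        bs = split_blocks(ms)
        model = fit_block_pls(bs, BlockPlsConfig(design=default_design(bs.names)))
        res = build_cim(bs, model, CimOptions(k_groups=4))
        profiles = cluster_profiles(res)
        # map each cluster to its dominant typology
        df = pd.concat([truth.typology, res.clusters], axis=1)
        dominant = df.groupby("group")["typology"].agg(lambda s: s.mode().iat[0])
        expr_cols = [v.name for v in res.matrix.variables if v.omic_type == "expression"]
        meth_cols = [v.name for v in res.matrix.variables if v.omic_type == "methylation"]
        g1 = dominant.index[dominant == 1][0]
        g3 = dominant.index[dominant == 3][0]
        assert profiles.loc[g1, expr_cols].mean() > 0 > profiles.loc[g1, meth_cols].mean()
        assert profiles.loc[g3, meth_cols].mean() > 0 > profiles.loc[g3, expr_cols].mean()
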