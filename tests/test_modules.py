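"""Module detection, eigengenes, merging, validation and hub calling."""

import numpy as np
import pandas as pd
import pytest

import corewire as cw
from corewire.modules import BACKGROUND, ModulePartition


def block_tom(sizes, within=0.9, between=0.01, seed=0):
    n = sum(sizes)
    rng = np.random.default_rng(seed)
    tom = np.full((n, n), between)
    start = 0
    truth = []
    for k, size in enumerate(sizes):
        tom[start:start + size, start:start + size] = within
        truth += [f"T{k}"] * size
        start += size
    tom += rng.uniform(0, 1e-4, size=(n, n))
    tom = (tom + tom.T) / 2
    np.fill_diagonal(tom, 1.0)
    genes = [f"g{i:03d}" for i in range(n)]
    return cw.TOMatrix(values=tom, gene_ids=genes, kind="plain"), pd.Series(truth, index=genes)


class TestClusterModules:
    def test_two_perfect_blocks(self):
        tom, truth = block_tom([50, 50])
        part = cw.cluster_modules(tom, min_module_size=30)
        assert len(part.labels) == 2
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, part.assignment) == pytest.approx(1.0)

    def test_all_equal_tom_is_degenerate_and_deterministic(self):
        n = 60
        tom = np.full((n, n), 0.3)
        np.fill_diagonal(tom, 1.0)
        t = cw.TOMatrix(values=tom, gene_ids=[f"g{i}" for i in range(n)])
        p1 = cw.cluster_modules(t, min_module_size=10)
        p2 = cw.cluster_modules(t, min_module_size=10)
        assert p1.assignment.equals(p2.assignment)
        assert len(p1.labels) <= 1  # no valid split: background or one module

    def test_tiny_input_all_background(self):
        tom, _ = block_tom([5])
        with pytest.warns(UserWarning):
            part = cw.cluster_modules(tom, min_module_size=30)
        assert set(part.assignment) == {BACKGROUND}

    def test_static_cut_height_mode(self):
        tom, truth = block_tom([40, 40])
        part = cw.cluster_modules(tom, min_module_size=20, cut_height=0.5)
        assert len(part.labels) == 2


class TestEigengene:
    def test_identical_genes(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(size=10)
        expr = pd.DataFrame([profile] * 5, index=[f"g{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(10)])
        eg, ve = cw.module_eigengene(expr, expr.index)
        assert ve == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(eg, z, atol=1e-9)

    def test_antisymmetric_pair_tie_break(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        expr = pd.DataFrame([x, -x], index=["a", "b"],
                            columns=[f"s{i}" for i in range(12)])
        eg, ve = cw.module_eigengene(expr, ["a", "b"])
        assert ve == pytest.approx(1.0)
        # mean standardized expression is 0; orientation follows first gene
        assert np.corrcoef(eg, x)[0, 1] > 0

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            expr = pd.DataFrame(rng.normal(size=(10, 9)),
                                index=[f"g{i}" for i in range(10)],
                                columns=[f"s{i}" for i in range(9)])
            eg, ve = cw.module_eigengene(expr, expr.index)
            X = expr.to_numpy()
            Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
            evals, evecs = np.linalg.eigh(Z.T @ Z)  # sample-space Gram matrix
            pc = evecs[:, -1]
            pc = pc / pc.std(ddof=1)
            agreement = abs(np.corrcoef(eg, pc)[0, 1])
            assert agreement == pytest.approx(1.0, abs=1e-9)
            assert ve == pytest.approx(evals[-1] / evals.sum(), abs=1e-9)

    def test_constant_gene_dropped(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(4, 8)),
                            index=list("abcd"), columns=[f"s{i}" for i in range(8)])
        expr.loc["c"] = 1.0
        with pytest.warns(UserWarning):
            eg, ve = cw.module_eigengene(expr, expr.index)
        assert np.isfinite(eg).all()


class TestMergeModules:
    def test_distinct_modules_unchanged(self, small_study):
        expr = small_study["expr_rna"].values
        truth = small_study["truth"].partition_rna.loc[expr.index]
        part = ModulePartition(assignment=truth.copy())
        merged, eigen, ve = cw.merge_modules(expr, part, merge_cut=0.1)
        assert sorted(merged.labels) == sorted(part.labels)

    def test_same_factor_modules_merge(self, small_study):
        expr = small_study["expr_rna"].values
        truth = small_study["truth"].partition_rna.loc[expr.index].copy()
        # split planted module M1 into two arbitrary halves
        m1 = list(truth.index[truth == "M1"])
        truth[m1[: len(m1) // 2]] = "M1a"
        truth[m1[len(m1) // 2:]] = "M1b"
        merged, _, _ = cw.merge_modules(expr, ModulePartition(assignment=truth))
        labels = merged.assignment[m1].unique()
        assert len(labels) == 1

    def test_label_permutation_invariance(self, small_study):
        expr = small_study["expr_rna"].values
        truth = small_study["truth"].partition_rna.loc[expr.index]
        part = ModulePartition(assignment=truth.copy())
        swap = {"M1": "M3", "M3": "M1"}
        part_sw = ModulePartition(assignment=truth.map(lambda l: swap.get(l, l)))
        a, _, _ = cw.merge_modules(expr, part)
        b, _, _ = cw.merge_modules(expr, part_sw)
        # same grouping of genes regardless of label names
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(a.assignment, b.assignment) == pytest.approx(1.0)


class TestValidation:
    def test_analytic_z_at_zero_proportion(self):
        # p_hat = 0 with n = 100 -> Z = -10 exactly
        z = (0.0 - 0.5) / np.sqrt(0.25 / 100)
        assert z == pytest.approx(-10.0)

    def test_planted_module_never_beaten_by_random(self, small_study):
        expr = small_study["expr_rna"].values
        truth = small_study["truth"].partition_rna.loc[expr.index]
        tom = cw.topological_overlap(cw.adjacency_from_expression(expr, 18.0),
                                     list(expr.index))
        val = cw.validate_modules(tom, ModulePartition(assignment=truth),
                                  n_resample=100, seed=0)
        planted = [m for m in val.table.index if m != BACKGROUND]
        assert (val.table.loc[planted, "n_random_higher"] == 0).all()
        assert np.allclose(val.table.loc[planted, "z"], -10.0)

    def test_random_module_near_null(self):
        rng = np.random.default_rng(4)
        n = 200
        X = rng.normal(size=(n, 12))
        tom = cw.topological_overlap(cw.signed_adjacency(np.corrcoef(X), 6.0),
                                     [f"g{i}" for i in range(n)])
        phats = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            lab = pd.Series(BACKGROUND, index=tom.gene_ids)
            lab.iloc[r.choice(n, 30, replace=False)] = "R"
            val = cw.validate_modules(tom, ModulePartition(assignment=lab),
                                      n_resample=50, seed=seed)
            phats.append(val.table.loc["R", "p_hat"])
        assert abs(np.mean(phats) - 0.5) < 0.15

    def test_relabeling_invariance(self, small_study):
        expr = small_study["expr_rna"].values
        truth = small_study["truth"].partition_rna.loc[expr.index]
        tom = cw.topological_overlap(cw.adjacency_from_expression(expr, 18.0),
                                     list(expr.index))
        v1 = cw.validate_modules(tom, ModulePartition(assignment=truth), 50, seed=3)
        swapped = truth.map(lambda l: {"M1": "ZZ"}.get(l, l))
        v2 = cw.validate_modules(tom, ModulePartition(assignment=swapped), 50, seed=3)
        assert v1.table.loc["M1", "z"] == pytest.approx(v2.table.loc["ZZ", "z"])


class TestConnectivityAndHubs:
    def test_complete_graph_module(self):
        n = 6
        adj = np.ones((n, n))
        part = ModulePartition(assignment=pd.Series(["A"] * n, index=[f"g{i}" for i in range(n)]))
        conn = cw.intramodular_connectivity(adj, part)
        assert np.allclose(conn["k_in"], n - 1)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(5)
        n = 40
        half = rng.uniform(0, 1, (n, n))
        adj = (half + half.T) / 2
        np.fill_diagonal(adj, 1.0)
        genes = [f"g{i}" for i in range(n)]
        lab = pd.Series(rng.choice(["A", "B", BACKGROUND], n), index=genes)
        conn = cw.intramodular_connectivity(adj, ModulePartition(assignment=lab))
        for i, g in enumerate(genes):
            expect = sum(adj[i, j] for j, h in enumerate(genes)
                         if j != i and lab[h] == lab[g])
            assert conn.loc[g, "k_in"] == pytest.approx(expect)

    def test_equal_connectivity_no_hubs(self):
        n = 8
        adj = np.ones((n, n))
        part = ModulePartition(assignment=pd.Series(["A"] * n, index=[f"g{i}" for i in range(n)]))
        conn = cw.find_hub_genes(cw.intramodular_connectivity(adj, part))
        assert not conn["is_hub"].any()

    def test_single_outlier_z_score(self):
        k = np.array([1.0] * 9 + [10.0])
        genes = [f"g{i}" for i in range(10)]
        conn = pd.DataFrame({"module": "A", "k_in": k, "hub_eligible": True}, index=genes)
        out = cw.find_hub_genes(conn)
        z_expected = (10 - k.mean()) / k.std(ddof=1)
        assert out.loc["g9", "z_k"] == pytest.approx(z_expected)
        assert z_expected == pytest.approx(2.846, abs=1e-3)
        assert out.loc["g9", "is_hub"]
        assert out["is_hub"].sum() == 1


def test_var_explained_increases_on_top_kme_half(small_study):
    """Restricting a coherent module to its best-correlated half cannot
    lower the eigengene's variance explained."""
    expr = small_study["expr_rna"].values
    truth = small_study["truth"].partition_rna.loc[expr.index]
    genes = list(truth.index[truth == "M1"])
    eg, ve_full = cw.module_eigengene(expr, genes)
    kme = {g: abs(np.corrcoef(expr.loc[g], eg)[0, 1]) for g in genes}
    top = sorted(genes, key=lambda g: -kme[g])[: len(genes) // 2]
    _, ve_top = cw.module_eigengene(expr, top)
    assert ve_top >= ve_full
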