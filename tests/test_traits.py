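"""Trait binarization, correlation p-values, kME/GS and gene selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

import corewire as cw
from corewire.modules import ModulePartition
from corewire.traits import CONTRASTS, binarize_traits, correlate


def study_metadata():
    """The 15-sample four-group design: swim 3+3, TAC 4+5."""
    cfg = cw.SynthConfig(n_genes=10, n_modules=1, module_sizes=(3,))
    from corewire.simulate import _metadata

    md = _metadata(cfg)
    md["hwbw"] = np.linspace(4.5, 7.5, len(md))
    return md


class TestBinarize:
    def test_design_counts(self):
        traits = binarize_traits(study_metadata())
        patho = traits.values["pathological_vs_physiological"]
        assert int(patho.sum()) == 9 and int((patho == 0).sum()) == 6
        tac2d = traits.values["tac2d_vs_swim2d"]
        assert tac2d.notna().sum() == 7  # 4 TAC vs 3 swim at 2 days
        assert int(tac2d.sum()) == 4
        tac2w = traits.values["tac2w_vs_swim2w"]
        assert tac2w.notna().sum() == 8  # 5 TAC vs 3 swim at 2 weeks
        assert traits.is_binary["pathological_vs_physiological"]
        assert not traits.is_binary["hwbw"]

    def test_degenerate_trait_excluded(self):
        md = study_metadata()
        md = md[md["group"] == "swim"]
        with pytest.warns(UserWarning):
            traits = binarize_traits(md)
        assert "pathological_vs_physiological" not in traits.values.columns

    def test_unknown_group_rejected(self):
        md = study_metadata()
        md.loc[md.index[0], "group"] = "sham"
        with pytest.raises(ValueError):
            binarize_traits(md)


class TestCorrelate:
    def test_zero_correlation_unit_p(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        y = y - np.polyval(np.polyfit(x, y, 1), x)  # exactly uncorrelated
        r, p = correlate(x, y, binary=True)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_perfect_correlation_floor_p(self):
        x = np.arange(10, dtype=float)
        r, p = correlate(x, 2 * x + 1, binary=True)
        assert r == pytest.approx(1.0)
        assert 0 < p < 1e-20

    def test_student_p_against_integration_oracle(self):
        # n=15, r=0.6: t = 0.6*sqrt(13/0.64), two-sided p from numerically
        # integrating the t density — independent of scipy.stats.t.sf
        n, r = 15, 0.6
        t_val = r * math.sqrt((n - 2) / (1 - r * r))
        assert t_val == pytest.approx(2.70415, abs=1e-4)
        df = n - 2
        dens = lambda u: (math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
                          * (1 + u * u / df) ** (-(df + 1) / 2))
        tail, _ = quad(dens, t_val, np.inf)
        p_oracle = 2 * tail
        assert p_oracle == pytest.approx(0.0181, abs=2e-4)
        # implementation path: build vectors with this exact correlation
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.normal(size=n)
            e = rng.normal(size=n)
            e = e - np.polyval(np.polyfit(x, e, 1), x)  # residualize
            xs = (x - x.mean()) / x.std()
            es = (e - e.mean()) / e.std()
            y = r * xs + math.sqrt(1 - r * r) * es
            rr, pp = correlate(x, y, binary=True)
            assert rr == pytest.approx(r, abs=1e-9)
            assert pp == pytest.approx(p_oracle, abs=1e-6)

    def test_constant_vector_flagged_missing(self):
        r, p = correlate(np.ones(10), np.arange(10.0), binary=True)
        assert math.isnan(r) and math.isnan(p)

    def test_pairwise_exclusion(self):
        x = np.array([1.0, 2, 3, np.nan, 5, 6])
        y = np.array([2.0, 4, 6, 8, 10, 12])
        r, _ = correlate(x, y, binary=True)
        assert r == pytest.approx(1.0)


class TestModuleTraitMatrix:
    def test_eigengene_equal_to_trait(self):
        rng = np.random.default_rng(1)
        md = study_metadata()
        hw = md["hwbw"].to_numpy()
        eigen = pd.DataFrame([hw + 1e-9 * rng.normal(size=len(hw))],
                             index=["M1"], columns=md.index)
        traits = binarize_traits(md)
        cor, p, p_bh = cw.module_trait_matrix(eigen, traits)
        assert cor.loc["M1", "hwbw"] == pytest.approx(1.0, abs=1e-4)
        assert p_bh.shape == p.shape

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(2)
        md = study_metadata()
        eigen = pd.DataFrame(rng.normal(size=(3, 15)),
                             index=["M1", "M2", "M3"], columns=md.index)
        traits = binarize_traits(md)
        cor1, _, _ = cw.module_trait_matrix(eigen, traits)
        perm = rng.permutation(15)
        md_p = md.iloc[perm]
        eigen_p = eigen.iloc[:, perm]
        cor2, _, _ = cw.module_trait_matrix(eigen_p, binarize_traits(md_p))
        assert np.allclose(cor1.to_numpy(), cor2.to_numpy(), atol=1e-12)

    def test_planted_effect_recovered(self, small_study):
        expr = small_study["expr_rna"].values
        truth = small_study["truth"].partition_rna.loc[expr.index]
        md = small_study["metadata"]
        eigen, _ = cw.eigengene_matrix(expr, ModulePartition(assignment=truth))
        traits = binarize_traits(md)
        cor, _, _ = cw.module_trait_matrix(eigen, traits)
        # planted effects: M1 +3 sd, M2 -3 sd on the pathological contrast
        patho = cor["pathological_vs_physiological"]
        assert abs(patho["M1"]) > 0.7
        assert abs(patho["M2"]) > 0.7
        assert np.sign(patho["M1"]) != np.sign(patho["M2"])


class TestMembershipAndSignificance:
    def test_gene_identical_to_eigengene(self, small_study):
        expr = small_study["expr_rna"].values
        truth = small_study["truth"].partition_rna.loc[expr.index]
        eigen, _ = cw.eigengene_matrix(expr, ModulePartition(assignment=truth))
        probe = pd.DataFrame([eigen.loc["M1"]], index=["probe"], columns=eigen.columns)
        kme = cw.module_membership(probe, eigen)
        assert kme.loc["probe", "M1"] == pytest.approx(1.0)

    def test_background_gene_kme_is_small(self):
        rng = np.random.default_rng(3)
        vals = []
        eigen_profile = rng.normal(size=15)
        eigen = pd.DataFrame([eigen_profile], index=["M1"],
                             columns=[f"s{i}" for i in range(15)])
        for seed in range(100):
            r = np.random.default_rng(seed + 100)
            g = pd.DataFrame(r.normal(size=(1, 15)), index=["g"], columns=eigen.columns)
            vals.append(abs(cw.module_membership(g, eigen).iloc[0, 0]))
        assert np.mean(vals) < 2 / math.sqrt(15) + 0.1

    def test_gs_of_trait_clone_is_one(self):
        md = study_metadata()
        traits = binarize_traits(md)
        g = pd.DataFrame([md["hwbw"]], index=["g"], columns=md.index)
        gs = cw.gene_significance(g, traits)
        assert gs.loc["g", "hwbw"] == pytest.approx(1.0)

    def test_own_module_kme_exceeds_other(self, small_study):
        expr = small_study["expr_rna"].values
        truth = small_study["truth"].partition_rna.loc[expr.index]
        eigen, _ = cw.eigengene_matrix(expr, ModulePartition(assignment=truth))
        kme = cw.module_membership(expr, eigen)
        m1 = truth.index[truth == "M1"]
        own = kme.loc[m1, "M1"].abs().median()
        other = kme.loc[m1, "M4"].abs().median()
        assert own > other


class TestRepresentativeGenes:
    def test_rank_agreement_upper_quartile(self):
        genes = [f"g{i}" for i in range(20)]
        vals = np.linspace(0.1, 0.9, 20)
        kme = pd.DataFrame({"M1": vals}, index=genes)
        gs = pd.DataFrame({"hwbw": vals}, index=genes)
        part = ModulePartition(assignment=pd.Series("M1", index=genes))
        sel = cw.select_representative_genes(kme, gs, part)
        expect = set(np.array(genes)[vals >= np.quantile(vals, 0.75)])
        assert set(sel["M1"]["genes"]) == expect
        assert sel["M1"]["trait"] == "hwbw"

    def test_tiny_module_hubs_only(self):
        genes = ["a", "b", "c"]
        kme = pd.DataFrame({"M1": [0.9, 0.8, 0.7]}, index=genes)
        gs = pd.DataFrame({"hwbw": [0.5, 0.4, 0.3]}, index=genes)
        part = ModulePartition(assignment=pd.Series("M1", index=genes))
        hubs = pd.DataFrame({"is_hub": [True, False, False]}, index=genes)
        with pytest.warns(UserWarning):
            sel = cw.select_representative_genes(kme, gs, part, hubs)
        assert sel["M1"]["genes"] == ["a"]

    def test_planted_module_yields_top_loading_genes(self, small_study):
        expr = small_study["expr_rna"].values
        gt = small_study["truth"]
        truth = gt.partition_rna.loc[expr.index]
        part = ModulePartition(assignment=truth)
        eigen, _ = cw.eigengene_matrix(expr, part)
        kme = cw.module_membership(expr, eigen)
        traits = binarize_traits(small_study["metadata"])
        gs = cw.gene_significance(expr, traits)
        sel = cw.select_representative_genes(kme, gs, part)
        m1 = [g for g in truth.index if truth[g] == "M1"]
        chosen = sel["M1"]["genes"]
        top_half = set(gt.loadings[m1].sort_values(ascending=False).index[: len(m1) // 2])
        overlap = len(set(chosen) & top_half) / max(len(chosen), 1)
        assert overlap >= 0.7


def test_permutation_null_p_uniformity():
    """Student p-values under label permutation are uniform (KS test)."""
    rng = np.random.default_rng(4)
    x = rng.normal(size=15)
    y = rng.normal(size=15)
    ps = []
    for _ in range(1000):
        perm = rng.permutation(15)
        _, p = correlate(x, y[perm], binary=False)
        ps.append(p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_module_ordering_anchors_pathology():
    cor = pd.DataFrame(
        {"pathological_vs_physiological": [0.9, -0.8, 0.1], "hwbw": [0.8, -0.7, 0.0]},
        index=["A", "B", "C"])
    mapping = cw.order_modules_by_trait(cor, prefix="RNA")
    assert set(mapping.values()) == {"RNA1", "RNA2", "RNA3"}
    # the most pathology-correlated module sits in the first half
    assert int(mapping["A"][3:]) <= 2
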