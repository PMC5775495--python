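import numpy as np
import pytest
from scipy import stats

from cropwild import popstats, simulate
from cropwild.genio import MISSING, AnalysisError, PopulationMap

from conftest import make_gm
from oracles import ld_prune_oracle, wc_fst_oracle, wc_fst_site_oracle


class TestWcFst:
    def test_complete_fixation_gives_one(self):
        gm = make_gm([[2]] * 6 + [[0]] * 6)
        r = popstats.wc_fst(gm, None, [f"s{i}" for i in range(6)],
                            [f"s{i}" for i in range(6, 12)], min_maf=0.0)
        assert r.theta_global == pytest.approx(1.0)

    def test_single_panmictic_population_is_near_zero(self):
        rng = np.random.default_rng(41)
        p = rng.uniform(0.1, 0.9, 5000)
        dosage = rng.binomial(2, p[None, :], size=(60, 5000)).astype(np.int16)
        gm = make_gm(dosage)
        a = [f"s{i}" for i in range(30)]
        b = [f"s{i}" for i in range(30, 60)]
        r = popstats.wc_fst(gm, None, a, b)
        assert abs(r.theta_global) < 0.01

    def test_matches_literal_oracle_on_toy(self, toy_two_pop):
        gm, pm, dosA, dosB = toy_two_pop
        r = popstats.wc_fst(gm, pm, "A", "B", min_maf=0.0)
        sitesA = [list(col) for col in np.array(dosA).T]
        sitesB = [list(col) for col in np.array(dosB).T]
        assert r.theta_global == pytest.approx(wc_fst_oracle(sitesA, sitesB), abs=1e-12)
        for j in range(3):
            a, b, c = wc_fst_site_oracle(sitesA[j], sitesB[j])
            assert r.a[j] == pytest.approx(a, abs=1e-12)
            assert r.b[j] == pytest.approx(b, abs=1e-12)
            assert r.c[j] == pytest.approx(c, abs=1e-12)

    def test_hand_checked_single_site(self):
        # popA (0,1,1,2,2,2), popB (0,0,0,1,1,0): theta = 19/55
        a, b, c = wc_fst_site_oracle([0, 1, 1, 2, 2, 2], [0, 0, 0, 1, 1, 0])
        assert a / (a + b + c) == pytest.approx(0.3454545454, abs=1e-9)
        gm = make_gm(np.array([[0, 1, 1, 2, 2, 2, 0, 0, 0, 1, 1, 0]]).T)
        r = popstats.wc_fst(gm, None, [f"s{i}" for i in range(6)],
                            [f"s{i}" for i in range(6, 12)], min_maf=0.0)
        assert r.theta_global == pytest.approx(0.3454545454, abs=1e-9)

    def test_symmetry(self, toy_two_pop):
        gm, pm, _, _ = toy_two_pop
        r1 = popstats.wc_fst(gm, pm, "A", "B", min_maf=0.0)
        r2 = popstats.wc_fst(gm, pm, "B", "A", min_maf=0.0)
        assert r1.theta_global == pytest.approx(r2.theta_global)

    def test_inclusive_site_filters(self):
        # exactly 3 genotyped per population and pooled MAF exactly 0.05
        # are retained (>=, unlike the strict global filter)
        colA = [1, 0, 0, MISSING, MISSING, MISSING]
        colB = [0, 0, 0, MISSING, MISSING, MISSING]
        gm = make_gm(np.array([colA + colB]).T)
        r = popstats.wc_fst(gm, None, [f"s{i}" for i in range(6)],
                            [f"s{i}" for i in range(6, 12)],
                            min_maf=1 / 12, min_ind=3)
        assert r.n_sites_used == 1
        with pytest.raises(AnalysisError):
            popstats.wc_fst(gm, None, [f"s{i}" for i in range(6)],
                            [f"s{i}" for i in range(6, 12)], min_ind=4)

    def test_consistency_across_divergence_levels(self):
        for target in (0.05, 0.15, 0.2, 0.35):
            cfg = simulate.SimConfig(n_sites=5000, fst_target=target,
                                     n_pure1=30, n_pure2=30, cross_spec=[],
                                     seed=100 + int(target * 100))
            gm, pm, _ = simulate.simulate_pair(cfg)
            r = popstats.wc_fst(gm, pm, "sp1_ref", "sp2_ref")
            assert abs(r.theta_global - target) < 0.03, target


class TestSiteHeterozygosity:
    def test_hand_values_and_flagging(self):
        gm = make_gm(np.array([
            [0, 1, 1, 2, 0, 0, 0, 0, 0, 0],   # 2/10 het
            [1, 1, 1, 1, 1, 1, 1, 0, 0, 2],   # 7/10 het -> flagged
        ]).T.reshape(10, 2))
        table, frac = popstats.site_heterozygosity(gm)
        assert table.het_obs.tolist() == pytest.approx([0.2, 0.7])
        assert table.flagged.tolist() == [False, True]
        assert frac == pytest.approx(0.5)

    def test_quartet_example(self):
        gm = make_gm(np.array([[0, 1, 1, 2]]).T.reshape(4, 1))
        table, _ = popstats.site_heterozygosity(gm)
        assert table.het_obs[0] == pytest.approx(0.5)
        assert not table.flagged[0]

    def test_hardy_weinberg_tail_fraction(self):
        # HW at p=0.5 with n diploids: P(flag) is the binomial tail P(X/n > 0.6)
        rng = np.random.default_rng(55)
        n, m = 20, 4000
        dosage = rng.binomial(2, 0.5, size=(n, m)).astype(np.int16)
        gm = make_gm(dosage)
        _, frac = popstats.site_heterozygosity(gm)
        expected = stats.binom.sf(int(0.6 * n), n, 0.5)  # P(X > 12)
        se = np.sqrt(expected * (1 - expected) / m)
        assert abs(frac - expected) < 4 * se


class TestLdPrune:
    def test_duplicate_column_collapses(self):
        rng = np.random.default_rng(61)
        col = rng.integers(0, 3, 30)
        gm = make_gm(np.column_stack([col, col, rng.integers(0, 3, 30)]))
        out = popstats.ld_prune(gm, r2_max=0.2)
        assert out.n_sites == 2
        assert out.sites.pos.tolist()[0] == gm.sites.pos[0]

    def test_independent_sites_mostly_kept(self):
        # truly unlinked sites in one panmictic population (pooling two
        # diverged populations would create real mixture LD); enough
        # samples that chance r^2 rarely tops 0.2
        rng = np.random.default_rng(62)
        p = rng.uniform(0.1, 0.9, 400)
        gm = make_gm(rng.binomial(2, p[None, :], size=(100, 400)).astype(np.int16))
        out = popstats.ld_prune(gm, r2_max=0.2)
        assert out.n_sites > 0.9 * gm.n_sites

    def test_toy_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(63)
        base = rng.integers(0, 3, 40)
        cols = [
            base,
            np.clip(base + rng.integers(0, 2, 40), 0, 2),  # correlated with 0
            rng.integers(0, 3, 40),
            base[::-1],
            np.clip(2 - base, 0, 2),                        # anti-correlated with 0
        ]
        gm = make_gm(np.column_stack(cols))
        out = popstats.ld_prune(gm, r2_max=0.2, window=5)
        oracle_idx = ld_prune_oracle(gm, 0.2)
        assert out.sites.pos.tolist() == gm.sites.pos.iloc[oracle_idx].tolist()

    def test_idempotent_subset(self):
        gm = simulate.simulate_pair(
            simulate.SimConfig(n_sites=150, seed=64, cross_spec=[])
        )[0]
        once = popstats.ld_prune(gm, r2_max=0.3)
        twice = popstats.ld_prune(once, r2_max=0.3)
        assert once == twice
        assert set(once.sites.pos) <= set(gm.sites.pos)


class TestPca:
    def test_pure_clusters_separate_and_f1_intermediate(self):
        cfg = simulate.SimConfig(n_sites=800, fst_target=0.3, seed=71,
                                 cross_spec=[("F1", 5)])
        gm, pm, _ = simulate.simulate_pair(cfg)
        coords, frac = popstats.pca(gm)
        pc1 = coords["PC1"]
        sp1 = pc1[[s for s in gm.sample_ids if s.startswith("sp1")]]
        sp2 = pc1[[s for s in gm.sample_ids if s.startswith("sp2")]]
        hyb = pc1[[s for s in gm.sample_ids if s.startswith("hyb")]]
        lo_cluster, hi_cluster = (sp1, sp2) if sp1.mean() < sp2.mean() else (sp2, sp1)
        assert lo_cluster.max() < hi_cluster.min()  # clusters fully separate
        assert (hyb > lo_cluster.mean()).all() and (hyb < hi_cluster.mean()).all()
        assert frac.sum() <= 1.0 + 1e-9

    def test_pc1_tracks_true_ancestry(self):
        cfg = simulate.SimConfig(n_sites=1500, fst_target=0.5, seed=72,
                                 cross_spec=[("F1", 6), ("F2", 6), ("BC1", 6), ("BC2", 6)])
        gm, pm, truth = simulate.simulate_pair(cfg)
        coords, _ = popstats.pca(gm)
        merged = truth.set_index("sample").join(coords)
        r = np.corrcoef(merged.true_S, merged.PC1)[0, 1]
        assert abs(r) > 0.99

    def test_degenerate_input_is_fatal(self):
        with pytest.raises(AnalysisError):
            popstats.pca(make_gm([[0, 1]]))
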