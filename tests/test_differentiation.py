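"""Differentiation statistics, permutation tests, AMOVA, PCoA, Mantel."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import coralpopgen as cp
from coralpopgen import GenotypeTable
from coralpopgen.differentiation import (
    CodedTable,
    allele_mismatch_matrix,
    amova,
    d_jost_value,
    gst_hedrick_value,
    haversine_km,
    mantel_ibd,
    pcoa,
    permute_significance,
    theta_wc_value,
)
from coralpopgen.diversity import heterozygosity
from coralpopgen.simdata import SimConfig, island_kernel, simulate
from oracles import d_jost_direct, gst_hedrick_direct, theta_anova


def two_site_random(seed, n1=10, n2=10, n_loci=2, alleles=(100, 102, 104, 106)):
    rng = np.random.default_rng(seed)
    calls = rng.choice(alleles, size=(n1 + n2, n_loci, 2))
    return GenotypeTable(
        [f"i{k}" for k in range(n1 + n2)],
        [f"L{j}" for j in range(n_loci)],
        calls,
        np.array(["a"] * n1 + ["b"] * n2, dtype=object),
    )


def stat_of(table, func):
    coded = CodedTable(table)
    sites = table.site_ids()
    return func(coded, coded.labels_for(sites), len(sites))


class TestThetaWC:
    def test_identical_sites_near_zero(self):
        rows = np.array(
            [[[100, 102]], [[100, 100]], [[102, 102]], [[100, 102]], [[100, 102]]]
        )
        block = np.concatenate([rows] * 4)  # 20 individuals per site
        calls = np.concatenate([block, block])
        t = GenotypeTable(
            [f"i{k}" for k in range(40)],
            ["L"],
            calls,
            np.array(["a"] * 20 + ["b"] * 20, dtype=object),
        )
        val = stat_of(t, theta_wc_value)
        assert val <= 0.0  # identical lists cannot look differentiated
        assert abs(val) < 0.06

    def test_fixed_differences_give_one(self):
        calls = np.array([[[100, 100]]] * 5 + [[[104, 104]]] * 5)
        t = GenotypeTable(
            [f"i{k}" for k in range(10)],
            ["L"],
            calls,
            np.array(["a"] * 5 + ["b"] * 5, dtype=object),
        )
        assert stat_of(t, theta_wc_value) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_anova_oracle(self, seed):
        t = two_site_random(seed)
        expected = theta_anova([t.calls[:10], t.calls[10:]])
        got = stat_of(t, theta_wc_value)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-10)

    def test_site_order_invariance(self, sole_preset):
        table, _, _ = sole_preset
        coded = CodedTable(table)
        sites = table.site_ids()
        a = theta_wc_value(coded, coded.labels_for(sites), len(sites))
        rev = list(reversed(sites))
        b = theta_wc_value(coded, coded.labels_for(rev), len(sites))
        assert a == pytest.approx(b, abs=1e-12)


class TestGstAndJostD:
    def oracle_stats(self, table):
        sites = table.site_ids()
        freqs, n_i, ho = [], [], []
        alleles = sorted(set(table.calls[table.calls > 0].ravel().tolist()))
        for s in sites:
            idx = table.site_indices(s)
            calls = table.calls[idx, 0, :]
            n_i.append(len(calls))
            counts = np.array([(calls == a).sum() for a in alleles], dtype=float)
            freqs.append(counts / counts.sum())
            ho.append(float(np.mean(calls[:, 0] != calls[:, 1])))
        return freqs, np.array(n_i, dtype=float), np.array(ho)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(2)
        base = rng.choice([100, 102, 104], size=(30, 1, 2))
        calls = np.concatenate([base, base])
        t = GenotypeTable(
            [f"i{k}" for k in range(60)],
            ["L"],
            calls,
            np.array(["a"] * 30 + ["b"] * 30, dtype=object),
        )
        assert abs(stat_of(t, gst_hedrick_value)) < 0.08
        assert abs(stat_of(t, d_jost_value)) < 0.08

    def test_fixed_distinct_alleles_give_one(self):
        calls = np.array([[[100, 100]]] * 8 + [[[104, 104]]] * 8)
        t = GenotypeTable(
            [f"i{k}" for k in range(16)],
            ["L"],
            calls,
            np.array(["a"] * 8 + ["b"] * 8, dtype=object),
        )
        assert stat_of(t, gst_hedrick_value) == pytest.approx(1.0, abs=1e-9)
        assert stat_of(t, d_jost_value) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_match_direct_formula_oracles(self, seed):
        t = two_site_random(seed, n_loci=1)
        freqs, n_i, ho = self.oracle_stats(t)
        assert stat_of(t, gst_hedrick_value) == pytest.approx(
            gst_hedrick_direct(freqs, n_i, ho), abs=1e-10
        )
        assert stat_of(t, d_jost_value) == pytest.approx(
            d_jost_direct(freqs, n_i, ho), abs=1e-10
        )


class TestPermutation:
    def test_p_equals_one_when_observed_is_minimal(self):
        # constant statistic: every permuted value ties the observed one
        def const_stat(coded, labels, k):
            return 0.5

        t = two_site_random(0)
        coded = CodedTable(t)
        _, p = permute_significance(
            const_stat, coded, coded.labels_for(["a", "b"]), 2, n_perm=99, seed=0
        )
        assert p == 1.0

    def test_identical_sites_rarely_significant(self):
        rng = np.random.default_rng(4)
        ps = []
        for rep in range(20):
            base = rng.choice([100, 102, 104, 106], size=(15, 3, 2))
            calls = np.concatenate([base, base])
            t = GenotypeTable(
                [f"i{k}" for k in range(30)],
                ["L1", "L2", "L3"],
                calls,
                np.array(["a"] * 15 + ["b"] * 15, dtype=object),
            )
            coded = CodedTable(t)
            _, p = permute_significance(
                theta_wc_value, coded, coded.labels_for(["a", "b"]), 2,
                n_perm=99, seed=rep,
            )
            ps.append(p)
        assert np.mean([p > 0.5 for p in ps]) >= 0.8

    def test_single_group_rejected(self):
        t = two_site_random(0)
        coded = CodedTable(t)
        with pytest.raises(ValueError):
            permute_significance(
                theta_wc_value, coded, np.zeros(20, dtype=int), 1, 99, 0
            )

    def test_seeded_reproducibility(self, sole_preset):
        table, _, _ = sole_preset
        res1 = cp.differentiation(table, n_perm=99, seed=7, pairwise=False)
        res2 = cp.differentiation(table, n_perm=99, seed=7, pairwise=False)
        assert res1.global_p == res2.global_p


class TestAmova:
    def build(self, seed=0, shift=0):
        rng = np.random.default_rng(seed)
        calls = []
        sites = []
        for s in range(4):
            pool = [100 + 2 * s * shift, 102 + 2 * s * shift, 104]
            calls.append(rng.choice(pool, size=(8, 2, 2)))
            sites += [f"s{s}"] * 8
        return GenotypeTable(
            [f"i{k}" for k in range(32)],
            ["L1", "L2"],
            np.concatenate(calls),
            np.array(sites, dtype=object),
        )

    def test_identical_sites_components_near_zero(self):
        rng = np.random.default_rng(1)
        base = rng.choice([100, 102], size=(30, 2, 2))
        calls = np.concatenate([base] * 4)
        t = GenotypeTable(
            [f"i{k}" for k in range(120)],
            ["L1", "L2"],
            calls,
            np.array(sum([[f"s{s}"] * 30 for s in range(4)], []), dtype=object),
        )
        res = amova(t, {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2"}, n_perm=99)
        assert res.sigma_among_groups == pytest.approx(0.0, abs=1e-9)
        assert abs(res.phi_st) < 0.06

    def test_components_sum_to_total(self):
        t = self.build(seed=3, shift=1)
        res = amova(t, {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2"}, n_perm=99)
        d2 = allele_mismatch_matrix(t)
        # reconstruct total variance from the SS identity
        total = res.sigma_among_groups + res.sigma_among_sites + res.sigma_within
        assert total > 0
        assert -1 <= res.phi_ct <= 1 and -1 <= res.phi_sc <= 1

    def test_collapsed_hierarchy_matches_single_level(self):
        # each group holds exactly one site: Phi_ST should match the
        # one-level analysis of the same distances
        t = self.build(seed=5, shift=2)
        g_unique = {f"s{s}": f"g{s}" for s in range(4)}
        g_paired = {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2"}
        res_u = amova(t, g_unique, n_perm=99)
        res_p = amova(t, g_paired, n_perm=99)
        assert res_u.phi_ct == pytest.approx(res_p.phi_st, abs=0.25)

    def test_requires_two_groups(self):
        t = self.build()
        with pytest.raises(ValueError):
            amova(t, {f"s{s}": "g" for s in range(4)})


class TestPcoa:
    def test_equilateral_triangle(self):
        d = pd.DataFrame(
            1.0 - np.eye(3), index=list("abc"), columns=list("abc")
        )
        coords, frac = pcoa(d)
        assert coords.shape[1] == 2
        assert frac[0] == pytest.approx(frac[1], abs=1e-9)
        for i in range(3):
            for j in range(i + 1, 3):
                dist = np.linalg.norm(coords.iloc[i] - coords.iloc[j])
                assert dist == pytest.approx(1.0, abs=1e-9)

    def test_planted_coordinates_roundtrip(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, _ = pcoa(d)
        rec = coords.to_numpy()
        d2 = np.linalg.norm(rec[:, None] - rec[None, :], axis=2)
        assert np.allclose(d, d2, atol=1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_depth_clusters_recovered(self, desmo_preset):
        from sklearn.cluster import KMeans
        from sklearn.metrics import adjusted_rand_score

        table, meta, _ = desmo_preset
        res = cp.differentiation(table, n_perm=99, seed=0, pairwise=True)
        coords, _ = pcoa(res.pairwise.clip(lower=0.0))
        km = KMeans(n_clusters=3, n_init=10, random_state=0).fit(
            coords.iloc[:, :2].to_numpy()
        )
        strata = meta.set_index("site_id").loc[coords.index, "stratum"]
        ari = adjusted_rand_score(strata, km.labels_)
        assert ari > 0.9


class TestMantel:
    def fake_meta(self, sites):
        return pd.DataFrame(
            {
                "site_id": sites,
                "seamount": ["X"] * len(sites),
                "region": ["r"] * len(sites),
                "lat": np.linspace(-44, -43, len(sites)),
                "lon": np.linspace(147, 148.5, len(sites)),
                "depth_m": [1000] * len(sites),
                "stratum": ["mid"] * len(sites),
                "fished": [False] * len(sites),
            }
        )

    def test_proportional_matrices_give_r2_one(self):
        sites = list("abcde")
        meta = self.fake_meta(sites)
        n = len(sites)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                dist[i, j] = haversine_km(
                    meta["lat"][i], meta["lon"][i], meta["lat"][j], meta["lon"][j]
                )
        fst = pd.DataFrame(dist * 1e-4, index=sites, columns=sites)
        res = mantel_ibd(fst, meta, n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_missing_coordinates_listed(self):
        sites = list("abcd")
        fst = pd.DataFrame(np.zeros((4, 4)), index=sites, columns=sites)
        meta = self.fake_meta(["a", "b", "c", "x"])
        with pytest.raises(ValueError, match="d"):
            mantel_ibd(fst, meta)

    def test_independent_fst_calibration(self):
        rng = np.random.default_rng(8)
        sites = list("abcdef")
        meta = self.fake_meta(sites)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            m = np.zeros((6, 6))
            iu = np.triu_indices(6, 1)
            vals = rng.random(len(iu[0]))
            m[iu] = vals
            m += m.T
            fst = pd.DataFrame(m, index=sites, columns=sites)
            if mantel_ibd(fst, meta, n_perm=99, seed=int(rng.integers(1 << 30))).p_value <= 0.05:
                hits += 1
        assert abs(hits / n_rep - 0.05) < 0.03

    def test_stepping_stone_detected(self):
        # migration only between neighbours along a line of demes
        hits = 0
        reps = 5
        for rep in range(reps):
            D = 6
            k = np.zeros((D, D))
            for j in range(D):
                k[j, j] = 0.9
                if j > 0:
                    k[j - 1, j] = 0.05
                if j < D - 1:
                    k[j + 1, j] = 0.05
            k[0, 0] = 0.95
            k[D - 1, D - 1] = 0.95
            cfg = SimConfig(
                n_demes=D,
                deme_size=40,
                generations=300,
                migration=k.tolist(),
                n_loci=8,
                mutation_rate=6e-3,
                sample_size=25,
                seed=50 + rep,
            )
            table, meta, _ = simulate(cfg)
            res = cp.differentiation(table, n_perm=99, seed=rep, pairwise=True)
            ibd = mantel_ibd(res.pairwise, meta, n_perm=199, seed=rep)
            if ibd.p_value <= 0.05:
                hits += 1
        assert hits >= int(0.8 * reps)


class TestPanmicticInvariant:
    def test_all_statistics_near_zero_on_panmictic_split(self):
        cfg = SimConfig(
            n_demes=1,
            deme_size=150,
            generations=40,
            migration=[[1.0]],
            n_loci=9,
            mutation_rate=5e-3,
            sample_size=100,
            seed=123,
        )
        table, _, _ = simulate(cfg)
        table.sites[:50] = "x"
        table.sites[50:] = "y"
        for func in (theta_wc_value, gst_hedrick_value, d_jost_value):
            val = stat_of(table, func)
            assert abs(val) < 0.02


class TestIslandOrdering:
    def test_theta_decreases_with_gene_flow(self):
        means = []
        grid = (0.1, 1.0, 10.0, 100.0)
        for fournm in grid:
            vals = []
            for rep in range(5):
                m = min(0.45, fournm / (4 * 50))
                cfg = SimConfig(
                    n_demes=4,
                    deme_size=50,
                    generations=300,
                    migration=island_kernel(4, m),
                    n_loci=6,
                    mutation_rate=1e-3,
                    sample_size=25,
                    seed=int(fournm * 100) + rep,
                )
                table, _, _ = simulate(cfg)
                vals.append(stat_of(table, theta_wc_value))
            means.append(np.mean(vals))
        rho = stats.spearmanr(grid, means).statistic
        assert rho == -1.0
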