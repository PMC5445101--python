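"""Synthetic genotypes and the simulation design (causal sets, scenarios)."""

import numpy as np
import pandas as pd
import pytest

import gblupset as gs
from gblupset.simulate import (DILUTION_GRID, FULL_PANEL_M, scenario_grid,
                               select_causal_sets, simulate_genotypes)


def test_inbred_genotypes_have_no_heterozygotes(small_geno):
    assert not np.any(small_geno.A == 1)
    assert set(np.unique(small_geno.A)) <= {0, 2}


def test_realized_maf_floor(small_geno):
    assert small_geno.p.min() >= 0.05
    assert small_geno.p.max() <= 0.5


def test_outbred_mode_produces_heterozygotes():
    g = simulate_genotypes(100, 600, inbred=False, seed=4)
    assert np.any(g.A == 1)


def test_block_ld_structure():
    """Mean within-block r^2 exceeds between-block r^2."""
    g = simulate_genotypes(200, 3000, block_len=50, seed=9)
    W = g.W
    rng = np.random.default_rng(0)
    within, between = [], []
    for _ in range(300):
        b = rng.integers(0, 3000 // 50)
        i, j = rng.integers(0, 50, size=2)
        if i != j:
            within.append(np.corrcoef(W[:, b * 50 + i], W[:, b * 50 + j])[0, 1] ** 2)
        k, l = rng.integers(0, 3000, size=2)
        if abs(k - l) > 100:
            between.append(np.corrcoef(W[:, k], W[:, l])[0, 1] ** 2)
    assert np.mean(within) > 5 * np.mean(between)


def test_requested_marker_count_and_chromosomes():
    g = simulate_genotypes(50, 1000, n_chrom=4, seed=2)
    assert g.n_markers == 1000
    assert len(np.unique(g.chrom)) == 4
    # sorted by (chrom block, position)
    for c in np.unique(g.chrom):
        pos = g.pos[g.chrom == c]
        assert np.all(np.diff(pos) > 0)


def test_degenerate_maf_range_rejected():
    with pytest.raises(ValueError):
        simulate_genotypes(50, 1000, maf_range=(0.5, 0.1))


def test_causal_set_sizes_and_disjointness(small_geno):
    cc = select_causal_sets(small_geno, "random", seed=5, n_c1=50, n_c2=200,
                            null_set_sizes=(30,), n_null_per_size=3)
    assert cc.C1.size == 50 and cc.C2.size == 200
    assert np.intersect1d(cc.C1, cc.C2).size == 0
    for ns in cc.null_sets:
        assert np.intersect1d(ns, cc.causal).size == 0


def test_default_causal_sets_match_design():
    g = simulate_genotypes(60, 18000, seed=3)
    cc = select_causal_sets(g, "random", seed=1)
    assert cc.C1.size == 100 and cc.C2.size == 900
    assert len(cc.null_sets) == 50
    sizes = sorted({ns.size for ns in cc.null_sets})
    assert sizes == [100, 500, 1000, 5000, 10000]


def test_cluster_model_regions(small_geno):
    cc = select_causal_sets(small_geno, "cluster", seed=6, n_c1=40, n_c2=100,
                            null_set_sizes=(), n_cluster_regions=8,
                            cluster_region_span=30)
    assert len(cc.cluster_regions) == 8
    allr = np.concatenate(cc.cluster_regions)
    assert len(np.unique(allr)) == 8 * 30  # disjoint regions
    for r in cc.cluster_regions:
        assert np.all(np.diff(r) == 1)  # consecutive markers
        assert len(set(small_geno.chrom[r])) == 1  # within one chromosome
        assert np.isin(cc.C1, r).sum() == 5  # 40/8 per region


def test_full_panel_proportion_scaling():
    g = simulate_genotypes(50, 1000, seed=8)
    cc = select_causal_sets(g, "random", seed=1, n_c1=10, n_c2=20,
                            null_set_sizes=(100, 500), n_null_per_size=1,
                            full_panel_proportions=True)
    exp = [max(10, round(100 * 1000 / FULL_PANEL_M)), max(10, round(500 * 1000 / FULL_PANEL_M))]
    assert sorted(ns.size for ns in cc.null_sets) == sorted(exp)


def test_phenotype_variance_near_target(small_geno):
    vs = []
    for s in range(20):
        cc = select_causal_sets(small_geno, "random", seed=100 + s, n_c1=50,
                                n_c2=200, null_set_sizes=())
        sc = gs.SimulationScenario(h2=0.5, hf2=0.3, n_rep=10, seed=200 + s)
        ph = gs.simulate_phenotypes(small_geno, cc, sc)
        vs.append(ph["value"].var(ddof=1))
    assert np.mean(vs) == pytest.approx(100, abs=15)


def test_zero_heritability_is_pure_noise(small_geno):
    cc = select_causal_sets(small_geno, "random", seed=1, n_c1=50, n_c2=200,
                            null_set_sizes=())
    sc = gs.SimulationScenario(h2=0.0, hf2=0.5, n_rep=4, seed=2)
    ph = gs.simulate_phenotypes(small_geno, cc, sc)
    line_means = ph.groupby("line_index")["value"].mean()
    # no line effect beyond noise: between-line variance ~ sigma_e^2 / n_rep
    assert line_means.var() < 3 * 100 / 4


def test_feature_variance_share_matches_hf2(small_geno):
    """Realized var(g1)/(var(g1)+var(g2)) ~ hf2 over repeated draws."""
    from gblupset.simulate import _draw_mvn

    cc = select_causal_sets(small_geno, "random", seed=3, n_c1=50, n_c2=200,
                            null_set_sizes=())
    g1m = gs.build_grm(small_geno, cc.C1)
    g2m = gs.build_grm(small_geno, cc.C2)
    sc = gs.SimulationScenario(h2=0.5, hf2=0.3, n_rep=1, seed=0)
    shares = []
    rng = np.random.default_rng(11)
    for _ in range(50):
        g1 = _draw_mvn(g1m, sc.sigma_g1_2, rng)
        g2 = _draw_mvn(g2m, sc.sigma_g2_2, rng)
        shares.append(g1.var() / (g1.var() + g2.var()))
    assert np.mean(shares) == pytest.approx(0.3, abs=0.05)


def test_scenario_variance_arithmetic():
    sc = gs.SimulationScenario(h2=0.3, hf2=0.2, sigma_P2=100.0)
    assert sc.sigma_g1_2 == pytest.approx(6.0)
    assert sc.sigma_g2_2 == pytest.approx(24.0)
    assert sc.sigma_e2 == pytest.approx(70.0)
    assert sc.sigma_g1_2 + sc.sigma_g2_2 + sc.sigma_e2 == pytest.approx(100.0)


def test_full_factorial_grid_enumerates_1440_cells():
    grid = scenario_grid()
    assert len(grid) == 1440
    assert len(DILUTION_GRID) == 20


def test_reduced_grid_product():
    grid = scenario_grid(h2_values=(0.1, 0.5), hf2_values=(0.1, 0.2),
                         n_rep_values=(5, 10), causal_models=("random",),
                         dilution_values=(0, 100, 200))
    assert len(grid) == 24


def test_dilution_feature_properties(small_geno):
    cc = select_causal_sets(small_geno, "random", seed=5, n_c1=50, n_c2=200,
                            null_set_sizes=())
    f0 = gs.dilute_feature(cc, 0, small_geno.n_markers, seed=1)
    np.testing.assert_array_equal(np.sort(f0.marker_idx), np.sort(cc.C1))
    f = gs.dilute_feature(cc, 80, small_geno.n_markers, seed=1)
    assert f.m_f == 50 + 80
    assert np.intersect1d(f.marker_idx, cc.C2).size == 0
    assert np.isin(cc.C1, f.marker_idx).all()


def test_run_scenario_grid_deterministic(small_geno):
    scs = scenario_grid(h2_values=(0.5,), hf2_values=(0.5,), n_rep_values=(5,),
                        causal_models=("random",), dilution_values=(0, 100))
    kw = dict(n_datasets=1, n_perm=150, statistics=("cvat",), seed=13)
    a = gs.run_scenario_grid(small_geno, scs, **kw)
    b = gs.run_scenario_grid(small_geno, scs, **kw)
    pd.testing.assert_frame_equal(a, b)
    assert set(a["dilution"]) == {0, 100}


def test_genotype_generation_deterministic():
    a = simulate_genotypes(30, 600, seed=5)
    b = simulate_genotypes(30, 600, seed=5)
    np.testing.assert_array_equal(a.A, b.A)
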