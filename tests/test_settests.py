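"""Set statistics: algebraic identities, dual formulas, parametric nulls."""

import numpy as np
import pytest
from scipy import stats

import gblupset as gs
from gblupset.effects import MarkerEffects
from gblupset.settests import (FeatureSet, count_test, cvat, cvat_decompose,
                               mt_cvat, per_marker_contributions,
                               satterthwaite_gamma_p, score_test, sum_test)


@pytest.fixture(scope="module")
def feature(sim_dataset):
    return FeatureSet("C1", sim_dataset["causal"].C1)


def test_cvat_contributions_sum_to_covariance(sim_dataset, feature):
    """3-line-style identity at scale: sum_f c_i == g_hat' g_hat_f (direct)."""
    eff, geno = sim_dataset["effects"], sim_dataset["geno"]
    c = per_marker_contributions(eff, geno, "cvat")
    f = feature.marker_idx
    g_f = geno.W[:, f] @ eff.s_hat[f]
    assert c[f].sum() == pytest.approx(float(eff.g_hat @ g_f), abs=1e-10)


def test_cvat_full_genome_equals_norm_of_ghat(sim_dataset):
    eff, geno = sim_dataset["effects"], sim_dataset["geno"]
    c = per_marker_contributions(eff, geno, "cvat")
    assert c.sum() == pytest.approx(float(eff.g_hat @ eff.g_hat), rel=1e-10)
    assert c.sum() >= 0


def test_cvat_decomposition_routes_agree(sim_dataset, feature):
    res = cvat(sim_dataset["effects"], sim_dataset["geno"], feature)
    assert res.extras["decomposition_gap"] < 1e-10 * max(1, abs(res.observed))
    assert res.observed == pytest.approx(res.extras["T_ff"] + res.extras["T_rf"], abs=1e-9)


def test_score_quadratic_form_equals_residual_form(sim_dataset, feature):
    """Dense (y-Xb)'V^-1 G_f V^-1 (y-Xb)/2 == e' Z G_f Z' e / 2."""
    fit, geno = sim_dataset["fit"], sim_dataset["geno"]
    y, lines = sim_dataset["y"], sim_dataset["lines"]
    n = y.size
    Z = np.zeros((n, fit.grm_.n))
    Z[np.arange(n), lines] = 1.0
    Gf = gs.build_grm(geno, feature.marker_idx).G
    V = fit.sigma_g2_ * Z @ fit.grm_.G @ Z.T + fit.sigma_e2_ * np.eye(n)
    Vi = np.linalg.inv(V)
    r = y - np.ones(n) * fit.beta_[0]
    T_quad = 0.5 * r @ Vi @ Z @ Gf @ Z.T @ Vi @ r
    res = score_test(fit, geno, feature, effects=sim_dataset["effects"])
    assert res.observed == pytest.approx(T_quad, rel=1e-8)


def test_score_equals_per_marker_expansion(sim_dataset, feature):
    eff, geno = sim_dataset["effects"], sim_dataset["geno"]
    q = per_marker_contributions(eff, geno, "score")
    T = q[feature.marker_idx].sum() / (2 * feature.m_f)
    res = score_test(sim_dataset["fit"], geno, feature, effects=eff)
    assert res.observed == pytest.approx(T, rel=1e-10)


def test_score_zero_residuals_give_zero(sim_dataset, feature):
    eff = sim_dataset["effects"]
    eff0 = MarkerEffects(
        s_hat=eff.s_hat, var_s=eff.var_s, df_e=eff.df_e,
        marker_idx=eff.marker_idx, g_hat=eff.g_hat,
        e_lines=np.zeros_like(eff.e_lines), obs_lines=eff.obs_lines,
    )
    q = per_marker_contributions(eff0, sim_dataset["geno"], "score")
    assert np.all(q == 0)


def test_score_exclude_feature_null_refits(sim_dataset, feature):
    res = score_test(sim_dataset["fit"], sim_dataset["geno"], feature,
                     null_model="exclude_feature")
    assert res.observed > 0
    all_markers = FeatureSet("all", np.arange(sim_dataset["geno"].n_markers))
    with pytest.raises(ValueError):
        score_test(sim_dataset["fit"], sim_dataset["geno"], all_markers,
                   null_model="exclude_feature")


def test_sum_test_matches_naive_loop(sim_dataset, feature):
    eff = sim_dataset["effects"]
    for basis, vec in (("s2", eff.s_hat), ("t2", eff.t_stat)):
        res = sum_test(eff, feature, basis=basis)
        naive = sum(float(vec[i]) ** 2 for i in feature.marker_idx)
        assert res.observed == pytest.approx(naive, rel=1e-12)
    single = FeatureSet("one", feature.marker_idx[:1])
    res = sum_test(eff, single, basis="s2")
    assert res.observed == pytest.approx(float(eff.s_hat[single.marker_idx[0]] ** 2))


def test_count_hypergeometric_exact_enumeration():
    """m=10, m_a=4, m_f=5, T=3 -> P(X>=3) = 66/252."""
    t = np.zeros(10)
    t[[0, 1, 2, 7]] = 5.0  # 4 associated markers, 3 inside the feature
    eff = MarkerEffects(s_hat=t, var_s=np.ones(10), df_e=20.0,
                        marker_idx=np.arange(10), g_hat=np.zeros(2))
    gs.marker_t_stats(eff)
    feat = FeatureSet("f", np.array([0, 1, 2, 3, 4]))
    res = count_test(eff, feat, t0=1.0, t0_kind="t")
    assert res.observed == 3
    assert res.m_a == 4
    assert res.p_parametric == pytest.approx(66 / 252, abs=1e-12)


def test_count_all_hits_inside_feature_minimal_p():
    t = np.zeros(12)
    t[[2, 3, 4]] = 9.0
    eff = MarkerEffects(s_hat=t, var_s=np.ones(12), df_e=20.0,
                        marker_idx=np.arange(12), g_hat=np.zeros(2))
    gs.marker_t_stats(eff)
    feat = FeatureSet("f", np.array([2, 3, 4]))
    res = count_test(eff, feat, t0=1.0, t0_kind="t")
    # P(X >= 3) for Hyper(12, 3, 3) = 1 / C(12,3)
    assert res.p_parametric == pytest.approx(1 / 220, abs=1e-12)


def test_count_no_marker_exceeds_threshold():
    eff = MarkerEffects(s_hat=np.zeros(10), var_s=np.ones(10), df_e=20.0,
                        marker_idx=np.arange(10), g_hat=np.zeros(2))
    gs.marker_t_stats(eff)
    feat = FeatureSet("f", np.arange(5))
    with pytest.warns(UserWarning):
        res = count_test(eff, feat, t0=10.0, t0_kind="t")
    assert res.observed == 0 and res.p_parametric == 1.0


def test_count_p_cutoff_matches_t_quantile(sim_dataset, feature):
    eff = sim_dataset["effects"]
    res_p = count_test(eff, feature, t0=0.05, t0_kind="p")
    n_below = int((eff.p_single[feature.marker_idx] < 0.05).sum())
    assert res_p.observed == n_below


def test_satterthwaite_closed_forms():
    # k = 1 (var = mean^2): exponential tail
    assert satterthwaite_gamma_p(2.0, 1.0, 1.0) == pytest.approx(np.exp(-2.0), rel=1e-10)
    # concentration limit: observed = mean, k -> inf => p -> 1/2
    assert satterthwaite_gamma_p(1.0, 1.0, 1e-8) == pytest.approx(0.5, abs=0.01)
    with pytest.raises(ValueError):
        satterthwaite_gamma_p(1.0, 0.0, 1.0)


def test_satterthwaite_gamma_close_to_empirical_p(sim_dataset):
    """Moment-matched gamma p tracks the permutation p for the score test."""
    geno = sim_dataset["geno"]
    rng = np.random.default_rng(42)
    engine = gs.NullEngine(n_perm=2000, seed=9)
    gaps = []
    for k in range(10):
        idx = np.sort(rng.choice(geno.n_markers, 60, replace=False))
        res = score_test(sim_dataset["fit"], geno, FeatureSet(f"r{k}", idx),
                         engine=engine, effects=sim_dataset["effects"])
        gaps.append(abs(res.p_parametric - res.p_empirical))
    assert np.median(gaps) < 0.02
    assert max(gaps) < 0.06


def test_cvat_decompose_disjoint_partition_sums_to_total(sim_dataset, feature):
    idx = feature.marker_idx
    genes = {"gA": idx[:20], "gB": idx[20:35], "gC": idx[35:]}
    f = FeatureSet("C1", idx, genes=genes)
    tab = cvat_decompose(sim_dataset["effects"], sim_dataset["geno"], f)
    assert tab["T"].sum() == pytest.approx(tab.attrs["feature_T"], abs=1e-10)
    assert not tab.attrs["overlapping_genes"]
    one = tab[tab.gene == "gB"].iloc[0]
    assert one["T_per_snp"] == pytest.approx(one["T"] / 15)


def test_cvat_decompose_overlapping_genes_evaluated_independently(sim_dataset, feature):
    idx = feature.marker_idx
    genes = {"g1": idx[:30], "g2": idx[20:]}
    f = FeatureSet("C1", idx, genes=genes)
    tab = cvat_decompose(sim_dataset["effects"], sim_dataset["geno"], f)
    assert tab.attrs["overlapping_genes"]
    c = per_marker_contributions(sim_dataset["effects"], sim_dataset["geno"], "cvat")
    for g, gi in genes.items():
        assert tab.set_index("gene").loc[g, "T"] == pytest.approx(c[gi].sum(), abs=1e-10)


def test_cvat_decompose_single_snp_gene(sim_dataset, feature):
    f = FeatureSet("C1", feature.marker_idx, genes={"g": feature.marker_idx[:1]})
    tab = cvat_decompose(sim_dataset["effects"], sim_dataset["geno"], f)
    assert tab["T"].iloc[0] == pytest.approx(tab["T_per_snp"].iloc[0])


def test_mt_cvat_identities(small_grm, small_geno, rng):
    df = gs.simulate_two_trait_phenotypes(
        small_grm, np.array([[30, 20], [20, 30]]), (70, 70), n_rep=3, seed=13
    )
    d1, d2 = df[df.trait == 1], df[df.trait == 2]
    fit = gs.MultiTraitGBLUP().fit(
        small_grm, d1["value"].to_numpy(), d2["value"].to_numpy(),
        lines1=d1["line_index"].to_numpy(), lines2=d2["line_index"].to_numpy(),
    )
    eff1, eff2 = gs.backsolve_effects(fit, small_geno)
    full = FeatureSet("all", np.arange(small_geno.n_markers))
    res = mt_cvat(fit, small_geno, full)
    assert res["CVAT_MF"].observed == pytest.approx(float(fit.g_hat1_ @ fit.g_hat2_), rel=1e-6)
    assert res["CVAT_M"].observed == pytest.approx(float(fit.g_hat1_ @ fit.g_hat1_), rel=1e-6)
    # per-marker expansion on a sub-feature
    sub = FeatureSet("sub", np.arange(50, 200))
    res_sub = mt_cvat(fit, small_geno, sub)
    c = eff2.s_hat * (small_geno.W.T @ eff1.g_hat)
    assert res_sub["CVAT_MF"].observed == pytest.approx(c[sub.marker_idx].sum(), abs=1e-10)


def test_mt_cvat_duplicate_trait_reduces_to_within(small_grm, small_geno, rng):
    y = rng.standard_normal(small_grm.n)
    fit = gs.MultiTraitGBLUP().fit(small_grm, y, y)
    sub = FeatureSet("sub", np.arange(100))
    res = mt_cvat(fit, small_geno, sub)
    assert res["CVAT_MF"].observed == pytest.approx(res["CVAT_M"].observed, rel=1e-3, abs=1e-9)


def test_statistics_invariant_to_feature_marker_order(sim_dataset, feature):
    eng = gs.NullEngine(n_perm=300, seed=3)
    shuffled = FeatureSet("C1", feature.marker_idx[::-1].copy())
    for f in (feature, shuffled):
        pass
    r1 = cvat(sim_dataset["effects"], sim_dataset["geno"], feature, engine=eng)
    r2 = cvat(sim_dataset["effects"], sim_dataset["geno"], shuffled, engine=eng)
    assert r1.observed == pytest.approx(r2.observed, rel=1e-12)
    assert r1.p_empirical == r2.p_empirical


def test_feature_validation():
    with pytest.raises(ValueError):
        FeatureSet("dup", np.array([1, 1, 2]))
    with pytest.raises(ValueError):
        FeatureSet("empty", np.array([], dtype=int))
    f = FeatureSet("oob", np.array([5]))
    with pytest.raises(ValueError):
        f.validate(3)
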