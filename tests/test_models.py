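"""Mixed-model (REML) correctness: oracles, identities, limits, recovery."""

import numpy as np
import pytest

import gblupset as gs
from gblupset.genotypes import GRM
from gblupset.models import GBLUP, GFBLUP, MultiTraitGBLUP, fit_gblup, residual_df


def _restricted_loglik(y, X, G, sg, se):
    """Independent dense evaluation of the restricted log-likelihood."""
    V = sg * G + se * np.eye(len(y))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, ld1 = np.linalg.slogdet(V)
    _, ld2 = np.linalg.slogdet(XtViX)
    return -0.5 * (ld1 + ld2 + y @ P @ y)


def test_reml_matches_dense_grid_search_oracle(rng):
    """n=8, G=I: engine estimates maximize the restricted loglik on a grid."""
    n = 8
    y = rng.standard_normal(n) * 2.0
    X = np.ones((n, 1))
    G = np.eye(n)
    fit = GBLUP().fit(GRM(G=G, m_used=n), y)
    grid = np.linspace(0.01, 4 * y.var(), 80)
    best, best_ll = None, -np.inf
    for sg in grid:
        for se in grid:
            ll = _restricted_loglik(y, X, G, sg, se)
            if ll > best_ll:
                best, best_ll = (sg, se), ll
    step = grid[1] - grid[0]
    # with G = I only the sum sg + se is identified; compare totals
    assert fit.sigma_g2_ + fit.sigma_e2_ == pytest.approx(best[0] + best[1], abs=2 * step)
    assert fit.loglik_ >= best_ll - 1e-6


def test_degenerate_zero_noise_fit_hits_boundary(small_grm):
    """y exactly Xb: variances at the floor, g_hat ~ 0."""
    n = small_grm.n
    y = np.full(n, 3.14)
    fit = GBLUP().fit(small_grm, y)
    vy = 1e-12
    assert fit.sigma_g2_ < 1e-6
    assert fit.sigma_e2_ < 1e-6
    assert np.abs(fit.g_hat_).max() < 1e-4


def test_loglik_nondecreasing_over_accepted_iterations(sim_dataset):
    path = np.array(sim_dataset["fit"].loglik_path_)
    assert np.all(np.diff(path) >= -1e-9)


def test_blup_solutions_satisfy_v_identities(sim_dataset):
    """b_hat and g_hat satisfy the GLS/BLUP identities at the converged theta."""
    fit = sim_dataset["fit"]
    y, lines = sim_dataset["y"], sim_dataset["lines"]
    G = sim_dataset["grm"].G
    n = y.size
    Z = np.zeros((n, G.shape[0]))
    Z[np.arange(n), lines] = 1.0
    V = fit.sigma_g2_ * Z @ G @ Z.T + fit.sigma_e2_ * np.eye(n)
    Vi = np.linalg.inv(V)
    X = np.ones((n, 1))
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    g = fit.sigma_g2_ * G @ Z.T @ Vi @ (y - X @ b)
    np.testing.assert_allclose(fit.beta_, b, atol=1e-8)
    np.testing.assert_allclose(fit.g_hat_, g, atol=1e-6)


def test_collapsed_and_dense_reml_agree_on_unbalanced_data(small_grm, rng):
    lines = np.repeat(np.arange(40), rng.integers(1, 5, size=40))
    g_true = rng.standard_normal(40)
    y = g_true[lines] + rng.standard_normal(lines.size) * 2
    G40 = GRM(G=small_grm.G[:40, :40], m_used=small_grm.m_used)
    fa = GBLUP(collapse=True).fit(G40, y, lines=lines)
    fb = GBLUP(collapse=False).fit(G40, y, lines=lines)
    assert fa.sigma_g2_ == pytest.approx(fb.sigma_g2_, rel=1e-4, abs=1e-6)
    assert fa.sigma_e2_ == pytest.approx(fb.sigma_e2_, rel=1e-4)
    assert fa.df_resid_ == pytest.approx(fb.df_resid_, rel=1e-4)
    np.testing.assert_allclose(fa.g_hat_, fb.g_hat_, atol=1e-5)
    np.testing.assert_allclose(fa.e_lines_, fb.e_lines_, atol=1e-6)


def test_df_resid_equals_dense_hat_trace(small_grm, rng):
    """n - tr(H) with H built explicitly from the converged components."""
    L = 30
    lines = np.repeat(np.arange(L), 3)
    y = rng.standard_normal(L)[lines] + rng.standard_normal(lines.size)
    G30 = GRM(G=small_grm.G[:L, :L], m_used=small_grm.m_used)
    fit = GBLUP().fit(G30, y, lines=lines)
    n = y.size
    Z = np.zeros((n, L))
    Z[np.arange(n), lines] = 1.0
    X = np.ones((n, 1))
    V = fit.sigma_g2_ * Z @ G30.G @ Z.T + fit.sigma_e2_ * np.eye(n)
    Vi = np.linalg.inv(V)
    A = X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
    P = Vi - Vi @ A
    H = A + fit.sigma_g2_ * (Z @ G30.G @ Z.T) @ P
    assert fit.df_resid_ == pytest.approx(n - np.trace(H), abs=1e-8)


def test_df_resid_monotone_in_signal_ratio(small_grm):
    """df_e = tr(sigma_e^2 P) decreases as sigma_g/sigma_e grows."""
    L = 25
    G = small_grm.G[:L, :L]
    X = np.ones((L, 1))
    dfs = []
    for sg in [0.0, 0.1, 1.0, 10.0, 100.0]:
        V = sg * G + np.eye(L)
        Vi = np.linalg.inv(V)
        P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
        dfs.append(np.trace(P))
    assert np.all(np.diff(dfs) < 0)
    assert dfs[0] == pytest.approx(L - 1, abs=1e-9)  # OLS limit


def test_df_resid_ols_limit_with_pure_noise(small_grm, rng):
    lines = np.repeat(np.arange(50), 4)
    y = rng.standard_normal(lines.size)
    G50 = GRM(G=small_grm.G[:50, :50], m_used=small_grm.m_used)
    fit = GBLUP().fit(G50, y, lines=lines)
    assert 0 < fit.df_resid_ <= y.size
    if fit.boundary_[0]:  # genetic variance at floor -> intercept-only fit
        assert fit.df_resid_ == pytest.approx(y.size - 1, abs=0.1)


def test_gfblup_single_component_reproduces_gblup(sim_dataset):
    f1 = sim_dataset["fit"]
    f2 = GFBLUP().fit([sim_dataset["grm"]], sim_dataset["y"], lines=sim_dataset["lines"])
    assert f2.sigma_g2_[0] == pytest.approx(f1.sigma_g2_, abs=1e-6)
    assert f2.loglik_ == pytest.approx(f1.loglik_, abs=1e-6)
    np.testing.assert_allclose(f2.g_hat_, f1.g_hat_, atol=1e-6)


def test_gfblup_zero_variance_component_hits_boundary():
    """Signal simulated only in component 2 -> component 1 variance near zero.

    Independent markers (block length 1) so no LD leaks signal into the
    first component's marker set.
    """
    geno = gs.simulate_genotypes(100, 400, block_len=1, seed=17)
    rng = np.random.default_rng(18)
    idx1 = np.arange(0, 100)
    idx2 = np.arange(100, 400)
    g1m = gs.build_grm(geno, idx1)
    g2m = gs.build_grm(geno, idx2)
    d, U = g2m.eig()
    g2 = U @ (np.sqrt(np.clip(d, 0, None) * 15.0) * rng.standard_normal(d.size))
    lines = np.repeat(np.arange(100), 5)
    y = g2[lines] + rng.standard_normal(lines.size) * np.sqrt(40.0)
    fit = GFBLUP().fit([g1m, g2m], y, lines=lines)
    assert fit.sigma_g2_[0] * g1m.mean_diag < 0.15 * fit.sigma_g2_[1] * g2m.mean_diag


def test_gfblup_lrt_vs_gblup_nonnegative(sim_dataset, small_geno):
    gf = gs.build_grm(small_geno, sim_dataset["causal"].C1)
    gr = gs.complement_grm(sim_dataset["grm"], gf)
    f2 = GFBLUP().fit([gf, gr], sim_dataset["y"], lines=sim_dataset["lines"])
    assert 2 * (f2.loglik_ - sim_dataset["fit"].loglik_) >= -1e-6


def test_two_trait_duplicate_gives_correlation_one(small_grm, rng):
    n = small_grm.n
    g = rng.standard_normal(n)
    y = g + 0.5 * rng.standard_normal(n)
    fit = MultiTraitGBLUP().fit(small_grm, y, y)
    assert fit.genetic_corr_ > 0.95
    assert fit.resid_cov_[0, 1] == 0.0  # sigma_e12 structurally zero


def test_two_trait_covariance_psd_and_resid_cov_zero(small_grm, rng):
    df = gs.simulate_two_trait_phenotypes(
        small_grm, np.array([[30, 24], [24, 30]]), (70, 70), n_rep=2, seed=5
    )
    d1, d2 = df[df.trait == 1], df[df.trait == 2]
    fit = MultiTraitGBLUP().fit(
        small_grm, d1["value"].to_numpy(), d2["value"].to_numpy(),
        lines1=d1["line_index"].to_numpy(), lines2=d2["line_index"].to_numpy(),
    )
    ev = np.linalg.eigvalsh(fit.trait_cov_)
    assert ev.min() >= -1e-8 * max(ev.max(), 1)
    assert fit.resid_cov_[0, 1] == 0.0
    assert -1 <= fit.genetic_corr_ <= 1


def test_incidence_matrix_wrapper(small_grm, rng):
    lines = np.repeat(np.arange(20), 2)
    y = rng.standard_normal(40)
    Z = np.zeros((40, small_grm.n))
    Z[np.arange(40), lines] = 1
    f1 = fit_gblup(y, np.ones((40, 1)), Z, small_grm)
    f2 = GBLUP().fit(small_grm, y, lines=lines)
    assert f1.sigma_g2_ == pytest.approx(f2.sigma_g2_, abs=1e-10)
    assert residual_df(f1) == pytest.approx(residual_df(f2))


def test_replicate_within_line_component(small_grm, rng):
    """Extra replicate-group random effect is estimated (uncollapsed path)."""
    L, reps, per = 30, 2, 3
    lines = np.repeat(np.arange(L), reps * per)
    groups = np.repeat(np.arange(L * reps), per)
    l_eff = rng.standard_normal(L * reps) * 2.0
    y = l_eff[groups] + rng.standard_normal(lines.size)
    G30 = GRM(G=small_grm.G[:L, :L], m_used=small_grm.m_used)
    fit = GBLUP().fit(G30, y, lines=lines, rep_groups=groups)
    assert fit.sigma_l2_ is not None
    assert fit.sigma_l2_ > fit.sigma_e2_  # group variance dominates by design


def test_dimension_mismatch_raises(small_grm):
    with pytest.raises(ValueError):
        GBLUP().fit(small_grm, np.zeros(10), lines=np.zeros(9, dtype=int))
    with pytest.raises(ValueError):
        GBLUP().fit(small_grm, np.zeros(10), lines=np.full(10, small_grm.n))
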