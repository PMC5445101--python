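"""GBLUP / GFBLUP / two-trait mixed-model estimators.

The models are scikit-learn style estimators over a precomputed genomic
relationship matrix (GRM):

* :class:`GBLUP` — y = X b + Z g + e with g ~ N(0, G sigma_g^2).
* :class:`GFBLUP` — several genomic components g_i ~ N(0, G_i sigma_gi^2).
* :class:`MultiTraitGBLUP` — two traits with genetic covariance
  g ~ N(0, G x Sigma_g) (Kronecker), optional replicate-within-line effects,
  and residual covariance between traits fixed to zero.

``lines`` maps each phenotypic record to a row of G; records are kept at the
replicate level.  When the fixed-effect design is constant within line and
there are no replicate-within-line random effects, the restricted likelihood
is evaluated exactly on line means plus a within-line sum-of-squares term
(an algebraic identity, not an approximation), which keeps fits fast at
thousands of records.

Genomic values are predicted for *all* rows of G, including lines without
phenotypes, so cross-validation by masking lines needs no special casing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .genotypes import GRM
from .reml import Component, REMLResult, fit_reml

__all__ = [
    "GBLUP",
    "GFBLUP",
    "MultiTraitGBLUP",
    "EffectStream",
    "fit_gblup",
    "fit_gfblup",
    "fit_multitrait",
    "residual_df",
]


@dataclass
class EffectStream:
    """One back-solvable genomic channel of a fitted model.

    The predicted genomic values satisfy ``g_hat = G[:, obs] @ alpha`` and
    ``Var(g_hat) = G[:, obs] @ M @ G[obs, :]`` so that marker-effect
    back-solving can reuse the GRM eigendecomposition.
    """

    label: str
    grm: GRM
    obs_lines: np.ndarray
    alpha: np.ndarray
    M: np.ndarray
    df_e: float

    @property
    def g_hat(self) -> np.ndarray:
        return self.grm.G[:, self.obs_lines] @ self.alpha


def _as_grm(G) -> GRM:
    if isinstance(G, GRM):
        return G
    G = np.asarray(G, dtype=float)
    return GRM(G=0.5 * (G + G.T), m_used=G.shape[0], marker_subset=None)


def _prepare_inputs(y, lines, X, n_lines):
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if lines is None:
        if n != n_lines:
            raise ValueError("without `lines`, y must have one record per G row")
        lines = np.arange(n)
    lines = np.asarray(lines, dtype=int).ravel()
    if lines.size != n:
        raise ValueError("`lines` length does not match y")
    if lines.min() < 0 or lines.max() >= n_lines:
        raise ValueError("line index out of range for G")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("X rows do not match y")
    return y, lines, X


def _collapse_by_line(y, lines, X):
    """Exact line-mean reduction.

    Returns (ybar, Xbar, r, sse, obs_lines, local) or None when X is not
    constant within line (collapse would change the model).
    """
    obs_lines, local = np.unique(lines, return_inverse=True)
    L = obs_lines.size
    r = np.bincount(local, minlength=L).astype(float)
    ybar = np.bincount(local, weights=y, minlength=L) / r
    sse = float(np.sum((y - ybar[local]) ** 2))
    Xbar = np.empty((L, X.shape[1]))
    for j in range(X.shape[1]):
        Xbar[:, j] = np.bincount(local, weights=X[:, j], minlength=L) / r
        if np.max(np.abs(X[:, j] - Xbar[local, j])) > 1e-10:
            return None
    return ybar, Xbar, r, sse, obs_lines, local


def _groups_to_K(codes):
    """Dense block membership matrix QQ' for a grouping code vector."""
    codes = np.asarray(codes)
    return (codes[:, None] == codes[None, :]).astype(float)


class _BaseGBLUP(BaseEstimator):
    def __init__(
        self,
        *,
        max_iter: int = 200,
        tol_loglik: float = 1e-6,
        tol_theta: float = 1e-5,
        var_floor_frac: float = 1e-8,
        collapse: str | bool = "auto",
    ):
        self.max_iter = max_iter
        self.tol_loglik = tol_loglik
        self.tol_theta = tol_theta
        self.var_floor_frac = var_floor_frac
        self.collapse = collapse

    def _reml(self, y, X, components, psd_blocks=()):
        return fit_reml(
            y,
            X,
            components,
            psd_blocks=psd_blocks,
            max_iter=self.max_iter,
            tol_loglik=self.tol_loglik,
            tol_theta=self.tol_theta,
            floor_frac=self.var_floor_frac,
        )

    def _check_fitted(self):
        if not hasattr(self, "loglik_"):
            raise RuntimeError("model is not fitted")


def _fit_single_trait(est, grms, y, lines, X, rep_groups):
    """Shared machinery for GBLUP/GFBLUP; returns a dict of fitted state."""
    n_lines = grms[0].n
    y, lines, X = _prepare_inputs(y, lines, X, n_lines)
    n_obs = y.size
    collapsed = None
    if est.collapse in ("auto", True) and rep_groups is None:
        collapsed = _collapse_by_line(y, lines, X)
    if est.collapse is True and collapsed is None:
        raise ValueError("collapse requested but X is not constant within line")

    if collapsed is not None:
        ybar, Xbar, r, sse, obs_lines, local = collapsed
        L = obs_lines.size
        comps = [Component(f"g{i}", K=g.G[np.ix_(obs_lines, obs_lines)]) for i, g in enumerate(grms)]
        comps.append(Component("e", diag=1.0 / r, extra_df=float(n_obs - L), extra_ss=sse))
        res = est._reml(ybar, Xbar, comps)
        P_lines = res.P
        e_lines = res.Py
        sigma_e2 = res.theta[-1]
        # df_e = n - tr(H); tr(H) = L - sigma_e^2 * tr(diag(1/r) P)
        df_e = n_obs - L + sigma_e2 * float(P_lines.diagonal() @ (1.0 / r))
    else:
        if n_obs > 4000:
            warnings.warn(
                f"replicate-level REML on {n_obs} records is dense O(n^3); "
                "consider a line-constant fixed-effect design",
                stacklevel=3,
            )
        obs_lines, local = np.unique(lines, return_inverse=True)
        L = obs_lines.size
        comps = [
            Component(f"g{i}", K=g.G[np.ix_(obs_lines, obs_lines)][np.ix_(local, local)])
            for i, g in enumerate(grms)
        ]
        if rep_groups is not None:
            comps.append(Component("l", K=_groups_to_K(rep_groups)))
        comps.append(Component("e", diag=np.ones(n_obs)))
        res = est._reml(y, X, comps)
        Zinc = np.zeros((n_obs, L))
        Zinc[np.arange(n_obs), local] = 1.0
        P_lines = Zinc.T @ res.P @ Zinc
        e_lines = Zinc.T @ res.Py
        sigma_e2 = res.theta[-1]
        df_e = sigma_e2 * float(np.trace(res.P))

    nf = len(grms)
    sigma_g2 = res.theta[:nf].copy()
    prepared = (y, lines, X)
    streams = []
    for i, g in enumerate(grms):
        streams.append(
            EffectStream(
                label=f"g{i}",
                grm=g,
                obs_lines=obs_lines,
                alpha=sigma_g2[i] * e_lines,
                M=sigma_g2[i] ** 2 * P_lines,
                df_e=df_e,
            )
        )
    return dict(
        res=res,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        sigma_l2=(res.theta[nf] if rep_groups is not None and collapsed is None else None),
        streams=streams,
        obs_lines=obs_lines,
        e_lines=e_lines,
        P_lines=P_lines,
        df_e=df_e,
        n_obs=n_obs,
        collapsed=collapsed is not None,
        prepared=prepared,
    )


class GBLUP(_BaseGBLUP):
    """Single-component genomic BLUP fitted by AI-REML.

    Parameters are the numerical controls; data enter through :meth:`fit`:

    ``fit(G, y, lines=..., X=..., rep_groups=...)`` where ``G`` is an
    (n_lines x n_lines) GRM (:class:`~gblupset.genotypes.GRM` or ndarray),
    ``y`` the phenotype records, ``lines`` integer codes into G rows,
    ``X`` the fixed-effect design (default intercept) and ``rep_groups``
    optional replicate-within-line grouping codes adding an extra random
    effect.
    """

    def fit(self, G, y, *, lines=None, X=None, rep_groups=None):
        grm = _as_grm(G)
        st = _fit_single_trait(self, [grm], y, lines, X, rep_groups)
        res: REMLResult = st["res"]
        self.grm_ = grm
        self.sigma_g2_ = float(st["sigma_g2"][0])
        self.sigma_e2_ = float(st["sigma_e2"])
        self.sigma_l2_ = st["sigma_l2"]
        # genomic variance on the per-line scale (mean diag of G ~ 2 for inbreds)
        vg = self.sigma_g2_ * grm.mean_diag
        self.h2_ = vg / (vg + self.sigma_e2_)
        self.beta_ = res.beta
        self.loglik_ = res.loglik
        self.loglik_path_ = res.loglik_path
        self.converged_ = res.converged
        self.boundary_ = res.boundary
        self.n_iter_ = res.n_iter
        self.obs_lines_ = st["obs_lines"]
        self.e_lines_ = st["e_lines"]
        self.P_lines_ = st["P_lines"]
        self.df_resid_ = st["df_e"]
        self.n_obs_ = st["n_obs"]
        self.collapsed_ = st["collapsed"]
        self.streams_ = st["streams"]
        self.g_hat_ = self.streams_[0].g_hat
        self._y, self._lines, self._X = st["prepared"]
        return self

    def predict(self, lines=None):
        """Predicted genomic values for the given G rows (default: all)."""
        self._check_fitted()
        return self.g_hat_ if lines is None else self.g_hat_[np.asarray(lines)]


class GFBLUP(_BaseGBLUP):
    """Genomic feature BLUP: several genomic variance components.

    ``fit(G_list, y, ...)`` with one GRM per component (e.g. feature and
    rest-of-genome).  The total genomic value is the sum over components and
    marker effects are recoverable per component.
    """

    def fit(self, G_list, y, *, lines=None, X=None, rep_groups=None):
        grms = [_as_grm(G) for G in G_list]
        if len(grms) < 1:
            raise ValueError("need at least one genomic component")
        st = _fit_single_trait(self, grms, y, lines, X, rep_groups)
        res: REMLResult = st["res"]
        self.grms_ = grms
        self.sigma_g2_ = st["sigma_g2"]
        self.sigma_e2_ = float(st["sigma_e2"])
        vg = float(sum(s * g.mean_diag for s, g in zip(self.sigma_g2_, grms)))
        self.h2_ = vg / (vg + self.sigma_e2_)
        self.beta_ = res.beta
        self.loglik_ = res.loglik
        self.loglik_path_ = res.loglik_path
        self.converged_ = res.converged
        self.boundary_ = res.boundary
        self.n_iter_ = res.n_iter
        self.obs_lines_ = st["obs_lines"]
        self.e_lines_ = st["e_lines"]
        self.P_lines_ = st["P_lines"]
        self.df_resid_ = st["df_e"]
        self.n_obs_ = st["n_obs"]
        self.collapsed_ = st["collapsed"]
        self.streams_ = st["streams"]
        self._y, self._lines, self._X = st["prepared"]
        self.g_hat_components_ = np.stack([s.g_hat for s in self.streams_])
        self.g_hat_ = self.g_hat_components_.sum(axis=0)
        return self

    def predict(self, lines=None):
        self._check_fitted()
        return self.g_hat_ if lines is None else self.g_hat_[np.asarray(lines)]


class MultiTraitGBLUP(_BaseGBLUP):
    """Two-trait GBLUP with genetic covariance G x Sigma_g.

    Residual covariance between traits is fixed to zero (traits measured on
    different individuals/environments); optional replicate-within-line
    effects per trait via ``rep_groups1/2``.  The 2x2 genetic covariance is
    kept positive semidefinite by eigenvalue projection after each REML step.
    """

    def fit(
        self,
        G,
        y1,
        y2,
        *,
        lines1=None,
        lines2=None,
        X1=None,
        X2=None,
        rep_groups1=None,
        rep_groups2=None,
    ):
        grm = _as_grm(G)
        n_lines = grm.n
        y1, lines1, X1 = _prepare_inputs(y1, lines1, X1, n_lines)
        y2, lines2, X2 = _prepare_inputs(y2, lines2, X2, n_lines)
        has_rep = rep_groups1 is not None or rep_groups2 is not None

        col1 = col2 = None
        if self.collapse in ("auto", True) and not has_rep:
            col1 = _collapse_by_line(y1, lines1, X1)
            col2 = _collapse_by_line(y2, lines2, X2)
        use_collapse = col1 is not None and col2 is not None

        if use_collapse:
            yb1, Xb1, r1, sse1, o1, _ = col1
            yb2, Xb2, r2, sse2, o2, _ = col2
            L1, L2 = o1.size, o2.size
            ys = np.concatenate([yb1, yb2])
            Xs = np.zeros((L1 + L2, X1.shape[1] + X2.shape[1]))
            Xs[:L1, : X1.shape[1]] = Xb1
            Xs[L1:, X1.shape[1]:] = Xb2
            G11 = grm.G[np.ix_(o1, o1)]
            G22 = grm.G[np.ix_(o2, o2)]
            G12 = grm.G[np.ix_(o1, o2)]
            Ltot = L1 + L2
            K11 = np.zeros((Ltot, Ltot)); K11[:L1, :L1] = G11
            K22 = np.zeros((Ltot, Ltot)); K22[L1:, L1:] = G22
            K12 = np.zeros((Ltot, Ltot)); K12[:L1, L1:] = G12; K12[L1:, :L1] = G12.T
            d1 = np.concatenate([1.0 / r1, np.zeros(L2)])
            d2 = np.concatenate([np.zeros(L1), 1.0 / r2])
            comps = [
                Component("g11", K=K11),
                Component("g12", K=K12, is_variance=False),
                Component("g22", K=K22),
                Component("e1", diag=d1, extra_df=float(y1.size - L1), extra_ss=sse1),
                Component("e2", diag=d2, extra_df=float(y2.size - L2), extra_ss=sse2),
            ]
            res = self._reml(ys, Xs, comps, psd_blocks=((0, 1, 2),))
            e1, e2 = res.Py[:L1], res.Py[L1:]
            Pbar = res.P
            rdiag = np.concatenate([res.theta[3] / r1, res.theta[4] / r2])
            # per-trait df_e: N_t - sum of hat diagonal over the trait block
            hat_fixed = np.einsum("ij,jk,ik->i", Xs, res.XtVinvX_inv, res.Vinv @ Xs)
            Vbar = np.zeros_like(Pbar)
            for c, th in zip(comps, res.theta):
                c.add_to(Vbar, th)
            hat_rand = np.einsum("ij,ji->i", Vbar - np.diag(rdiag), Pbar)
            hat_diag = hat_fixed + hat_rand
            df1 = y1.size - L1 + (L1 - float(hat_diag[:L1].sum()))
            df2 = y2.size - L2 + (L2 - float(hat_diag[L1:].sum()))
            n_obs = (y1.size, y2.size)
        else:
            o1, loc1 = np.unique(lines1, return_inverse=True)
            o2, loc2 = np.unique(lines2, return_inverse=True)
            L1, L2 = o1.size, o2.size
            n1, n2 = y1.size, y2.size
            if n1 + n2 > 4000:
                warnings.warn("dense two-trait REML on %d records" % (n1 + n2), stacklevel=2)
            ys = np.concatenate([y1, y2])
            Xs = np.zeros((n1 + n2, X1.shape[1] + X2.shape[1]))
            Xs[:n1, : X1.shape[1]] = X1
            Xs[n1:, X1.shape[1]:] = X2
            Gz11 = grm.G[np.ix_(o1, o1)][np.ix_(loc1, loc1)]
            Gz22 = grm.G[np.ix_(o2, o2)][np.ix_(loc2, loc2)]
            Gz12 = grm.G[np.ix_(o1, o2)][np.ix_(loc1, loc2)]
            N = n1 + n2
            K11 = np.zeros((N, N)); K11[:n1, :n1] = Gz11
            K22 = np.zeros((N, N)); K22[n1:, n1:] = Gz22
            K12 = np.zeros((N, N)); K12[:n1, n1:] = Gz12; K12[n1:, :n1] = Gz12.T
            comps = [
                Component("g11", K=K11),
                Component("g12", K=K12, is_variance=False),
                Component("g22", K=K22),
            ]
            for rg, sl, nn in ((rep_groups1, slice(0, n1), n1), (rep_groups2, slice(n1, N), n2)):
                if rg is not None:
                    Kl = np.zeros((N, N))
                    Kl[sl, sl] = _groups_to_K(rg)
                    comps.append(Component("l", K=Kl))
            comps.append(Component("e1", diag=np.concatenate([np.ones(n1), np.zeros(n2)])))
            comps.append(Component("e2", diag=np.concatenate([np.zeros(n1), np.ones(n2)])))
            res = self._reml(ys, Xs, comps, psd_blocks=((0, 1, 2),))
            Z1 = np.zeros((n1, L1)); Z1[np.arange(n1), loc1] = 1.0
            Z2 = np.zeros((n2, L2)); Z2[np.arange(n2), loc2] = 1.0
            e1 = Z1.T @ res.Py[:n1]
            e2 = Z2.T @ res.Py[n1:]
            Zblk = np.zeros((N, L1 + L2))
            Zblk[:n1, :L1] = Z1
            Zblk[n1:, L1:] = Z2
            Pbar = Zblk.T @ res.P @ Zblk
            th_e1, th_e2 = res.theta[-2], res.theta[-1]
            df1 = th_e1 * float(np.trace(res.P[:n1, :n1]))
            df2 = th_e2 * float(np.trace(res.P[n1:, n1:]))
            n_obs = (n1, n2)

        s11, s12, s22 = res.theta[0], res.theta[1], res.theta[2]
        self.grm_ = grm
        self.trait_cov_ = np.array([[s11, s12], [s12, s22]])
        self.resid_cov_ = np.diag([res.theta[-2], res.theta[-1]])
        self.genetic_corr_ = float(s12 / np.sqrt(max(s11 * s22, 1e-300)))
        self.beta_ = res.beta
        self.loglik_ = res.loglik
        self.loglik_path_ = res.loglik_path
        self.converged_ = res.converged
        self.boundary_ = res.boundary
        self.n_iter_ = res.n_iter
        self.df_resid_ = (df1, df2)
        self.n_obs_ = n_obs
        self.collapsed_ = use_collapse

        # effect streams: g_t = G[:, o_union] alpha_t with
        # alpha_1 = s11 e1 (+) s12 e2, alpha_2 = s12 e1 (+) s22 e2
        o_union, inv = np.unique(np.concatenate([o1, o2]), return_inverse=True)
        i1, i2 = inv[: o1.size], inv[o1.size:]
        Lu = o_union.size

        def _stream(w1, w2, label, df):
            J = np.zeros((Lu, L1 + L2))
            J[i1, np.arange(L1)] = w1
            J[i2, L1 + np.arange(L2)] = w2
            alpha = J @ np.concatenate([e1, e2])
            M = J @ Pbar @ J.T
            return EffectStream(label=label, grm=grm, obs_lines=o_union, alpha=alpha, M=M, df_e=df)

        self.streams_ = [_stream(s11, s12, "trait1", df1), _stream(s12, s22, "trait2", df2)]
        self.g_hat1_ = self.streams_[0].g_hat
        self.g_hat2_ = self.streams_[1].g_hat
        return self

    def predict(self, lines=None):
        self._check_fitted()
        out = np.stack([self.g_hat1_, self.g_hat2_])
        return out if lines is None else out[:, np.asarray(lines)]


def _codes_from_incidence(Z):
    Z = np.asarray(Z)
    if Z.ndim != 2 or not np.all((Z == 0) | (Z == 1)) or not np.all(Z.sum(axis=1) == 1):
        raise ValueError("Z must be a 0/1 incidence matrix with one 1 per row")
    return np.argmax(Z, axis=1)


def fit_gblup(y, X, Z, G, extra_random=None, **kwargs) -> GBLUP:
    """Functional wrapper: Z is a line-incidence matrix (or code vector)."""
    lines = _codes_from_incidence(Z) if np.ndim(Z) == 2 else np.asarray(Z)
    return GBLUP(**kwargs).fit(G, y, lines=lines, X=X, rep_groups=extra_random)


def fit_gfblup(y, X, Z, G_list, **kwargs) -> GFBLUP:
    lines = _codes_from_incidence(Z) if np.ndim(Z) == 2 else np.asarray(Z)
    return GFBLUP(**kwargs).fit(G_list, y, lines=lines, X=X)


def fit_multitrait(y1, y2, X1, X2, Z1, Z2, G, Q1=None, Q2=None, **kwargs) -> MultiTraitGBLUP:
    l1 = _codes_from_incidence(Z1) if np.ndim(Z1) == 2 else np.asarray(Z1)
    l2 = _codes_from_incidence(Z2) if np.ndim(Z2) == 2 else np.asarray(Z2)
    q1 = _codes_from_incidence(Q1) if Q1 is not None and np.ndim(Q1) == 2 else Q1
    q2 = _codes_from_incidence(Q2) if Q2 is not None and np.ndim(Q2) == 2 else Q2
    return MultiTraitGBLUP(**kwargs).fit(
        G, y1, y2, lines1=l1, lines2=l2, X1=X1, X2=X2, rep_groups1=q1, rep_groups2=q2
    )


def residual_df(fit) -> float:
    """Residual degrees of freedom n - tr(H) of a fitted model."""
    fit._check_fitted()
    df = fit.df_resid_
    return df
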