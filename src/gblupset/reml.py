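"""Dense average-information REML for linear mixed models.

The engine maximizes the restricted log-likelihood of

    y ~ N(X b, V(theta)),    V(theta) = sum_i theta_i K_i

where each ``K_i`` is a dense symmetric matrix or a diagonal (given by its
diagonal vector).  A component may additionally carry an "absorbed" residual
term ``-1/2 (nu log theta_i + ss / theta_i)`` in the likelihood; this is how
replicate-level records collapsed to group means keep their within-group sum
of squares exact (the restricted likelihood of a balanced-within-group model
factorizes into a between-group part and a within-group scaled chi-square).

Updates are average-information steps with step-halving on likelihood
decrease; variance parameters are floored at ``floor_frac * var(y)`` and 2x2
covariance blocks are projected to the PSD cone after every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["Component", "REMLResult", "fit_reml"]


@dataclass
class Component:
    """One variance-structure term theta_i * K_i.

    Exactly one of ``K`` (dense) or ``diag`` (diagonal vector) is set.
    ``extra_df``/``extra_ss`` attach the absorbed within-group residual term.
    ``is_variance`` distinguishes variances (floored >= 0) from covariances.
    """

    name: str
    K: np.ndarray | None = None
    diag: np.ndarray | None = None
    extra_df: float = 0.0
    extra_ss: float = 0.0
    is_variance: bool = True

    def matvec(self, v: np.ndarray) -> np.ndarray:
        if self.K is not None:
            return self.K @ v
        return self.diag * v

    def add_to(self, V: np.ndarray, theta: float) -> None:
        if self.K is not None:
            V += theta * self.K
        else:
            V[np.diag_indices_from(V)] += theta * self.diag

    def trace_with(self, M: np.ndarray) -> float:
        """tr(M K_i) for symmetric M."""
        if self.K is not None:
            return float(np.vdot(M, self.K))
        return float(M.diagonal() @ self.diag)


@dataclass
class REMLResult:
    theta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    boundary: np.ndarray
    loglik_path: list = field(default_factory=list)
    # solver by-products at the converged parameters
    beta: np.ndarray | None = None
    P: np.ndarray | None = None
    Py: np.ndarray | None = None
    Vinv: np.ndarray | None = None
    XtVinvX_inv: np.ndarray | None = None
    message: str = ""


def _project_psd_blocks(theta, components, psd_blocks, floor):
    """Clip each (var, cov, var) triple to the PSD cone; floor variances."""
    for i in range(len(theta)):
        if components[i].is_variance and theta[i] < floor:
            theta[i] = floor
    for (i, j, k) in psd_blocks:
        S = np.array([[theta[i], theta[j]], [theta[j], theta[k]]])
        d, Q = np.linalg.eigh(S)
        if d[0] < 0:
            S = (Q * np.clip(d, 0.0, None)) @ Q.T
            theta[i], theta[j], theta[k] = S[0, 0], S[0, 1], S[1, 1]
            theta[i] = max(theta[i], floor)
            theta[k] = max(theta[k], floor)
        # keep correlation strictly inside (-1, 1)
        lim = 0.9999 * np.sqrt(theta[i] * theta[k])
        theta[j] = float(np.clip(theta[j], -lim, lim))
    return theta


def _likelihood_parts(y, X, components, theta):
    """Return (loglik, P, Py, beta, Vinv, XtVinvX_inv) at theta."""
    n = y.shape[0]
    V = np.zeros((n, n))
    for c, th in zip(components, theta):
        c.add_to(V, th)
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return None
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vinv = cho_solve(cf, np.eye(n))
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    sign, logdetX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        return None
    XtVinvX_inv = np.linalg.inv(XtVinvX)
    beta = XtVinvX_inv @ (VinvX.T @ y)
    P = Vinv - VinvX @ XtVinvX_inv @ VinvX.T
    Py = P @ y
    quad = float(y @ Py)
    ll = -0.5 * (logdetV + logdetX + quad)
    for c, th in zip(components, theta):
        if c.extra_df > 0:
            ll += -0.5 * (c.extra_df * np.log(th) + c.extra_ss / th)
    return ll, P, Py, beta, Vinv, XtVinvX_inv


def _default_start(y, components):
    """Split var(y) over components; absorbed residual terms seed sigma_e."""
    vy = max(float(np.var(y)), 1e-12)
    q = len(components)
    theta = np.full(q, vy / q)
    for i, c in enumerate(components):
        if c.extra_df > 0:
            theta[i] = max(c.extra_ss / c.extra_df, 1e-3 * vy)
        if not c.is_variance:
            theta[i] = 0.0
    return theta


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    components: list[Component],
    psd_blocks: tuple[tuple[int, int, int], ...] = (),
    theta0: np.ndarray | None = None,
    max_iter: int = 200,
    tol_loglik: float = 1e-6,
    tol_theta: float = 1e-5,
    floor_frac: float = 1e-8,
    max_halvings: int = 30,
) -> REMLResult:
    """Average-information REML with damped updates.

    Convergence when ``|delta loglik| < tol_loglik`` and
    ``max |delta theta| / (|theta| + 1) < tol_theta``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows do not match y length")
    q = len(components)
    vy = max(float(np.var(y)), 1e-12)
    floor = floor_frac * vy

    theta = np.array(theta0, dtype=float) if theta0 is not None else _default_start(y, components)
    theta = _project_psd_blocks(theta, components, psd_blocks, floor)

    parts = _likelihood_parts(y, X, components, theta)
    if parts is None:
        raise np.linalg.LinAlgError("V not positive definite at starting values")
    ll, P, Py, beta, Vinv, XtVinvX_inv = parts
    path = [ll]
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        # score and average information in the current point
        KPy = [c.matvec(Py) for c in components]
        PKPy = [P @ u for u in KPy]
        score = np.empty(q)
        for i, c in enumerate(components):
            trPK = c.trace_with(P)
            score[i] = -0.5 * (trPK - float(Py @ KPy[i]))
            if c.extra_df > 0:
                score[i] += -0.5 * (c.extra_df / theta[i] - c.extra_ss / theta[i] ** 2)
        AI = np.empty((q, q))
        for i in range(q):
            for j in range(i, q):
                AI[i, j] = AI[j, i] = 0.5 * float(KPy[i] @ PKPy[j])
            if components[i].extra_df > 0:
                AI[i, i] += components[i].extra_df / (2.0 * theta[i] ** 2)
        # Active set: variances pinned at the floor whose gradient points
        # further down are held fixed so they do not poison the AI step.
        free = np.array(
            [
                not (c.is_variance and theta[i] <= floor * (1 + 1e-6) and score[i] < 0)
                for i, c in enumerate(components)
            ]
        )
        if not free.any():
            converged = True
            message = "all parameters at boundary"
            break
        AIf = AI[np.ix_(free, free)]
        scoref = score[free]
        # Levenberg-Marquardt damping: escalate ridge until the proposed step
        # is finite and of sane magnitude (AI can be singular, e.g. perfectly
        # correlated traits or variance components at the boundary).
        scale = (np.abs(theta) + vy)[free]
        lam = 0.0
        nf = int(free.sum())
        diag0 = np.eye(nf) * max(AIf.diagonal().max(), 1e-12)
        for _ in range(40):
            try:
                deltaf = np.linalg.solve(AIf + (lam + 1e-12) * diag0, scoref)
            except np.linalg.LinAlgError:
                deltaf = None
            if deltaf is not None and np.all(np.isfinite(deltaf)) and np.max(np.abs(deltaf) / scale) <= 10.0:
                break
            lam = max(lam * 10.0, 1e-10)
        else:
            deltaf = scoref / max(AIf.diagonal().max(), 1e-12)
        delta = np.zeros(q)
        delta[free] = deltaf

        step = 1.0
        accepted = False
        for _ in range(max_halvings):
            cand = _project_psd_blocks(theta + step * delta, components, psd_blocks, floor)
            parts = _likelihood_parts(y, X, components, cand)
            if parts is not None and parts[0] >= ll - 1e-10:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            message = "no improving step found (likely at boundary/maximum)"
            converged = len(path) > 1 and abs(path[-1] - path[-2]) < tol_loglik
            break
        new_ll, P, Py, beta, Vinv, XtVinvX_inv = parts
        dtheta = np.max(np.abs(cand - theta) / (np.abs(theta) + 1.0))
        dll = abs(new_ll - ll)
        theta, ll = cand, new_ll
        path.append(ll)
        if dll < tol_loglik and dtheta < tol_theta:
            converged = True
            break
    else:
        message = "maximum iterations reached"

    boundary = np.array(
        [c.is_variance and theta[i] <= floor * (1 + 1e-6) for i, c in enumerate(components)]
    )
    return REMLResult(
        theta=theta,
        loglik=ll,
        converged=converged,
        n_iter=it,
        boundary=boundary,
        loglik_path=path,
        beta=beta,
        P=P,
        Py=Py,
        Vinv=Vinv,
        XtVinvX_inv=XtVinvX_inv,
        message=message,
    )
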