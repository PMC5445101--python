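"""Back-solving per-marker effects from fitted genomic models.

From a fitted GBLUP-type model the per-marker effects are recovered as
``s_hat = W' (W W')^- g_hat`` and their variances from the variance of the
predicted genomic values, ``Var(s_hat) = W'(WW')^- Var(g_hat) (WW')^- W``.
Since ``W W' = m G``, the pseudo-inverse reuses the GRM eigendecomposition;
with ``Var(g_hat) = G M G`` (the models expose ``M``), the factors of G
cancel against the pseudo-inverse and the diagonal costs one m x k product.

Single-marker t statistics ``t_j = s_j / sqrt(Var(s_j))`` are referred to a
t distribution with the residual degrees of freedom of the penalized fit
(two-sided p-values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotypes import GenotypeData
from .models import GBLUP, GFBLUP, EffectStream, MultiTraitGBLUP

__all__ = ["MarkerEffects", "backsolve_effects", "marker_t_stats",
           "marker_effects_table", "full_effect_covariance"]

VAR_FLOOR = 1e-12


@dataclass
class MarkerEffects:
    """Per-marker effects, variances and t statistics for one genomic channel."""

    s_hat: np.ndarray
    var_s: np.ndarray
    df_e: float
    marker_idx: np.ndarray
    g_hat: np.ndarray
    t_stat: np.ndarray | None = None
    p_single: np.ndarray | None = None
    flagged: np.ndarray | None = None
    label: str = ""
    # line-level projected residuals of the parent fit (for the score test)
    e_lines: np.ndarray | None = field(default=None, repr=False)
    obs_lines: np.ndarray | None = field(default=None, repr=False)

    @property
    def m(self) -> int:
        return self.s_hat.size


def _backsolve_stream(stream: EffectStream, genotypes: GenotypeData) -> MarkerEffects:
    grm = stream.grm
    if grm.n != genotypes.n_lines:
        raise ValueError("fit and genotypes refer to different line sets")
    idx = (
        np.arange(genotypes.n_markers)
        if grm.marker_subset is None
        else np.asarray(grm.marker_subset)
    )
    W = genotypes.W[:, idx]
    m = idx.size
    if m != grm.m_used:
        raise ValueError("marker order/subset mismatch between fit and genotypes")
    d, U = grm.eig_nonnull()
    Uo = U[stream.obs_lines, :]
    A = W.T @ U  # (m, k)
    s_hat = (A @ (Uo.T @ stream.alpha)) / m
    inner = Uo.T @ stream.M @ Uo
    var_s = np.einsum("ij,jk,ik->i", A, inner, A) / m**2
    var_s = np.maximum(var_s, 0.0)
    eff = MarkerEffects(
        s_hat=s_hat,
        var_s=var_s,
        df_e=stream.df_e,
        marker_idx=idx,
        g_hat=stream.g_hat,
        label=stream.label,
        e_lines=stream.alpha.copy(),
        obs_lines=stream.obs_lines,
    )
    return marker_t_stats(eff)


def backsolve_effects(fit, genotypes: GenotypeData):
    """Back-solve marker effects from a fitted model.

    Returns a :class:`MarkerEffects` for :class:`~gblupset.models.GBLUP`,
    a list (one per genomic component) for GFBLUP, and a (trait1, trait2)
    tuple for the two-trait model.
    """
    fit._check_fitted()
    out = [_backsolve_stream(s, genotypes) for s in fit.streams_]
    if isinstance(fit, GBLUP):
        eff = out[0]
        # raw line-level projected residuals (alpha = sigma_g^2 * e_lines)
        eff.e_lines = fit.e_lines_.copy()
        return eff
    if isinstance(fit, MultiTraitGBLUP):
        return tuple(out)
    if isinstance(fit, GFBLUP):
        for eff, s in zip(out, fit.streams_, strict=True):
            eff.e_lines = fit.e_lines_.copy()
        return out
    return out


def marker_effects_table(effects: MarkerEffects, genotypes: GenotypeData):
    """Per-marker table (marker id, chrom, pos, s_hat, var_s, t, p)."""
    import pandas as pd

    idx = effects.marker_idx
    return pd.DataFrame(
        {
            "marker_id": genotypes.marker_ids[idx],
            "chrom": genotypes.chrom[idx],
            "pos": genotypes.pos[idx],
            "s_hat": effects.s_hat,
            "var_s": effects.var_s,
            "t": effects.t_stat,
            "p": effects.p_single,
        }
    )


def full_effect_covariance(fit, genotypes: GenotypeData, component: int = 0,
                           max_markers: int = 5000) -> np.ndarray:
    """Full m x m covariance of the back-solved effects (small m only).

    Quadratic in the number of markers; only the diagonal feeds the
    single-marker t statistics, so this is opt-in for small panels.
    """
    stream = fit.streams_[component]
    idx = (
        np.arange(genotypes.n_markers)
        if stream.grm.marker_subset is None
        else np.asarray(stream.grm.marker_subset)
    )
    if idx.size > max_markers:
        raise ValueError(f"full covariance limited to {max_markers} markers")
    W = genotypes.W[:, idx]
    m = idx.size
    d, U = stream.grm.eig_nonnull()
    Uo = U[stream.obs_lines, :]
    A = W.T @ U
    inner = Uo.T @ stream.M @ Uo
    return (A @ inner @ A.T) / m**2


def marker_t_stats(effects: MarkerEffects) -> MarkerEffects:
    """Fill t statistics and two-sided p-values from t(df_e).

    Markers whose effect variance is below the numerical floor get t = 0,
    p = 1 and are flagged.
    """
    if effects.df_e <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    low = effects.var_s < VAR_FLOOR
    denom = np.sqrt(np.where(low, 1.0, effects.var_s))
    t = np.where(low, 0.0, effects.s_hat / denom)
    p = 2.0 * stats.t.sf(np.abs(t), df=effects.df_e)
    p = np.where(low, 1.0, p)
    effects.t_stat = t
    effects.p_single = p
    effects.flagged = low
    return effects
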