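"""GBLUP-derived set tests for genomic features.

Four statistics measure the association between a marker set (genomic
feature) and a trait, all computed from one GBLUP fit:

* CVAT, the covariance association test ``T = g_hat' g_hat_f`` between the
  total genomic value and the feature genomic value ``g_hat_f = W_f s_hat_f``;
* the score (SKAT-equivalent) quadratic form
  ``T = 1/2 e' Z G_f Z' e`` in the projected residuals ``e = V^-1(y - Xb)``;
* the sum of squared single-marker statistics (effects or t);
* the count of individually associated markers, with a hypergeometric
  parametric null.

Every statistic is a sum of per-marker contributions, so a single
permutation engine (:mod:`gblupset.permutation`) provides competitive-null
empirical p-values for all of them.  CVAT extends to a per-gene
decomposition and to two traits (MT-CVAT, covariance between one trait's
total genomic value and the other's feature value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .effects import MarkerEffects, backsolve_effects
from .genotypes import GenotypeData, build_grm, complement_grm
from .models import GBLUP, MultiTraitGBLUP
from .permutation import NullEngine, empirical_pvalue

__all__ = [
    "FeatureSet",
    "SetTestResult",
    "per_marker_contributions",
    "cvat",
    "score_test",
    "sum_test",
    "count_test",
    "satterthwaite_gamma_p",
    "cvat_decompose",
    "mt_cvat",
]


@dataclass
class FeatureSet:
    """A named marker index set, optionally partitioned into genes."""

    name: str
    marker_idx: np.ndarray
    genes: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        self.marker_idx = np.asarray(self.marker_idx, dtype=np.int64)
        if self.marker_idx.size < 1:
            raise ValueError("feature must contain at least one marker")
        if len(np.unique(self.marker_idx)) != self.marker_idx.size:
            raise ValueError("feature marker indices must be unique")

    @property
    def m_f(self) -> int:
        return self.marker_idx.size

    def validate(self, n_markers: int) -> None:
        if self.marker_idx.min() < 0 or self.marker_idx.max() >= n_markers:
            raise ValueError("feature marker index out of range")


@dataclass
class SetTestResult:
    statistic_name: str
    feature: str
    observed: float
    p_empirical: float | None = None
    p_parametric: float | None = None
    n_perm: int = 0
    null_mean: float | None = None
    null_var: float | None = None
    t0: float | None = None
    m_a: int | None = None
    null_samples: np.ndarray | None = field(default=None, repr=False)
    extras: dict = field(default_factory=dict)


def per_marker_contributions(
    effects: MarkerEffects,
    genotypes: GenotypeData,
    statistic: str,
    t0: float | None = None,
    second_trait_effects: MarkerEffects | None = None,
) -> np.ndarray:
    """Per-marker contribution vector c such that T = (scale) * sum_f c_i.

    cvat:   c_i = s_i * (w_i' g_hat), summing to g_hat' g_hat_f over a feature
    score:  c_i = (e' Z w_i)^2, with scale 1/(2 m_f) applied by the test
    sum_s2 / sum_t2: squared single-marker statistics
    count:  indicator |t_i| > t0
    mt_cvat: c_i = s2_i * (w_i' g_hat_1) (the across-trait covariance terms)
    """
    W = genotypes.W
    if statistic == "cvat":
        return effects.s_hat * (W.T @ effects.g_hat)
    if statistic == "score":
        if effects.e_lines is None or effects.obs_lines is None:
            raise ValueError("score contributions need the fit's projected residuals")
        return (W[effects.obs_lines, :].T @ effects.e_lines) ** 2
    if statistic == "sum_s2":
        return effects.s_hat**2
    if statistic == "sum_t2":
        return effects.t_stat**2
    if statistic == "count":
        if t0 is None:
            raise ValueError("count statistic needs a threshold t0")
        return (np.abs(effects.t_stat) > t0).astype(float)
    if statistic == "mt_cvat":
        if second_trait_effects is None:
            raise ValueError("mt_cvat needs the second trait's effects")
        return second_trait_effects.s_hat * (W.T @ effects.g_hat)
    raise ValueError(f"unknown statistic {statistic!r}")


def _finish(result: SetTestResult, contribs, feature, engine: NullEngine | None,
            scale: float = 1.0, parametric_from_null: bool = False):
    if engine is not None:
        draws = engine.draws(contribs, feature.marker_idx) * scale
        result.p_empirical = empirical_pvalue(result.observed, draws)
        result.n_perm = engine.n_perm
        result.null_mean = float(draws.mean())
        result.null_var = float(draws.var(ddof=1))
        result.null_samples = draws
        if parametric_from_null and result.null_mean > 0 and result.null_var > 0:
            result.p_parametric = satterthwaite_gamma_p(
                result.observed, result.null_mean, result.null_var
            )
    return result


def cvat(effects: MarkerEffects, genotypes: GenotypeData, feature: FeatureSet,
         engine: NullEngine | None = None) -> SetTestResult:
    """Covariance association test T = g_hat' g_hat_f.

    Also evaluates the decomposition T = g_f' g_f + g_r' g_f and records the
    agreement of the two routes.
    """
    feature.validate(genotypes.n_markers)
    contribs = per_marker_contributions(effects, genotypes, "cvat")
    T = float(contribs[feature.marker_idx].sum())
    f = feature.marker_idx
    g_f = genotypes.W[:, f] @ effects.s_hat[f]
    g_r = effects.g_hat - g_f
    T_alt = float(g_f @ g_f + g_r @ g_f)
    res = SetTestResult("CVAT", feature.name, T,
                        extras={"T_ff": float(g_f @ g_f), "T_rf": float(g_r @ g_f),
                                "decomposition_gap": abs(T - T_alt)})
    if res.extras["decomposition_gap"] > 1e-6 * max(1.0, abs(T)):
        warnings.warn("CVAT decomposition routes disagree beyond tolerance", stacklevel=2)
    return _finish(res, contribs, feature, engine)


def score_test(null_fit: GBLUP, genotypes: GenotypeData, feature: FeatureSet,
               null_model: str = "all_markers", engine: NullEngine | None = None,
               effects: MarkerEffects | None = None) -> SetTestResult:
    """SKAT-type score statistic T = 1/2 e' Z G_f Z' e, G_f = W_f W_f'/m_f.

    ``null_model='all_markers'`` uses the provided all-marker GBLUP null
    (fitted once); ``'exclude_feature'`` refits the null on the complement
    GRM (one REML per feature).
    """
    feature.validate(genotypes.n_markers)
    if null_model == "exclude_feature":
        if feature.m_f >= genotypes.n_markers:
            raise ValueError("feature covers all markers; complement null is empty")
        grm_f = build_grm(genotypes, feature.marker_idx)
        grm_r = complement_grm(null_fit.grm_, grm_f)
        null_fit = GBLUP(**null_fit.get_params()).fit(
            grm_r, null_fit._y, lines=null_fit._lines, X=null_fit._X
        )
        effects = None
    elif null_model != "all_markers":
        raise ValueError(f"unknown null model {null_model!r}")
    if effects is None:
        effects = backsolve_effects(null_fit, genotypes)
    contribs = per_marker_contributions(effects, genotypes, "score")
    scale = 1.0 / (2.0 * feature.m_f)
    T = float(contribs[feature.marker_idx].sum() * scale)
    res = SetTestResult("Score", feature.name, T, extras={"null_model": null_model})
    return _finish(res, contribs, feature, engine, scale=scale, parametric_from_null=True)


def satterthwaite_gamma_p(observed: float, null_mean: float, null_var: float) -> float:
    """Upper-tail p from a moment-matched Gamma(k = mean^2/var, theta = var/mean)."""
    if null_mean <= 0 or null_var <= 0:
        raise ValueError("moment matching needs positive null mean and variance")
    k = null_mean**2 / null_var
    theta = null_var / null_mean
    return float(stats.gamma.sf(observed, a=k, scale=theta))


def sum_test(effects: MarkerEffects, feature: FeatureSet, basis: str = "s2",
             genotypes: GenotypeData | None = None,
             engine: NullEngine | None = None) -> SetTestResult:
    """Sum of squared single-marker statistics over the feature (s^2 or t^2)."""
    if basis not in ("s2", "t2"):
        raise ValueError("basis must be 's2' or 't2'")
    stat = "sum_" + basis
    contribs = effects.s_hat**2 if basis == "s2" else effects.t_stat**2
    T = float(contribs[feature.marker_idx].sum())
    res = SetTestResult("Sum", feature.name, T, extras={"basis": basis})
    return _finish(res, contribs, feature, engine)


def count_test(effects: MarkerEffects, feature: FeatureSet, t0: float = 0.05,
               t0_kind: str = "p", engine: NullEngine | None = None) -> SetTestResult:
    """Count of markers in the feature with |t| above threshold.

    ``t0`` is a single-marker p-value cutoff by default (converted through the
    t(df_e) quantile) or a direct |t| threshold with ``t0_kind='t'``.  The
    parametric null is Hyper(m, m_a, m_f): m markers tested, m_a associated
    genome-wide, m_f in the feature; p = P(X >= T_count).
    """
    if t0_kind == "p":
        t_crit = float(stats.t.ppf(1.0 - t0 / 2.0, df=effects.df_e))
    elif t0_kind == "t":
        t_crit = float(t0)
    else:
        raise ValueError("t0_kind must be 'p' or 't'")
    contribs = (np.abs(effects.t_stat) > t_crit).astype(float)
    m = effects.m
    m_a = int(contribs.sum())
    T = int(contribs[feature.marker_idx].sum())
    res = SetTestResult("Count", feature.name, float(T), t0=t_crit, m_a=m_a)
    if m_a == 0:
        warnings.warn("no marker exceeds the threshold; count p-value is 1", stacklevel=2)
        res.p_parametric = 1.0
    else:
        res.p_parametric = float(stats.hypergeom.sf(T - 1, m, m_a, feature.m_f))
    return _finish(res, contribs, feature, engine)


def cvat_decompose(effects: MarkerEffects, genotypes: GenotypeData,
                   feature: FeatureSet) -> pd.DataFrame:
    """Per-gene CVAT contributions g_hat' g_hat_fi and per-SNP values.

    When the genes partition the feature disjointly the gene contributions
    sum to the feature statistic; overlapping genes are evaluated
    independently (no double-count correction) and flagged.
    """
    if not feature.genes:
        raise ValueError("feature has no gene map")
    contribs = per_marker_contributions(effects, genotypes, "cvat")
    rows = []
    seen: set[int] = set()
    overlapping = False
    for gene, idx in feature.genes.items():
        idx = np.asarray(idx, dtype=np.int64)
        if idx.size == 0:
            raise ValueError(f"gene {gene!r} has no markers")
        if seen.intersection(idx.tolist()):
            overlapping = True
        seen.update(idx.tolist())
        T_g = float(contribs[idx].sum())
        rows.append({"gene": gene, "m_fi": idx.size, "T": T_g, "T_per_snp": T_g / idx.size})
    df = pd.DataFrame(rows)
    df.attrs["overlapping_genes"] = overlapping
    df.attrs["feature_T"] = float(contribs[feature.marker_idx].sum())
    return df


def mt_cvat(fit2: MultiTraitGBLUP, genotypes: GenotypeData, feature: FeatureSet,
            engine: NullEngine | None = None) -> dict[str, SetTestResult]:
    """Within- and across-trait CVAT from a two-trait fit.

    Returns CVAT_M = g1'g_f1, CVAT_F = g2'g_f2, CVAT_MF = g1'g_f2,
    CVAT_FM = g2'g_f1 (trait 1 = "M", trait 2 = "F").
    """
    if not isinstance(fit2, MultiTraitGBLUP):
        raise ValueError("mt_cvat needs a two-trait fit")
    feature.validate(genotypes.n_markers)
    eff1, eff2 = backsolve_effects(fit2, genotypes)
    out: dict[str, SetTestResult] = {}
    specs = {
        "CVAT_M": (eff1, eff1),
        "CVAT_F": (eff2, eff2),
        "CVAT_MF": (eff1, eff2),  # g1' g_f2
        "CVAT_FM": (eff2, eff1),
    }
    for name, (total, feat) in specs.items():
        contribs = feat.s_hat * (genotypes.W.T @ total.g_hat)
        T = float(contribs[feature.marker_idx].sum())
        res = SetTestResult(name, feature.name, T)
        out[name] = _finish(res, contribs, feature, engine)
    return out
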