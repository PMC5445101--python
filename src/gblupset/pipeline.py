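"""One-stop analysis of a data set: GBLUP fit, back-solve, set tests.

``analyze_dataset`` fits the all-marker GBLUP null once, back-solves marker
effects, builds the per-marker contribution vector of every requested
statistic, and evaluates all features against the competitive null with a
shared permutation stream per feature (the same rotations serve every
statistic, as the statistics are all sums of per-marker contributions).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .effects import backsolve_effects
from .genotypes import GenotypeData, build_grm
from .models import GBLUP
from .permutation import NullEngine, empirical_pvalue
from .settests import FeatureSet, per_marker_contributions, satterthwaite_gamma_p

__all__ = ["analyze_dataset", "STAT_NAMES"]

STAT_NAMES = ("cvat", "score", "sum_s2", "sum_t2", "count_0.05", "count_0.01")


def _pheno_arrays(pheno) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pheno, pd.DataFrame):
        return pheno["value"].to_numpy(float), pheno["line_index"].to_numpy(int)
    y, lines = pheno
    return np.asarray(y, float), np.asarray(lines, int)


def analyze_dataset(
    genotypes: GenotypeData,
    pheno,
    features: list[FeatureSet],
    *,
    grm=None,
    statistics: tuple[str, ...] = STAT_NAMES,
    n_perm: int = 1000,
    seed: int = 0,
    null_mode: str = "circular",
    domain: np.ndarray | None = None,
    X: np.ndarray | None = None,
    fit: GBLUP | None = None,
) -> pd.DataFrame:
    """Evaluate set statistics for many features from one GBLUP fit.

    ``pheno`` is a phenotype table (line_index/value columns) or a
    ``(y, lines)`` pair.  Returns one row per (feature, statistic) with the
    observed value, empirical p, and the parametric p where one exists
    (moment-matched gamma for the score test, hypergeometric for counts).
    """
    y, lines = _pheno_arrays(pheno)
    if fit is None:
        grm = grm or build_grm(genotypes)
        fit = GBLUP().fit(grm, y, lines=lines, X=X)
    effects = backsolve_effects(fit, genotypes)

    contrib_rows = []
    meta = []  # (name, kind, extra)
    for stat in statistics:
        if stat.startswith("count_"):
            p_cut = float(stat.split("_", 1)[1])
            t_crit = float(stats.t.ppf(1 - p_cut / 2, df=effects.df_e))
            contrib_rows.append((np.abs(effects.t_stat) > t_crit).astype(float))
            meta.append((stat, "count", t_crit))
        else:
            contrib_rows.append(per_marker_contributions(effects, genotypes, stat))
            meta.append((stat, stat, None))
    C = np.vstack(contrib_rows)
    m = genotypes.n_markers
    m_a = {name: int(C[i].sum()) for i, (name, kind, _) in enumerate(meta) if kind == "count"}

    engine = NullEngine(n_perm=n_perm, mode=null_mode, seed=seed, domain=domain)
    rows = []
    for feat in features:
        feat.validate(m)
        draws = engine.draws(C, feat.marker_idx)
        for i, (name, kind, t_crit) in enumerate(meta):
            scale = 1.0 / (2.0 * feat.m_f) if kind == "score" else 1.0
            obs = float(C[i, feat.marker_idx].sum() * scale)
            dr = draws[i] * scale
            p_emp = empirical_pvalue(obs, dr)
            p_par = None
            if kind == "score" and dr.mean() > 0 and dr.var() > 0:
                p_par = satterthwaite_gamma_p(obs, float(dr.mean()), float(dr.var(ddof=1)))
            elif kind == "count":
                p_par = float(stats.hypergeom.sf(obs - 1, m, m_a[name], feat.m_f)) if m_a[name] else 1.0
            rows.append(
                {
                    "feature": feat.name,
                    "m_f": feat.m_f,
                    "statistic": name,
                    "observed": obs,
                    "p_empirical": p_emp,
                    "p_parametric": p_par,
                    "n_perm": n_perm,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["h2_hat"] = fit.h2_
    out.attrs["df_e"] = effects.df_e
    return out
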