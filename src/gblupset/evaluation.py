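"""Detection performance and predictive-ability evaluation.

Detection power is summarized by the F1 score, the harmonic mean of
precision p = TP/(TP+FP) and recall r = TP/(TP+FN), at a set-test p-value
cutoff (default 0.05): causal features below the cutoff are true positives,
null sets below it false positives.

Predictive ability (PA) of the two-component genomic-feature model is the
mean Spearman correlation, over repeated 90/10 line-level splits, between
the total genomic values predicted with all phenotypes and those predicted
with the validation lines' phenotypes masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GRM, complement_grm
from .models import GFBLUP

__all__ = [
    "EvalMetrics",
    "f1_score",
    "classify_detections",
    "gfblup_cv_predictive_ability",
    "significance_vs_pa",
]


@dataclass
class EvalMetrics:
    TP: int
    FP: int
    FN: int
    TN: int
    alpha: float = 0.05

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if (self.TP + self.FP) else 0.0

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else 0.0

    @property
    def f1(self) -> float:
        return f1_score(self.TP, self.FP, self.FN)


def f1_score(TP: int, FP: int, FN: int) -> float:
    """F1 = 2 p r / (p + r); defined as 0 when p + r = 0 (i.e. TP = 0)."""
    if min(TP, FP, FN) < 0:
        raise ValueError("counts must be non-negative")
    p = TP / (TP + FP) if (TP + FP) else 0.0
    r = TP / (TP + FN) if (TP + FN) else 0.0
    return 2.0 * p * r / (p + r) if (p + r) else 0.0


def classify_detections(
    results: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "per_level",
    p_col: str = "p_empirical",
):
    """Score detections of causal features against null sets.

    ``results`` needs columns ``kind`` ('causal'/'null'), ``p_empirical``
    (or ``p_col``), ``dilution`` and ``dataset``.  In ``per_level`` mode an
    :class:`EvalMetrics` is returned per dilution level (null sets, which do
    not vary with dilution, contribute the same FP/TN to each level); in
    ``averaged`` mode each causal feature's test result is first averaged
    over the dilution range per data set, giving one overall metric.
    """
    nulls = results[results["kind"] == "null"]
    causal = results[results["kind"] == "causal"]
    if nulls.empty:
        raise ValueError("no null sets: precision undefined")
    FP = int((nulls[p_col] < alpha).sum())
    TN = int(len(nulls) - FP)
    if mode == "per_level":
        rows = []
        for d, grp in causal.groupby("dilution"):
            TP = int((grp[p_col] < alpha).sum())
            FN = len(grp) - TP
            m = EvalMetrics(TP, FP, FN, TN, alpha)
            rows.append({"dilution": d, "TP": TP, "FP": FP, "FN": FN, "TN": TN,
                         "precision": m.precision, "recall": m.recall, "f1": m.f1})
        return pd.DataFrame(rows).sort_values("dilution").reset_index(drop=True)
    if mode == "averaged":
        mean_p = causal.groupby("dataset")[p_col].mean()
        TP = int((mean_p < alpha).sum())
        FN = len(mean_p) - TP
        return EvalMetrics(TP, FP, FN, TN, alpha)
    raise ValueError("mode must be 'per_level' or 'averaged'")


def gfblup_cv_predictive_ability(
    grm_full: GRM,
    grm_feature: GRM,
    y: np.ndarray,
    lines: np.ndarray,
    *,
    n_folds: int = 50,
    train_frac: float = 0.9,
    seed: int = 0,
    against: str = "prediction",
    X: np.ndarray | None = None,
    **est_kwargs,
):
    """Cross-validated predictive ability of the two-component model.

    Per fold, variance components are re-estimated on a random ``train_frac``
    subset of the lines and the total genomic value g_total = f + r is
    predicted for the held-out lines.  ``against='prediction'`` correlates
    the masked predictions with the all-data predictions (rank correlation);
    ``against='phenotype'`` correlates them with the held-out line means
    (conventional alternative, not the primary definition here).

    Returns (PA, per-fold DataFrame); folds whose REML fit fails to converge
    are skipped and counted.
    """
    y = np.asarray(y, float)
    lines = np.asarray(lines, int)
    grm_rest = complement_grm(grm_full, grm_feature)
    full = GFBLUP(**est_kwargs).fit([grm_feature, grm_rest], y, lines=lines, X=X)
    g_full = full.g_hat_
    obs = np.unique(lines)
    n_train = int(round(train_frac * obs.size))
    rng = np.random.default_rng(seed)
    rows, skipped = [], 0
    for fold in range(n_folds):
        train = rng.choice(obs, size=n_train, replace=False)
        val = np.setdiff1d(obs, train)
        mask = np.isin(lines, train)
        fit = GFBLUP(**est_kwargs).fit(
            [grm_feature, grm_rest], y[mask], lines=lines[mask],
            X=None if X is None else X[mask],
        )
        if not fit.converged_:
            skipped += 1
            continue
        g_cv = fit.g_hat_
        if against == "prediction":
            rho = stats.spearmanr(g_full[val], g_cv[val]).statistic
        elif against == "phenotype":
            ybar = np.array([y[lines == l].mean() for l in val])
            rho = stats.spearmanr(ybar, g_cv[val]).statistic
        else:
            raise ValueError("against must be 'prediction' or 'phenotype'")
        rows.append({"fold": fold, "rho": float(rho), "n_val": val.size})
    detail = pd.DataFrame(rows)
    detail.attrs["skipped"] = skipped
    pa = float(detail["rho"].mean()) if len(detail) else np.nan
    return pa, detail


def significance_vs_pa(pvals, pa) -> float:
    """Spearman correlation between -log(p) of the set test and PA."""
    pvals = np.asarray(pvals, float)
    pa = np.asarray(pa, float)
    if pvals.size != pa.size:
        raise ValueError("pvals and pa must align")
    if pvals.size < 3:
        raise ValueError("need at least 3 features")
    return float(stats.spearmanr(-np.log(pvals), pa).statistic)
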