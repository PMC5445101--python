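"""Desk-scale replications of the simulation-study results.

Each function runs one study component end to end on synthetic genotypes:
phenotypic-variance verification, the correlation structure among set-test
significances over a dilution series, the F1 power floor under the cluster
causal model, null-set p-value calibration, REML parameter recovery, and the
relationship between set-test significance and cross-validated predictive
ability.  All randomness flows from the ``seed`` argument.

Problem sizes default to the desk scale used throughout the package
(200 lines x 20,000 markers with block LD, standing in for a sequenced
inbred panel three orders of magnitude larger); they are arguments, so
larger runs only cost time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import classify_detections, gfblup_cv_predictive_ability
from .genotypes import GenotypeData, GRM, build_grm
from .models import GBLUP, MultiTraitGBLUP
from .pipeline import analyze_dataset
from .settests import FeatureSet
from .simulate import (SimulationScenario, dilute_feature, select_causal_sets,
                       simulate_genotypes, simulate_phenotypes,
                       simulate_two_trait_phenotypes)

__all__ = [
    "build_panel",
    "phenotypic_variance",
    "dilution_series_results",
    "fig_correlations",
    "power_floor",
    "null_calibration",
    "h2_recovery",
    "twotrait_recovery",
    "pa_significance_correlation",
]

DILUTIONS_0_2000 = tuple(range(0, 2001, 100))


def build_panel(seed: int, n_lines: int = 200, n_markers: int = 20_000):
    """Shared synthetic panel: genotypes + all-marker GRM."""
    geno = simulate_genotypes(n_lines, n_markers, seed=seed)
    return geno, build_grm(geno)


def _sub(seed: int, *key: int) -> int:
    """Derived child seed (< 2^31), deterministic in (seed, key)."""
    return int(np.random.default_rng([seed & 0x7FFFFFFF, *key]).integers(2**31))


def phenotypic_variance(
    geno: GenotypeData,
    seed: int,
    *,
    n_datasets: int = 20,
    h2: float = 0.3,
    hf2: float = 0.3,
    n_rep: int = 10,
) -> float:
    """Mean sample variance of y over replicate data sets (target sigma_P^2)."""
    out = []
    for d in range(n_datasets):
        causal = select_causal_sets(geno, "random", seed=_sub(seed, 10, d), null_set_sizes=())
        sc = SimulationScenario(h2=h2, hf2=hf2, n_rep=n_rep, seed=_sub(seed, 11, d))
        ph = simulate_phenotypes(geno, causal, sc)
        out.append(float(ph["value"].var(ddof=1)))
    return float(np.mean(out))


def dilution_series_results(
    geno: GenotypeData,
    grm: GRM,
    seed: int,
    *,
    n_datasets: int = 10,
    h2: float = 0.3,
    hf2: float = 0.3,
    n_rep: int = 5,
    causal_model: str = "random",
    n_perm: int = 2000,
    statistics=("cvat", "score", "sum_s2", "sum_t2", "count_0.05", "count_0.01"),
    dilutions=DILUTIONS_0_2000,
    null_set_sizes: tuple[int, ...] = (),
    fresh_panels: bool = False,
):
    """Set-test results over the dilution series, pooled over data sets.

    With ``fresh_panels`` each replicate data set draws its own synthetic
    genotype panel, so pooled quantities marginalize over panel
    realizations instead of conditioning on a single draw.
    """
    frames = []
    for d in range(n_datasets):
        if fresh_panels:
            geno, grm = build_panel(_sub(seed, 99, d), geno.n_lines, geno.n_markers)
        causal = select_causal_sets(
            geno, causal_model, seed=_sub(seed, 20, d), null_set_sizes=null_set_sizes
        )
        sc = SimulationScenario(h2=h2, hf2=hf2, n_rep=n_rep, causal_model=causal_model,
                                seed=_sub(seed, 21, d))
        ph = simulate_phenotypes(geno, causal, sc)
        feats = [
            dilute_feature(causal, dl, geno.n_markers, seed=_sub(seed, 22, d, dl))
            for dl in dilutions
        ]
        feats += [FeatureSet(f"null{i}", idx) for i, idx in enumerate(causal.null_sets)]
        res = analyze_dataset(geno, ph, feats, grm=grm, statistics=statistics,
                              n_perm=n_perm, seed=_sub(seed, 23, d))
        res["dataset"] = d
        res["kind"] = np.where(res["feature"].str.startswith("null"), "null", "causal")
        res["dilution"] = [int(f.split("+")[1]) if "+" in f else -1 for f in res["feature"]]
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def fig_correlations(results: pd.DataFrame, base: str = "cvat") -> dict[str, float]:
    """Pearson correlations of -log p between the base statistic and the rest."""
    causal = results[results["kind"] == "causal"]
    wide = causal.pivot_table(index=["dataset", "feature"], columns="statistic",
                              values="p_empirical")
    neglog = -np.log(wide)
    out = {}
    for stat in neglog.columns:
        if stat == base:
            continue
        out[stat] = float(np.corrcoef(neglog[base], neglog[stat])[0, 1])
    return out


def power_floor(
    geno: GenotypeData,
    grm: GRM,
    seed: int,
    *,
    n_datasets: int = 20,
    h2: float = 0.5,
    hf2: float = 0.5,
    n_rep: int = 50,
    n_perm: int = 1000,
    alpha: float = 0.05,
    null_set_sizes: tuple[int, ...] = (100, 500, 1000, 5000, 10000),
    fresh_panels: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Minimum F1 (percent) over the dilution range, cluster causal model."""
    res = dilution_series_results(
        geno, grm, seed, n_datasets=n_datasets, h2=h2, hf2=hf2, n_rep=n_rep,
        causal_model="cluster", n_perm=n_perm, statistics=("cvat",),
        null_set_sizes=null_set_sizes, fresh_panels=fresh_panels,
    )
    per_level = classify_detections(res, alpha=alpha, mode="per_level")
    return float(per_level["f1"].min() * 100.0), per_level


def null_calibration(
    geno: GenotypeData,
    grm: GRM,
    seed: int,
    *,
    n_datasets: int = 5,
    n_features: int = 500,
    feature_size: int = 100,
    n_perm: int = 2000,
    statistics=("cvat", "score"),
    h2: float = 0.3,
    hf2: float = 0.3,
    n_rep: int = 10,
) -> pd.DataFrame:
    """Empirical p-values for random marker sets (should be uniform).

    Features are drawn uniformly from *all* markers: a uniformly random set
    is exactly exchangeable with the rotation windows, so the competitive
    null holds by construction.  (Sets restricted to non-causal markers are
    systematically depleted relative to random windows and give slightly
    conservative p-values.)
    """
    per_ds = int(np.ceil(n_features / n_datasets))
    frames = []
    for d in range(n_datasets):
        causal = select_causal_sets(geno, "random", seed=_sub(seed, 30, d), null_set_sizes=())
        sc = SimulationScenario(h2=h2, hf2=hf2, n_rep=n_rep, seed=_sub(seed, 31, d))
        ph = simulate_phenotypes(geno, causal, sc)
        rng = np.random.default_rng(_sub(seed, 32, d))
        feats = [
            FeatureSet(
                f"null{d}_{i}",
                np.sort(rng.choice(geno.n_markers, feature_size, replace=False)),
            )
            for i in range(per_ds)
        ]
        res = analyze_dataset(geno, ph, feats, grm=grm, statistics=statistics,
                              n_perm=n_perm, seed=_sub(seed, 33, d))
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def ks_uniform_p(pvals: np.ndarray) -> float:
    """Kolmogorov-Smirnov p-value against Uniform(0, 1)."""
    return float(stats.kstest(np.asarray(pvals), "uniform").pvalue)


def h2_recovery(
    geno: GenotypeData,
    grm: GRM,
    seed: int,
    *,
    h2_values=(0.1, 0.3, 0.5),
    hf2: float = 0.3,
    n_rep: int = 10,
    n_datasets: int = 20,
) -> dict[float, float]:
    """Mean estimated h2 per generating h2 (all-marker GBLUP fits)."""
    out = {}
    for h2 in h2_values:
        ests = []
        for d in range(n_datasets):
            causal = select_causal_sets(geno, "random", seed=_sub(seed, 40, d), null_set_sizes=())
            sc = SimulationScenario(h2=h2, hf2=hf2, n_rep=n_rep,
                                    seed=_sub(seed, 41, int(h2 * 10), d))
            ph = simulate_phenotypes(geno, causal, sc)
            fit = GBLUP().fit(grm, ph["value"].to_numpy(), lines=ph["line_index"].to_numpy())
            ests.append(fit.h2_)
        out[h2] = float(np.mean(ests))
    return out


def twotrait_recovery(
    grm: GRM,
    seed: int,
    *,
    rho: float = 0.8,
    sigma_g2: float = 30.0,
    sigma_e2: float = 70.0,
    n_rep: int = 2,
    n_datasets: int = 20,
) -> float:
    """Mean estimated genetic correlation for a generating correlation rho."""
    cov = np.array([[sigma_g2, rho * sigma_g2], [rho * sigma_g2, sigma_g2]])
    ests = []
    for d in range(n_datasets):
        df = simulate_two_trait_phenotypes(grm, cov, (sigma_e2, sigma_e2),
                                           n_rep=n_rep, seed=_sub(seed, 50, d))
        d1, d2 = df[df.trait == 1], df[df.trait == 2]
        fit = MultiTraitGBLUP().fit(
            grm, d1["value"].to_numpy(), d2["value"].to_numpy(),
            lines1=d1["line_index"].to_numpy(), lines2=d2["line_index"].to_numpy(),
        )
        ests.append(fit.genetic_corr_)
    return float(np.mean(ests))


def pa_significance_correlation(
    geno: GenotypeData,
    grm: GRM,
    seed: int,
    *,
    n_datasets: int = 10,
    h2: float = 0.5,
    hf2: float = 0.3,
    n_rep: int = 5,
    n_perm: int = 1000,
    n_folds: int = 20,
    dilutions=DILUTIONS_0_2000,
    fresh_panels: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Spearman correlation between CVAT -log p and GFBLUP predictive ability.

    Features span the dilution series; predictive ability is the mean rank
    correlation over ``n_folds`` random 90/10 line-level splits of the
    two-component (feature + rest) model.  The reported correlation is the
    rank correlation across the features of a data set, averaged over
    replicate data sets (the within-data-set correlation is the quantity of
    interest; pooling across data sets would mix in between-data-set
    baseline differences in predictive ability).
    """
    rows = []
    for d in range(n_datasets):
        if fresh_panels:
            geno, grm = build_panel(_sub(seed, 99, d), geno.n_lines, geno.n_markers)
        causal = select_causal_sets(geno, "random", seed=_sub(seed, 60, d), null_set_sizes=())
        sc = SimulationScenario(h2=h2, hf2=hf2, n_rep=n_rep, seed=_sub(seed, 61, d))
        ph = simulate_phenotypes(geno, causal, sc)
        y = ph["value"].to_numpy()
        lines = ph["line_index"].to_numpy()
        feats = [
            dilute_feature(causal, dl, geno.n_markers, seed=_sub(seed, 62, d, dl))
            for dl in dilutions
        ]
        res = analyze_dataset(geno, (y, lines), feats, grm=grm, statistics=("cvat",),
                              n_perm=n_perm, seed=_sub(seed, 63, d))
        pmap = dict(zip(res["feature"], res["p_empirical"]))
        for feat in feats:
            grm_f = build_grm(geno, feat.marker_idx)
            pa, _ = gfblup_cv_predictive_ability(
                grm, grm_f, y, lines, n_folds=n_folds, seed=_sub(seed, 64, d)
            )
            rows.append({"dataset": d, "feature": feat.name, "m_f": feat.m_f,
                         "p_cvat": pmap[feat.name], "pa": pa})
    table = pd.DataFrame(rows)
    per_ds = [
        float(stats.spearmanr(-np.log(g["p_cvat"]), g["pa"]).statistic)
        for _, g in table.groupby("dataset")
    ]
    table.attrs["per_dataset_rho"] = per_ds
    table.attrs["pooled_rho"] = float(
        stats.spearmanr(-np.log(table["p_cvat"]), table["pa"]).statistic
    )
    return float(np.mean(per_ds)), table
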