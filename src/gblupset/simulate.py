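"""Synthetic inbred-line genotypes and simulated quantitative phenotypes.

The generator emulates a DGRP-like panel: fully inbred lines (homozygous
allele counts 0/2), minor allele frequencies >= 0.05, and block-wise linkage
disequilibrium produced by a founder-haplotype copy scheme (per block of
consecutive markers each line copies one of a small founder pool with a
small per-marker mutation probability, so markers within a block are
correlated and blocks are independent).

Phenotypes follow y = Z g1 + Z g2 + e with g1 ~ N(0, G1 s_g1^2) built from a
100-SNP causal feature set C1, g2 ~ N(0, G2 s_g2^2) from 900 background
causal SNPs C2, and iid residuals.  The variance split is parameterized by
the genomic heritability h2 = (s_g1^2 + s_g2^2)/s_P^2 and the feature share
hf2 = s_g1^2/(s_g1^2 + s_g2^2), with total phenotypic variance s_P^2 = 100.
Features are "diluted" by adding non-causal markers to C1; false-positive
behaviour is probed with 50 non-causal null sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GRM, GenotypeData, build_grm
from .settests import FeatureSet

__all__ = [
    "SimulationScenario",
    "CausalConfig",
    "simulate_genotypes",
    "select_causal_sets",
    "simulate_phenotypes",
    "simulate_two_trait_phenotypes",
    "dilute_feature",
    "scenario_grid",
    "run_scenario_grid",
]

#: marker count of a sequenced DGRP-scale panel; desk-scale defaults stand in for this
FULL_PANEL_M = 1_725_755

H2_GRID = (0.1, 0.3, 0.5)
HF2_GRID = (0.1, 0.2, 0.3, 0.5)
NREP_GRID = (5, 10, 50)
CAUSAL_MODELS = ("random", "cluster")
DILUTION_GRID = tuple(range(100, 2001, 100))


@dataclass
class SimulationScenario:
    """One cell of the simulation design."""

    h2: float = 0.3
    hf2: float = 0.3
    n_rep: int = 10
    causal_model: str = "random"
    dilution: int = 0
    sigma_P2: float = 100.0
    replicate_id: int = 0
    seed: int = 0

    @property
    def sigma_g1_2(self) -> float:
        return self.h2 * self.hf2 * self.sigma_P2

    @property
    def sigma_g2_2(self) -> float:
        return self.h2 * (1.0 - self.hf2) * self.sigma_P2

    @property
    def sigma_e2(self) -> float:
        return (1.0 - self.h2) * self.sigma_P2


@dataclass
class CausalConfig:
    """Causal marker sets and matched null sets."""

    C1: np.ndarray
    C2: np.ndarray
    null_sets: list[np.ndarray] = field(default_factory=list)
    causal_model: str = "random"
    cluster_regions: list[np.ndarray] = field(default_factory=list)

    @property
    def causal(self) -> np.ndarray:
        return np.concatenate([self.C1, self.C2])


def _chrom_names(n_chrom: int) -> list[str]:
    base = ["2L", "2R", "3L", "3R", "X", "4"]
    if n_chrom <= len(base):
        return base[:n_chrom]
    return base + [f"chr{i}" for i in range(len(base) + 1, n_chrom + 1)]


def simulate_genotypes(
    n_lines: int = 200,
    n_markers: int = 20_000,
    *,
    n_chrom: int = 5,
    block_len: int = 50,
    n_founders: int = 8,
    flip_prob: float = 0.02,
    maf_range: tuple[float, float] = (0.05, 0.5),
    maf_min: float = 0.05,
    inbred: bool = True,
    seed: int = 0,
) -> GenotypeData:
    """Generate an inbred-line panel with block LD.

    Markers failing the realized-MAF floor are dropped and regenerated, so
    every emitted marker has minor allele frequency >= ``maf_min``.
    """
    if n_markers < 10 * block_len:
        raise ValueError("need at least 10 blocks of markers")
    lo, hi = maf_range
    if not (0 < lo < hi <= 0.5):
        raise ValueError("degenerate maf_range")
    rng = np.random.default_rng(seed)
    cols: list[np.ndarray] = []
    got = 0
    while got < n_markers:
        want = n_markers - got
        n_blocks = max(1, int(np.ceil(1.2 * want / block_len)))
        for _ in range(n_blocks):
            q = rng.uniform(lo, hi, size=block_len)
            founders = (rng.random((n_founders, block_len)) < q).astype(np.int8)
            if inbred:
                assign = rng.integers(n_founders, size=n_lines)
                hap = founders[assign]
                flips = rng.random((n_lines, block_len)) < flip_prob
                A_blk = 2 * (hap ^ flips)
            else:
                A_blk = np.zeros((n_lines, block_len), dtype=np.int8)
                for _h in range(2):
                    assign = rng.integers(n_founders, size=n_lines)
                    hap = founders[assign]
                    flips = rng.random((n_lines, block_len)) < flip_prob
                    A_blk += hap ^ flips
            freq = A_blk.mean(axis=0) / 2.0
            flip_col = freq > 0.5
            A_blk[:, flip_col] = 2 - A_blk[:, flip_col]
            maf = np.minimum(freq, 1.0 - freq)
            keep = maf >= maf_min
            if keep.any():
                cols.append(A_blk[:, keep].astype(np.int8))
        got = sum(c.shape[1] for c in cols)
    A = np.concatenate(cols, axis=1)[:, :n_markers]

    names = _chrom_names(n_chrom)
    bounds = np.linspace(0, n_markers, n_chrom + 1).astype(int)
    chrom = np.empty(n_markers, dtype=object)
    pos = np.empty(n_markers, dtype=np.int64)
    for c in range(n_chrom):
        sl = slice(bounds[c], bounds[c + 1])
        chrom[sl] = names[c]
        pos[sl] = 1000 * (np.arange(bounds[c + 1] - bounds[c]) + 1)
    return GenotypeData(
        line_ids=np.array([f"line{i:04d}" for i in range(n_lines)]),
        marker_ids=np.array([f"snp{i:06d}" for i in range(n_markers)]),
        chrom=chrom.astype(str),
        pos=pos,
        A=A,
    )


def select_causal_sets(
    genotypes: GenotypeData,
    causal_model: str = "random",
    seed: int = 0,
    *,
    n_c1: int = 100,
    n_c2: int = 900,
    null_set_sizes: tuple[int, ...] = (100, 500, 1000, 5000, 10000),
    n_null_per_size: int = 10,
    cluster_region_span: int = 50,
    n_cluster_regions: int = 20,
    full_panel_proportions: bool = False,
) -> CausalConfig:
    """Draw the causal sets C1 (feature, 100 SNPs) and C2 (background, 900).

    Under the cluster model C1 comes from ``n_cluster_regions`` disjoint runs
    of ``cluster_region_span`` consecutive markers (n_c1 / n_regions from
    each); under the random model both sets are drawn genome-wide.  Null sets
    are sampled from the non-causal pool (each set internally without
    replacement; different sets may overlap one another).
    """
    m = genotypes.n_markers
    rng = np.random.default_rng(seed)
    regions: list[np.ndarray] = []
    if causal_model == "random":
        perm = rng.permutation(m)
        C1 = np.sort(perm[:n_c1])
        C2 = np.sort(perm[n_c1 : n_c1 + n_c2])
    elif causal_model == "cluster":
        if n_c1 % n_cluster_regions:
            raise ValueError("n_c1 must divide evenly over cluster regions")
        per_region = n_c1 // n_cluster_regions
        taken = np.zeros(m, dtype=bool)
        tries = 0
        while len(regions) < n_cluster_regions:
            tries += 1
            if tries > 100_000:
                raise RuntimeError("could not place disjoint cluster regions")
            start = int(rng.integers(0, m - cluster_region_span + 1))
            span = np.arange(start, start + cluster_region_span)
            if genotypes.chrom[span[0]] != genotypes.chrom[span[-1]]:
                continue
            if taken[span].any():
                continue
            taken[span] = True
            regions.append(span)
        C1 = np.sort(
            np.concatenate(
                [rng.choice(r, size=per_region, replace=False) for r in regions]
            )
        )
        pool = np.setdiff1d(np.arange(m), C1)
        C2 = np.sort(rng.choice(pool, size=n_c2, replace=False))
    else:
        raise ValueError(f"unknown causal model {causal_model!r}")

    sizes = list(null_set_sizes)
    if full_panel_proportions:
        sizes = [max(10, int(round(s * m / FULL_PANEL_M))) for s in sizes]
    pool = np.setdiff1d(np.arange(m), np.concatenate([C1, C2]))
    null_sets = []
    for s in sizes:
        if s > pool.size:
            raise ValueError(f"null-set size {s} exceeds non-causal pool {pool.size}")
        for _ in range(n_null_per_size):
            null_sets.append(np.sort(rng.choice(pool, size=s, replace=False)))
    return CausalConfig(C1=C1, C2=C2, null_sets=null_sets,
                        causal_model=causal_model, cluster_regions=regions)


def _draw_mvn(grm: GRM, sigma2: float, rng: np.random.Generator) -> np.ndarray:
    """Genomic values with per-line variance sigma2 and correlation from G.

    Drawn as N(0, G sigma2 / mean_diag(G)) via eigendecomposition (negative
    eigenvalues clipped), so the stated variance refers to the realized
    per-line scale regardless of the GRM's diagonal (~2 for inbred panels).
    """
    d, U = grm.eig()
    d = np.clip(d, 0.0, None)
    z = rng.standard_normal(d.size)
    return U @ (np.sqrt(d * sigma2 / grm.mean_diag) * z)


def simulate_phenotypes(
    genotypes: GenotypeData,
    causal: CausalConfig,
    scenario: SimulationScenario,
    *,
    grm_c1: GRM | None = None,
    grm_c2: GRM | None = None,
) -> pd.DataFrame:
    """Simulate replicate-level phenotypes y = Z g1 + Z g2 + e.

    Returns a table with columns line_id, line_index, replicate, value.
    The causal GRMs may be passed in to avoid recomputation.
    """
    rng = np.random.default_rng(scenario.seed)
    n = genotypes.n_lines
    g1 = np.zeros(n)
    g2 = np.zeros(n)
    if scenario.sigma_g1_2 > 0:
        grm_c1 = grm_c1 or build_grm(genotypes, causal.C1)
        g1 = _draw_mvn(grm_c1, scenario.sigma_g1_2, rng)
    if scenario.sigma_g2_2 > 0:
        grm_c2 = grm_c2 or build_grm(genotypes, causal.C2)
        g2 = _draw_mvn(grm_c2, scenario.sigma_g2_2, rng)
    lines = np.repeat(np.arange(n), scenario.n_rep)
    e = rng.standard_normal(lines.size) * np.sqrt(scenario.sigma_e2)
    y = g1[lines] + g2[lines] + e
    return pd.DataFrame(
        {
            "line_id": genotypes.line_ids[lines],
            "line_index": lines,
            "replicate": np.tile(np.arange(scenario.n_rep), n),
            "value": y,
        }
    )


def simulate_two_trait_phenotypes(
    grm: GRM,
    trait_cov: np.ndarray,
    resid_var: tuple[float, float],
    n_rep: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Two traits with genetic covariance G (x) trait_cov and iid residuals."""
    rng = np.random.default_rng(seed)
    trait_cov = np.asarray(trait_cov, dtype=float)
    d, U = grm.eig()
    d = np.clip(d, 0.0, None)
    Lc = np.linalg.cholesky(trait_cov + 1e-12 * np.eye(2))
    Zg = rng.standard_normal((d.size, 2))
    g = (U * np.sqrt(d / grm.mean_diag)[None, :]) @ Zg @ Lc.T  # (n_lines, 2)
    n = grm.n
    lines = np.repeat(np.arange(n), n_rep)
    frames = []
    for t in range(2):
        e = rng.standard_normal(lines.size) * np.sqrt(resid_var[t])
        frames.append(
            pd.DataFrame(
                {
                    "trait": t + 1,
                    "line_index": lines,
                    "replicate": np.tile(np.arange(n_rep), n),
                    "value": g[lines, t] + e,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def dilute_feature(
    causal: CausalConfig,
    n_noncausal: int,
    n_markers: int,
    seed: int = 0,
    name: str | None = None,
) -> FeatureSet:
    """Feature = C1 plus ``n_noncausal`` markers sampled outside C1 and C2."""
    rng = np.random.default_rng(seed)
    pool = np.setdiff1d(np.arange(n_markers), causal.causal)
    if n_noncausal > pool.size:
        raise ValueError("not enough non-causal markers for requested dilution")
    extra = rng.choice(pool, size=n_noncausal, replace=False) if n_noncausal else np.empty(0, dtype=np.int64)
    idx = np.sort(np.concatenate([causal.C1, extra.astype(np.int64)]))
    return FeatureSet(name=name or f"C1+{n_noncausal}", marker_idx=idx)


def scenario_grid(
    h2_values=H2_GRID,
    hf2_values=HF2_GRID,
    n_rep_values=NREP_GRID,
    causal_models=CAUSAL_MODELS,
    dilution_values=DILUTION_GRID,
    sigma_P2: float = 100.0,
) -> list[SimulationScenario]:
    """Full factorial scenario list (3 x 4 x 3 x 2 x 20 = 1,440 by default)."""
    return [
        SimulationScenario(h2=h2, hf2=hf2, n_rep=nr, causal_model=cm,
                           dilution=dl, sigma_P2=sigma_P2)
        for nr, h2, hf2, cm, dl in itertools.product(
            n_rep_values, h2_values, hf2_values, causal_models, dilution_values
        )
    ]


def run_scenario_grid(
    genotypes: GenotypeData,
    scenarios: list[SimulationScenario],
    *,
    n_datasets: int = 1,
    n_perm: int = 1000,
    statistics: tuple[str, ...] = ("cvat", "score", "sum_s2", "sum_t2", "count_0.05", "count_0.01"),
    include_null_sets: bool = False,
    null_set_sizes: tuple[int, ...] = (100, 500, 1000, 5000, 10000),
    seed: int = 0,
    grm=None,
) -> pd.DataFrame:
    """Run the set tests over scenario cells.

    Cells sharing (h2, hf2, n_rep, causal_model) reuse the same data set per
    replicate (dilution only changes the feature, as in the study design).
    Returns one row per (scenario, dataset, feature, statistic).
    """
    from .pipeline import analyze_dataset  # local import to avoid cycle

    grm = grm or build_grm(genotypes)
    by_cell: dict[tuple, list[int]] = {}
    for sc in scenarios:
        by_cell.setdefault((sc.h2, sc.hf2, sc.n_rep, sc.causal_model, sc.sigma_P2), []).append(sc.dilution)
    rows = []
    for cell, dilutions in by_cell.items():
        h2, hf2, n_rep, cm, sP2 = cell
        for d in range(n_datasets):
            key = abs(hash((round(h2, 3), round(hf2, 3), n_rep, cm, d))) % (2**31)
            causal = select_causal_sets(
                genotypes, cm, seed=np.random.default_rng([seed, key, 1]).integers(2**31),
                null_set_sizes=null_set_sizes if include_null_sets else (),
            )
            sc = SimulationScenario(
                h2=h2, hf2=hf2, n_rep=n_rep, causal_model=cm, sigma_P2=sP2,
                replicate_id=d,
                seed=int(np.random.default_rng([seed, key, 2]).integers(2**31)),
            )
            pheno = simulate_phenotypes(genotypes, causal, sc)
            features = [
                dilute_feature(causal, dl, genotypes.n_markers,
                               seed=int(np.random.default_rng([seed, key, 3, dl]).integers(2**31)))
                for dl in sorted(set(dilutions))
            ]
            null_features = [
                FeatureSet(name=f"null{i}", marker_idx=idx)
                for i, idx in enumerate(causal.null_sets)
            ]
            res = analyze_dataset(
                genotypes, pheno, features + null_features, grm=grm,
                statistics=statistics, n_perm=n_perm, seed=int(np.random.default_rng([seed, key, 4]).integers(2**31)),
            )
            res["kind"] = np.where(res["feature"].str.startswith("null"), "null", "causal")
            res["dilution"] = [
                int(f.split("+")[1]) if "+" in f else -1 for f in res["feature"]
            ]
            res["h2"], res["hf2"], res["n_rep"], res["causal_model"], res["dataset"] = (
                h2, hf2, n_rep, cm, d,
            )
            rows.append(res)
    return pd.concat(rows, ignore_index=True)
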