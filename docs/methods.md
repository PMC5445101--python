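# Methods

## Model

The core model is genomic BLUP (GBLUP): for phenotypic records **y** on a
panel of genotyped lines,

    y = X b + Z g + e,        g ~ N(0, G σ_g²),   e ~ N(0, I σ_e²),

where **Z** links records to lines and **G** = **WW**′/m is the genomic
relationship matrix built from the centered and scaled allele-count matrix,
w_i = (a_i − 2p_i)/√(2p_i(1−p_i)) with p_i the minor allele frequency.
Extensions fitted by the same machinery:

* **GFBLUP** — several genomic components g_i ~ N(0, G_i σ_gi²) built from
  marker subsets (e.g. a genomic feature and the rest of the genome);
* **two-trait GBLUP** — g ~ N(0, G ⊗ Σ_g) with a 2×2 genetic covariance,
  per-trait residual variances (residual covariance fixed to zero: the two
  traits are assumed measured on different individuals), and optional
  replicate-within-line random effects.

Per-marker effects are recovered from the predicted genomic values by the
pseudo-inverse back-solve ŝ = W′(WW′)⁻ĝ, their variances from
Var(ŝ) = W′(WW′)⁻ Var(ĝ) (WW′)⁻ W, and single-marker statistics
t_j = ŝ_j/√Var(ŝ_j) are referred to a t distribution with the residual
degrees of freedom df_e = n − tr(H) of the penalized fit.

Four set statistics measure the association of a marker set f:

| statistic | definition | parametric null |
|---|---|---|
| CVAT  | T = ĝ′ĝ_f, ĝ_f = W_f ŝ_f | — |
| Score | T = ½ ê′ Z G_f Z′ ê, ê = V̂⁻¹(y − Xb̂) | moment-matched Gamma |
| Sum   | T = Σ_f ŝ_i² (or t_i²) | — |
| Count | T = Σ_f I(\|t_i\| > t₀) | Hyper(m, m_a, m_f) |

All four are sums of per-marker contributions, so one competitive-null
engine serves them all: the genome is treated as circular, the contribution
vector is rotated by a random offset (preserving the multiset of
contributions and the local LD structure of the statistics), and the
feature statistic is recomputed at its original positions.  The empirical
p-value is (#{T_perm ≥ T_obs} + 1)/(n_perm + 1); the add-one estimator keeps
p strictly positive (the raw proportion is available by flag).  A
random-marker-set null and a genic-only rotation domain are alternatives.

CVAT extends to a per-gene decomposition (gene contributions reported per
SNP because gene sizes vary) and to two traits: T_MF = ĝ₁′ĝ_f2 and
T_FM = ĝ₂′ĝ_f1 measure the covariance between one trait's total genomic
value and the other trait's feature value.

## REML

Variance components are estimated by average-information (AI) REML with:

* Levenberg–Marquardt damping of the AI step and step-halving so the
  restricted log-likelihood never decreases across accepted iterations;
* an active-set rule: variances pinned at the floor (10⁻⁸ × var(y)) whose
  gradient points further down are held fixed for that iteration;
* projection of the 2×2 genetic covariance onto the PSD cone (eigenvalue
  clipping) after every step, with the correlation clamped to ±0.9999;
* convergence when |Δ loglik| < 10⁻⁶ and max |Δθ|/(|θ|+1) < 10⁻⁵,
  at most 200 iterations; boundary convergence is reported in the fit.

**Exact line-mean reduction.**  When the fixed-effect design is constant
within line and residuals are iid (the replicate structure of an inbred
panel), the restricted likelihood factorizes into a between-line part on
line means (with residual covariance σ_e² diag(1/r_l)) and a within-line
scaled-χ² term ν log σ_e² + SSE/σ_e².  The engine exploits this identity —
estimates, likelihood differences, BLUPs, projected residuals and df_e are
exactly those of the replicate-level model (verified against a dense
replicate-level fit in the tests) — making 10,000-record fits a 200×200
problem.  df_e is computed exactly as tr(R P̂) (equivalently n − tr(H)), so
no stochastic trace estimation is needed.

Everywhere an inverse of G or WW′ appears, an eigen-based pseudo-inverse
with relative cutoff 10⁻⁸·λ_max is used (G is singular by construction:
column centering removes one dimension).

**Scale convention for inbred panels.**  With Hardy–Weinberg scaling on
fully homozygous lines, diag(G) ≈ 2, so σ_g² under g ~ N(0, G σ_g²) is half
the per-line genomic variance.  The package therefore (i) reports
heritability as h² = d̄σ̂_g²/(d̄σ̂_g² + σ̂_e²) with d̄ = mean diag(G), and
(ii) simulates genomic values with covariance G σ²/d̄, so that stated
variance components refer to the realized per-line scale and the simulated
total phenotypic variance equals σ_P².  Set statistics are invariant to
this convention; G itself is never rescaled.

## Synthetic data

The generator emulates a DGRP-like panel of fully inbred, sequenced lines:

* **genotypes** — homozygous calls 0/2; per block of 50 consecutive markers
  each line copies one of 8 founder haplotypes with per-marker flip
  probability 0.02 (within-block LD, independence across blocks); marker
  MAFs uniform on [0.05, 0.5] with the realized-MAF floor enforced; five
  chromosome arms for the circular ordering.  Desk-scale default: 200 lines
  × 20,000 markers.
* **causal structure** — 1,000 causal SNPs split into C1 (100, the feature
  causal set) and C2 (900, background); under the cluster model C1 is drawn
  5 per region from 20 disjoint 50-marker regions.  Features are diluted by
  adding 100–2,000 non-causal SNPs to C1; 50 non-causal null sets (10 each
  of 100/500/1k/5k/10k SNPs) probe the false-positive rate.
* **phenotypes** — y = Zg₁ + Zg₂ + e with σ_g1² = h²·h_f²·σ_P²,
  σ_g2² = h²(1−h_f²)·σ_P², σ_e² = (1−h²)·σ_P², σ_P² = 100; the factorial
  design h² ∈ {0.1, 0.3, 0.5} × h_f² ∈ {0.1, 0.2, 0.3, 0.5} ×
  N_rep ∈ {5, 10, 50} × {random, cluster} × 20 dilution levels gives 1,440
  scenario cells.

What the generator does **not** emulate: real long-range LD, population
structure and inversion polymorphisms, MAF-dependent effect sizes, and —
critically — the sequence-scale marker density.  A 1,000-SNP causal set in a
20,000-marker panel is 5% of the genome (vs 0.06% in a 1.7M-SNP panel), so
random or rotated marker sets of a few thousand markers carry appreciable
causal signal.  Passing tests therefore demonstrate the statistics'
algebra, calibration and relative behaviour, not absolute power at
sequence scale; see Limitations.

## Numerical and design choices

* Score-test null model: the all-marker GBLUP (fitted once); the
  exclude-feature null (refit per feature on the complement GRM) is opt-in.
* Satterthwaite moments for the score test's Gamma approximation are taken
  from the permutation sample, aligning the parametric and competitive
  nulls; the gamma and empirical p agree to ~0.02 in tests.
* Count-test thresholds are single-marker p cutoffs (0.05, 0.01 by
  default) converted through the t(df_e) quantile; the variance floor
  10⁻¹² maps zero-variance markers to t = 0, p = 1, flagged.
* Rotation offsets are drawn uniformly from 1..m per permutation stream;
  each feature gets its own deterministic stream derived from the engine
  seed and the feature's marker indices, so results are bit-reproducible
  and feature p-values are not artificially coupled.
* Ties in the empirical p count as exceedances (≥, conservative).
* Cross-validated predictive ability: per 90/10 line-level split (random
  draws, not a partition), variance components are re-estimated on the
  training lines and the total genomic value f̂ + r̂ of the held-out lines
  is compared (Spearman) with the all-data predictions; the mean over
  splits is the feature's PA.  The conventional prediction-vs-phenotype
  variant is available by flag.
* With m ≫ n the back-solve gives ŝ ∝ W′ê, so the sum-of-ŝ² statistic is
  per-feature proportional to the score statistic and the two share
  permutation p-values under a common engine.  Distinguishing them
  requires different null mechanisms per statistic, which this package
  deliberately does not do.
* The significance-vs-PA correlation is reported as the within-data-set
  Spearman across the dilution features, averaged over replicate data
  sets; pooling points across data sets mixes in between-data-set baseline
  PA differences and attenuates the association.

## Problem sizes

The study replications marginalize over panel realizations: each replicate
data set draws a fresh synthetic genotype panel.  A single synthetic panel
is an exchangeable nuisance draw (unlike a real reference panel, which is
itself the study population), and desk-scale results vary appreciably
between panel draws, so conditioning on one draw would make headline
numbers panel-lottery artifacts.

Default experiment sizes (all arguments): 200 lines × 20,000 markers;
10 replicate data sets × 21 dilution features at 2,000 permutations for the
statistic-correlation study; 20 data sets at 1,000 permutations for the
power floor; 500 null features for calibration; 20 data sets per
heritability for REML recovery; 10 data sets × 20 cross-validation splits
for predictive ability.

## Limitations

* Desk-scale causal density (5% of markers causal) contaminates the
  competitive null for large or heavily diluted features: far-dilution
  recall under the cluster model drops to 0.3–0.5 where a sequence-scale
  panel retains near-full power, so the minimum F1 over the full dilution
  range lands near 25–30% rather than above 40%.  Small-dilution F1
  reaches the calibrated ceiling (~0.57 given 50 null sets at α = 0.05),
  and p-values stay calibrated — the loss is power, not validity.
* Two-trait REML with a genetic correlation at the ±1 boundary converges
  slowly (boundary crawling under PSD projection).
* Dense REML paths (non-line-constant fixed effects, replicate-within-line
  components) are O(n³) in the number of records and intended for n of a
  few thousand at most.
* The hypergeometric count null ignores LD between markers; it is reported
  alongside the empirical p, not instead of it.
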