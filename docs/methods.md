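# Methods

## Model

The trait measured in two non-overlapping populations is treated as two
correlated traits. Stacking the phenotype records of both populations
(population 1 first), the model for K genomic kernels is

    y = X b + Σ_k Z a_k + e,
    [a_{1,k}; a_{2,k}] ~ N(0, M_k ⊗ G_k),   e ~ N(0, R ⊗ I),

where `G_k` is the VanRaden genomic relationship matrix built from the SNPs
of region class k, `M_k` its 2×2 genetic (co)variance matrix, and `R =
diag(σ²_e1, σ²_e2)`. The residual covariance between populations is
structurally zero — no individual has records in both populations, so it is
inestimable — and fixed effects default to one intercept (overall mean) per
trait.

Because every individual carries a record for exactly one trait, the
phenotypic covariance of the stacked records reduces to an n×n matrix with
entries

    V[i,j] = Σ_k M_k[t_i, t_j] · G_k[i, j] + δ_ij σ²_e,t_i ,

where `t_i` is the population of record i. No Kronecker product is ever
materialised; all REML and BLUP computations are dense operations on this
n×n V.

Derived quantities: `h²_p = Σ_k σ²_{ap,k} / (Σ_k σ²_{ap,k} + σ²_{ep})` and,
per kernel, `r_{g,k} = σ_{a12,k} / √(σ²_{a1,k} σ²_{a2,k})`. Standard errors
come from the inverse average-information matrix by the delta method.

## GRM conventions

`G = WW'/Σ_j 2p_j(1−p_j)` with `w_ij = m_ij − 2p_j`. The allele counted as
2 is the first `.bim` allele, and `p_j` is the counted-allele frequency on
the pooled two-population sample even when it exceeds 0.5 — centering
requires the counted-allele frequency, and using the literal minor-allele
frequency would mis-center SNPs whose counted allele is major. Missing
genotypes surviving QC are mean-imputed (`w = 0`), which keeps column means
exactly zero. Region-restricted GRMs use region-restricted denominators, so
each kernel is a standalone VanRaden matrix and each fitted `M_k` is
interpretable as that region class's genetic covariance. A consequence used
throughout (and tested) is the exact reconstruction identity
`G_ALL = Σ_k denom_k G_k / Σ_k denom_k` over any disjoint exhaustive SNP
partition.

## Quality control

SNPs are removed when the missing rate exceeds 1%, the minor allele
frequency is below 0.05, or a 1-df chi-square Hardy–Weinberg test on the
pooled sample gives p < 1e-6. The chi-square (rather than exact) test
matches common chip-QC practice; pooling the two populations is a
simplification (HWE can fail in a pooled sample through the Wahlund effect,
which slightly over-filters differentiated SNPs). Monomorphic SNPs get
p = 1 by convention and are left to the MAF filter. Phenotypes can be
rank-transformed with a quantile (inverse-normal) transform: rank r of n
(average ranks for ties) maps to the standard-normal quantile of
(r − 0.5)/n.

## LD-block partitioning

The genome is split per chromosome by recursive bisection: while any block
exceeds `max_block_snps` (default 200), the largest block is split at the
admissible breakpoint (both halves ≥ `min_snps`, default 25) minimising the
local cross-LD score — the sum of genotype r² over pairs within a
`window` (default 50) SNPs on either side of the break. Ties go to the
leftmost breakpoint, making the procedure deterministic. The windowed score
keeps each candidate O(window²) and reflects that independence matters most
near the boundary. Genotype (not haplotype) correlation is used; phasing is
out of scope. Externally supplied block tables (TSV: chrom, start_bp,
end_bp, block_id; 1-based inclusive) bypass the splitter.

## REML

Average-information REML. Parameters are optimised in unconstrained
coordinates — log variances and a Fisher-z transformed correlation per
kernel — which enforces positive semidefiniteness by construction and, more
importantly, avoids the boundary pathology of clamped natural-scale
updates: a clamped Newton iteration can pin a variance at its floor at a
non-stationary point and declare convergence (we observed exactly this on
low-variance block kernels before adopting the transformation). The score
and AI matrix are computed on the natural scale and pulled back through the
Jacobian; the first 3 steps are Levenberg-damped, and every step is halved
until the restricted log-likelihood does not decrease, so accepted
iterations are monotone. Convergence requires a log-likelihood gain below
`tol` (default 1e-8) with a small parameter change, or two consecutive
sub-`tol` gains (a numerically flat likelihood). Correlations are bounded
at |r| ≤ 0.999 (boundary estimates display as ±1.0 after rounding) and
variances at 1e-8 × the phenotypic variance. Initialisation splits each
population's phenotypic variance 50/50 between genetic and residual, the
genetic half equally across kernels, covariances at zero. The
log-likelihood includes the full `−(n−p)/2·log 2π` constant.

Each iteration costs one Cholesky of V plus one explicit inverse (for the
projection matrix P), i.e. O(n³) with n the number of phenotyped records —
entirely adequate at the scales this package targets (hundreds to a few
thousand records). The covariance test `lrt_zero_covariance` refits with
σ_{a12,k} fixed at zero (Fisher-z pinned at 0) and refers
2·(llₓ − ll₀), clamped at zero, to a 1-df chi-square.

## Local genetic correlation and region classes

Every block is analysed by an exact bivariate one-kernel REML fit on the
block-restricted GRM, regardless of its univariate signal, giving `r̂_lgc`
and a covariance-LRT p-value. This replaces summary-statistic LGC
approximations: at the scales handled here the exact fit is affordable, has
the same estimand, and needs no GWAS layer. Blocks whose fit fails or whose
genetic variance collapses to the boundary yield an undefined record and
fall into the default class — conservative, and it keeps partitions
exhaustive. Block fits use a looser tolerance (1e-4, ≤ 60 iterations):
near-boundary precision does not change classification.

Two classification schemes:

* **significance (SIG/NON)** — the `top_k` (default 20) blocks with the
  smallest p-values are SIG; ties at the boundary go to the earlier block
  in genome order; undefined blocks are never SIG;
* **magnitude (POS/NEG/RES)** — `r̂ ≥ threshold` → POS, `r̂ ≤ −threshold`
  → NEG (default threshold 0.5, boundary inclusive), everything else RES.

Point estimates are used as is; no shrinkage is applied. At small sample
sizes low-variance blocks produce boundary estimates (±1) with large
p-values — such blocks can be misclassified by the magnitude scheme, but
since they carry little variance the misassigned kernels are barely
perturbed.

## Prediction and cross-validation

All five models share one BLUP core: fixed effects by GLS, then per kernel
`â_k = (M_k-weighted cross-kernel rows) · V⁻¹(y − X b̂)`; total GEBVs are
exact sums of kernel components. A dense Henderson mixed-model-equations
solver exists purely as a cross-check (it requires invertible `M_k ⊗ G_k`,
so it is exercised on jittered full-rank instances) and must agree with the
GLS path to 1e-8.

Candidates (validation individuals) are included in the GRMs — genomic
relationships are known from genotypes — but their phenotypes never enter
REML or the BLUP right-hand side. In cross-validation, variance components
and (by default) the LGC classification are re-estimated on every training
split; a `classes_policy="fixed"` option classifies once on the full data,
which is cheaper but lets validation phenotypes influence region classes
(documented leakage, off by default). Folds are stratified by population so
unbalanced data never produce folds devoid of one population; metrics (r =
Pearson correlation of response with GEBV, b = OLS slope of response on
GEBV) are computed per population on the pooled validation predictions of
each repeat, then summarised as mean ± SD over repeats. Every model sees
identical folds, so per-repeat differences are paired.

## Synthetic data generator

The generator produces exactly the structure the partitioned models target,
with deterministic control:

* **genotypes** — per haplotype, a latent Gaussian AR(1) chain (parameter
  ρ, default 0.9) thresholded at Φ⁻¹(p_j) gives within-block adjacent-SNP
  correlation ≈ ρ and exactly zero correlation across block boundaries;
  genotype = sum of two independent haplotypes; allele frequencies are
  uniform on [maf_min, 1 − maf_min] (default maf_min 0.1) and shared
  between populations (an optional logit-scale drift perturbs them);
* **effects** — per block, causal-SNP effect pairs are bivariate normal
  with the block's target correlation; each block's genic contribution is
  rescaled so it carries its configured variance share and total genetic
  variance is 1 per population; residuals are independent between
  populations with variance (1 − h²)/h² (default h² = 0.5, a moderately
  heritable quantitative trait).

Defaults describe an unbalanced two-population design (375/125, ~3:1 — in
the range typical when a large reference population is paired with a
smaller one) over 2 chromosomes × 5 blocks × 60 SNPs. The `heterogeneous`
preset plants 20% of blocks at r_lgc = +0.9, 20% at −0.9 and 60% at 0,
with variance shares weighted 8 : 2 : 0.5. Two considerations fixed these
weights: (i) per-block REML needs detectable per-block variance at this
scale, so the genetic signal is concentrated in the correlated regions — a
major-QTL-like architecture of the kind where partitioned models show their
largest gains; and (ii) the global genetic correlation implied by the
share-weighted average (≈ +0.47) is clearly positive, the regime in which
multi-trait GBLUP is expected to beat single-trait GBLUP. The `null` preset
(all r_lgc = 0, equal shares) drives type-I-error suites; `homogeneous-<r>`
sets every block to the same correlation.

What the generator does **not** emulate: realistic allele-frequency
spectra, demographic history, selection, pedigree structure, genotyping
error, or polygenic architectures in which local correlation varies
smoothly rather than by block. Passing tests therefore demonstrate
correctness of the estimation and prediction machinery and the qualitative
behaviour of the models under planted heterogeneity — not performance on
any particular real dataset.

## Problem sizes used in the shipped experiments

The repository's experiment suites run on one CPU in minutes, with sizes
chosen as the smallest that leave the statistical conclusions stable:
parameter recovery at n = 500 per population, m = 2000 SNPs, 20 replicates;
LRT calibration on 200 block-level tests at n = 150/100; the model-ranking
experiment at the preset defaults with 20 paired 80/20 splits. The
cross-validation driver itself supports the full repeated 10×10-fold
protocol.

## Known limitations

* Two populations only; residual covariance fixed at zero (structural).
* At most the three POS/NEG/RES kernels; no leave-one-chromosome-out GRMs,
  dominance or epistasis kernels.
* The per-block REML estimator of local genetic correlation is noisy for
  blocks with small genetic variance; classification inherits that noise
  (boundary ±1 estimates), exactly as summary-statistic LGC estimators do
  at low power.
* The LD splitter optimises a windowed breakpoint score; it does not use
  recombination maps and makes no claim of reproducing any published block
  atlas.
* Genotype imputation, de-regressed-proof derivation and GWAS summary
  statistics are out of scope; responses are taken as pre-corrected values.
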