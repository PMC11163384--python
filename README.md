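# lgcblup

Genomic prediction across two populations using **local genetic
correlations**.

When the same trait is measured in two populations (two breeds, two cohorts,
two environments), a multi-trait GBLUP model can borrow information between
them through the *global* genetic correlation r<sub>g</sub>. But the genetic
correlation is rarely uniform along the genome: some LD regions carry effects
that agree strongly between the populations, some carry effects of opposite
sign, and most carry little shared signal. A single genome-wide r<sub>g</sub>
averages these regimes away. `lgcblup` implements prediction models that
instead partition the genome into approximately independent LD blocks,
estimate each block's **local genetic correlation (LGC)** by exact bivariate
REML, and give each class of regions its own genomic relationship kernel and
its own 2×2 genetic covariance matrix.

## The models

All models are built on the bivariate linear mixed model

```
[y1]   [X1  0] [b1]   [Z1  0] [a1]   [e1]         [a1]              [e1]
[y2] = [0  X2] [b2] + [0  Z2] [a2] + [e2],        [a2] ~ N(0, M⊗G), [e2] ~ N(0, R⊗I)
```

with `G = WW' / Σ 2pⱼ(1−pⱼ)` the VanRaden genomic relationship matrix
(`w_ij = m_ij − 2pⱼ`, pooled-sample allele frequencies),
`M = [[σ²ₐ₁, σₐ₁₂], [σₐ₁₂, σ²ₐ₂]]` and diagonal residual `R`. Heritabilities
are `h²ₚ = σ²ₐₚ/(σ²ₐₚ+σ²ₑₚ)` and the genetic correlation is
`r_g = σₐ₁₂/√(σ²ₐ₁σ²ₐ₂)`.

| Estimator | Kernels | Idea |
|---|---|---|
| `STGBLUP` | 1 | single-trait GBLUP within one population |
| `STGBLUPCombined` | 1 | single-trait GBLUP on the pooled populations |
| `MTGBLUP` | 1 | bivariate model, global r_g |
| `LGCModel1` | 2 (SIG/NON) | regions with the most significant LGC get their own kernel (top-k smallest LGC p-values, default k = 20) |
| `LGCModel2` | 3 (POS/NEG/RES) | regions split by LGC sign/magnitude (default \|r̂\| ≥ 0.5) |

Per-block LGC is estimated by refitting the bivariate model with the
block-restricted GRM as its only kernel; significance comes from a 1-df
likelihood-ratio test of σₐ₁₂ = 0. Variance components are estimated by
average-information REML in log-variance / Fisher-z coordinates. Prediction
solves BLUP by GLS + conditional expectation (a Henderson mixed-model-equation
path exists as a cross-check), and total GEBVs are exact sums of per-kernel
components.

## Worked example

```python
import numpy as np
from lgcblup import (paper_like_scenario, simulate_dataset, center_genotypes,
                     make_grm, make_model_spec, fit_reml, derive_params,
                     MTGBLUP, LGCModel2, STGBLUP, run_cv)

cfg = paper_like_scenario("heterogeneous", seed=1)   # 2 populations (375/125),
g, pheno, truth = simulate_dataset(cfg)              # 10 LD blocks, r_lgc = +0.9/-0.9/0

grm = make_grm(center_genotypes(g), individual_ids=g.individual_ids)
vc = fit_reml(make_model_spec(grm, g, pheno, n_traits=2))
dp = derive_params(vc)
print(np.round(dp.h2, 2), np.round(dp.r_g, 2))

metrics = run_cv(g, pheno, {
    "STGBLUP[POP1]": STGBLUP(population="POP1"),
    "MTGBLUP": MTGBLUP(),
    "LGC-model-2": LGCModel2(threshold=0.5),
}, k=5, repeats=2, seed=1)
print(metrics.summary()[["model", "pop", "r_mean", "b_mean"]])
```

Output (seed 1):

```
[0.48 0.3 ] [0.39]
        model  pop   r_mean   b_mean
STGBLUP[POP1] POP1 0.399044 1.044195
      MTGBLUP POP1 0.402351 1.043808
      MTGBLUP POP2 0.181515 0.829773
  LGC-model-2 POP1 0.415301 1.017355
  LGC-model-2 POP2 0.209901 0.707814
```

The first line is the fitted heritabilities (truth 0.5 in both populations;
the small second population is estimated noisily in a single replicate) and
the global genetic correlation, which under this heterogeneous architecture
is a share-weighted average of the planted +0.9 / −0.9 / 0 block
correlations (truth ≈ 0.47). The table shows cross-validation accuracy `r`
(correlation of response and GEBV in the validation folds) and unbiasedness
`b` (regression slope of response on GEBV; 1 = dispersion-unbiased). In
this replicate the three-kernel model improves accuracy over MTGBLUP in
both populations because its POS and NEG kernels are fitted with
covariances of the correct opposite signs instead of one diluted global
covariance; averaged over replicates (see the reproduction script below)
the ordering LGC-model-2 > MTGBLUP > STGBLUP is systematic.

The same pipeline is scriptable from the shell:

```bash
lgcblup simulate --out runs/demo --scenario heterogeneous --seed 1
lgcblup qc        --genotypes runs/demo/genotypes --out runs/demo
lgcblup partition --genotypes runs/demo/genotypes.qc --out runs/demo
lgcblup lgc       --genotypes runs/demo/genotypes.qc --phenotypes runs/demo/phenotypes.tsv --out runs/demo
lgcblup cv        --genotypes runs/demo/genotypes.qc --phenotypes runs/demo/phenotypes.tsv --out runs/demo
```

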