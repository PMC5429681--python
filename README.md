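# pqifgene

Gene-based association analysis of **longitudinal binary disease traits**
with rare and common variants.  `pqifgene` collapses the variants of each
gene into a weighted-sum (WSS) burden score, models the repeated binary
outcome with a marginal logistic model estimated by **quadratic inference
functions (QIF)**, and selects associated genes with a **SCAD-penalized QIF
(pQIF)** tuned by a BIC-type criterion (BIQIF).  It is aimed at statistical
geneticists analyzing longitudinal sequencing cohorts where the number of
candidate genes is large relative to the sample.

## The model

For subject i at visit t,

    E(Y_it) = mu_it,    logit(mu_it) = alpha_0 + sum_k gamma_k E_ikt + sum_j beta_j C_ij,

where E_ikt are environmental covariates (age, smoking, ...) and C_ij is the
gene score C_ij = sum_v w_v G_ijv with WSS weights w_v = 1/sqrt(p_v(1-p_v)),
p_v the sample minor-allele frequency, so rare variants (MAF < 5%) dominate.
The QIF estimator expands the inverse working correlation on basis matrices
(independent / exchangeable / AR(1)) and minimizes

    Q_n(beta) = psibar_n' Cbar_n^{-1} psibar_n,

which avoids estimating the intra-class correlation and stays efficient
under a misspecified working structure.  The penalized estimator minimizes
n Q_n + n sum_j p_lam(|beta_j|) with the SCAD penalty (a = 3.7, intercept
unpenalized), giving exact zeros, and lambda is chosen on a grid by
BIQIF = n Q_n(beta_hat) + df log(n).  Unbalanced panels (missing visits) are
handled by per-subject selection matrices.  See `docs/methods.md` for the
full account.

## Worked example

Simulate one scenario-1 cohort (500 subjects, three visits, 20 predictors:
age, smoking and 18 gene scores of which three are causal), then fit the
unpenalized and penalized models:

```python
import numpy as np
from pqifgene import (scenario_one, build_dataset, basis_matrices,
                      fit_qif, lambda_grid, select_model)

sc = scenario_one(n=500, p=20, rho=0.4)        # truth: age +0.9, genes -0.7, -0.6, +0.5
ds = build_dataset(sc, np.random.default_rng(42))
basis = basis_matrices("ar1", T=3)

qif = fit_qif(ds.design, basis)
path = select_model(ds.design, basis, lambda_grid(0.2, 20, 0.01), qif_init=qif)
sel = path.selected
print("selected lambda:", sel.lam)
print(sel.coef[sel.active].round(3))
```

Output:

```
selected lambda: 0.11
intercept    0.217
age          0.959
gene01      -0.688
gene02      -0.572
gene03       0.494
```

The BIQIF-selected model keeps exactly the four true signals (plus the
unpenalized intercept) and zeroes the 16 noise predictors; the surviving
coefficients are close to the generating values because SCAD leaves large
coefficients unshrunk.  `fit_qif`/`qif_stderr` give the corresponding
unpenalized estimates and sandwich standard errors.

A command-line pipeline wraps the same functionality:

```bash
pqifgene collapse genotypes.vcf genemap.tsv -o scores.tsv
pqifgene fit phenotypes.csv scores.tsv -o results/ --structure ar1
pqifgene simulate scenario.yaml -o study/ --seed 7
```

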