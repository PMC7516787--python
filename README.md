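# mblasso — two-stage multi-locus GWAS with dual-measure screening

`mblasso` detects quantitative trait nucleotides (QTNs) in genome-wide
association studies where the SNP count `p` vastly exceeds the sample size
`n`. It is aimed at quantitative geneticists working with inbred panels
(e.g. *Arabidopsis*-style accession collections) who want a multi-locus
alternative to single-marker mixed-model scans: all candidate loci are
estimated jointly, so no Bonferroni-style multiple-test correction is
needed.

## The method

The trait model is the linear mixed genetic model

```
y = 1 mu + Q alpha + X beta + eps,      eps ~ MVN(0, sigma2_e I)
```

with `X` the n x p genotype matrix coded additively (homozygotes +1/-1,
heterozygote 0) and `Q` optional fixed effects such as population-structure
proportions. Fitting runs in two stages:

**Stage 1 — dual-measure screening.** After correcting the phenotype
(`y' = y - Q alpha_hat`, alpha by least squares), SNPs are ranked by two
marginal association measures:

* Pearson correlation `omega_i = rho(X_i, y')`,
* mutual information `psi_i = I(X_i; y')` (genotypes are discrete; the
  phenotype is discretized into ~sqrt(n) equal-width bins).

For each measure, the top `n - 1` SNPs are refined by SCAD-penalized
regression (folded-concave penalty, `gamma = 3.7`; selection keeps effects
that remain exactly nonzero), giving the Type-I set. One iterative-screening
step subtracts the fitted Type-I contribution from `y'` and re-screens the
remaining SNPs, reviving loci that are marginally silent but jointly
informative (Type II). The candidate set `C` is the de-duplicated union of
both measures' Type-I and Type-II sets.

**Stage 2 — shrinkage estimation and testing.** An empirical-Bayes
hierarchical Lasso (EM algorithm; each effect has its own prior variance
with a scaled inverse-chi-square hyperprior) is fitted on the *original*
phenotype over `C`. Effects with `|beta| < 1e-5` are dropped; each survivor
is then tested by a nested likelihood-ratio test reported as a LOD score,

```
LOD = -2 (L0 - L1) / 4.6052,      significant iff LOD >= 3
```

which corresponds to a per-marker p-value of about 2e-4 (chi-square, 1 df).

The package also ships a simulation engine for the standard benchmark
(six QTNs with heritabilities 0.10/0.05/0.05/0.15/0.05/0.05, optional
polygenic background `u ~ MVN(0, sigma2_pg K)` and Hadamard-product
epistasis) and an evaluation suite (per-QTN power with the 1 kb matching
rule, effect MSE, type-1 error ratio).

## Worked example

```python
from mblasso import MBLASSO
from mblasso import simulator as sim

G, y, truth = sim.simulate_scenario(scenario=1, n=199, p=2000, seed=1)
est = MBLASSO().fit(G, y)
print(est.stage_sizes_)
print(est.results_)
```

prints the per-stage bookkeeping and association table:

```
{'k2': 7, 'k3': 0, 'k': 7, 'tau2': 3, 'tau3': 2, 'tau': 5, 'nu': 7, 'o': 7}
    snp_id  chromosome  position    effect        lod       p_value  significant
0   snp286           1    117841  1.606989   6.980637  1.429204e-08         True
1   snp357           1    145011 -1.171084   4.141602  1.258187e-05         True
2   snp535           2     54465 -1.042987   2.639354  4.896289e-04        False
3   snp858           3     21468  1.334724   5.275577  8.264954e-07         True
4  snp1143           3    133641  2.065589  10.599730  2.814417e-12         True
5  snp1226           4      9718  0.844900   2.336768  1.036454e-03        False
6  snp1715           5     45013  1.548375   5.928433  1.740654e-07         True
```

The Pearson branch kept 7 SNPs (`k2`), the MI branch 5 (`tau2 + tau3`,
including 2 revived by the iterative step); their de-duplicated union held
`nu = 7` candidates, all of which survived shrinkage (`o = 7`). Five
markers clear LOD >= 3: four sit within 1 kb of true simulated QTNs
(`truth.qtn_indices` is 285, 571, 857, 1142, 1428, 1714, with generating
effects 1.47-2.55; SNP ids are 1-based), while `snp357` is a false
positive on this draw — across the 100-replicate benchmark such calls
amount to a type-1 ratio below 0.03% of null SNPs. The two sub-threshold
rows are correctly left non-significant. The same analysis is available
from the shell:

```bash
mblasso simulate --n 199 --p 2000 --seed 1 --out-prefix sim
mblasso run --genotype sim.geno.tsv --map sim.map.tsv --phenotype sim.pheno.tsv
mblasso evaluate --results mblasso.assoc.tsv --map sim.map.tsv --truth sim.truth.json
```

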