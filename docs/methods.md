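# Methods

## Model and procedure

The package fits the linear mixed genetic model
`y = 1 mu + Q alpha + X beta + eps`, `eps ~ MVN(0, sigma2_e I)`, where `X`
holds additively coded SNP genotypes (+1/-1 homozygotes, 0 heterozygote)
and `Q` optional fixed-effect covariates. Estimation is two-stage:

1. **Fixed-effect correction.** `alpha` is estimated by OLS of `y` on
   `[1, Q]` and only the `Q alpha_hat` part is subtracted, leaving the
   grand mean in `y'`; the stage-2 model fits `mu` itself. (Whether an
   intercept belongs in this regression is genuinely open; including it
   makes the correction invariant to covariate centering, which is why we
   chose it.)
2. **Screening.** Each branch (Pearson `omega`, mutual information `psi`)
   keeps the SNPs whose score reaches the `(n-1)`-th largest value — ties
   at the cutoff are all kept, so the screen can exceed `n-1`. SCAD
   regression on the screened design retains the exactly-nonzero effects
   (Type I); one iterative-screening pass subtracts the Type-I fit from
   `y'` (using the SCAD coefficients, not a refit) and repeats the
   screen-plus-SCAD step once on the complement (Type II). Candidates are
   the de-duplicated union across both branches, so `|C| <= k + tau`.
   The alternative screen size `n / log n` is available by configuration.
3. **Shrinkage and testing.** The EM Bayesian Lasso runs on the *original*
   `y` over `C`; effects below `1e-5` in magnitude are dropped once after
   convergence, then every survivor gets a nested likelihood-ratio test
   (all other retained effects, the mean and the residual variance
   re-maximized under the null) reported as `LOD = -2(L0 - L1)/4.6052`
   with significance at `LOD >= 3` (p ~ 2e-4 at 1 df). Re-maximizing the
   nuisance effects under the null — rather than freezing them at their
   alternative-model values — makes this a proper nested test; the choice
   is ours, the convention in the source material being unstated.

## SCAD solver

The SCAD objective is the penalized mean-squared loss
`(1/2n)||y - X beta||^2 + sum_j rho_{lambda,gamma}(|beta_j|)` with the
usual three-branch folded-concave penalty and `gamma = 3.7`. The `1/2n`
loss scaling matters: it puts `lambda` on the scale of the standardized
coefficients so that the penalty's nearly-unbiased outer branch
(`|beta| >= gamma lambda`) is actually reachable along the path. Without
it the useful part of the path never leaves the Lasso-like inner branch
and estimates are heavily biased.

Columns of `X` and `y` are standardized internally (intercept by
centering, unpenalized); coefficients are reported on the original scales.
Cyclic coordinate descent solves each path point exactly per coordinate
(the 1-D restriction is piecewise quadratic; we minimize it analytically),
warm-starting along a 100-point log-spaced path from `lambda_max` (the
smallest all-zero `lambda`, `max_j |x_j' y| / n`) down to
`0.001 lambda_max`.

Numerical choices:

* Convergence: `max |delta beta| < 1e-7` per sweep, or a per-sweep
  objective decrease below `1e-10`. The second rule exists because the
  nonconvex per-coordinate minimizer is discontinuous and two correlated
  columns can trade places forever at equal objective value.
* The path stops early once a fit exceeds 90% density of `min(n, m)`
  (only when `m` approaches `n`): near-saturated fits are orders of
  magnitude slower to converge and no selection rule below can pick them.
* Sweep cap 10,000 per `lambda`; non-convergence warns and keeps the best
  iterate.

**Penalty-level selection.** The default is deterministic: the extended
BIC (`gamma_EBIC = 0.5`), `n log(RSS/n) + df (log n + log m)`, evaluated
on the **OLS refit** of each path support, with ties resolved to the
smallest `lambda` and supports denser than `3n/4` excluded. Two failure
modes drove this choice, both specific to screened panels where every
column is marginally correlated with the trait and `m ~ n - 1`: plain BIC
on the penalized fits picks the near-saturated tail (RSS falls almost
linearly in df), while EBIC on the penalized fits picks the null model
(shrinkage bias makes sparse fits near `lambda_max` look poor). Scoring
the refitted supports removes the bias term from the comparison and is
standard practice in post-selection estimation. K-fold cross-validation
is available by configuration (`lambda_strategy="cv"`), seeded for
reproducibility, as is a fixed `lambda`.

## Mutual-information estimator

`I(X;Y) = H(X) + H(Y) - H(X,Y)` in nats over the 3 genotype states and an
equal-width binning of `y'` into `round(sqrt(n))` bins (configurable), with
`0 log 0 := 0` and no pseudo-counts by default (Laplace smoothing
available). Equal-width histogram binning is the single largest source of
divergence from any particular MI implementation a study might have used;
only the *ranking* of `psi_i` feeds the screen, which also makes the
natural-log base immaterial. The identity route and the direct double-sum
route are both implemented and cross-checked to `1e-10` in the tests.

## EM Bayesian Lasso

Hierarchical model `beta_j | sigma2_j ~ N(0, sigma2_j)` with a scaled
inverse-chi-square `(tau, omega)` hyperprior on each `sigma2_j`; default
`(tau, omega) = (-1, 0)`, giving the M-step
`sigma2_j <- (bhat_j^2 + V_jj) / 2`. The divide-by-two matters: it makes
the prior-variance recursion geometric, so weak effects genuinely collapse
below the `1e-5` retention rule within ~100 iterations. (The flat-prior
alternative `(tau, omega) = (-2, 0)`, i.e. dividing by one, decays only
like `1/t` and effectively never drops an effect; both variants are
available through the `tau`/`omega` parameters.)

The E-step uses the exact Gaussian posterior of `beta`, computed from a
`k x k` system over the currently active effects, or the dual `n x n`
(Woodbury) system when the active set exceeds `n` — so `nu > n` candidate
sets pose no problem. Exactness of the E-step makes the EM objective (the
marginal likelihood times the hyperprior) provably non-decreasing, which
the tests assert sweep-by-sweep; a coordinate-wise approximate E-step
would be cheaper per sweep but forfeits that guarantee. Once a prior
variance falls below `1e-12` the posterior is a point mass at zero and the
column leaves the computation (well below the `1e-5` reporting rule).
Initialization is deterministic: `mu = mean(y)`, `beta = 0`,
`sigma2_j = 1`, `sigma2_e = var(y)`. Convergence: largest parameter change
below `1e-8`, cap 1000 iterations.

## Simulation engine

The generator emulates the standard six-QTN benchmark: `n = 199`
individuals, SNPs spread over five chromosomes with strictly increasing
base-pair positions (~400 bp mean spacing), per-SNP allele frequencies
uniform on [0.05, 0.5] with QTN columns forced to 0.30, genotypes drawn
under Hardy-Weinberg equilibrium. Optional AR(1) Gaussian-copula
correlation within blocks emulates linkage disequilibrium (off by
default). Effects are back-calculated from heritabilities via
`V_P = (sigma2_e + sigma2_pg + sigma2_epi_total) / (1 - sum h_i)` and
`b_i = sqrt(h_i V_P / (2 f_i (1 - f_i)))`; with the benchmark's values
this gives `h2_pg = 2 / (12/0.55) = 0.092` for the polygenic scenario and
`1.25 / 25 = 0.05` per epistatic pair. Scenario 2 adds
`u ~ MVN(0, sigma2_pg K)` with `K = Z Z' / p` from column-standardized
genotypes (VanRaden-style; the construction is configurable since no
single convention is canonical). Scenario 3 adds three Hadamard-product
interaction terms at loci disjoint from the six QTNs, with `b_jj` sized so
each pair contributes `sigma2_epi = 1.25` under HWE independence.

What the synthetic panel does **not** emulate: real linkage
disequilibrium structure, allele-frequency spectra and population
stratification of an actual accession panel. Consequently the benchmark
reproduces operating *regimes* (type-1 error ratio well below 0.05%,
average power near 0.7, near-certain detection of the h2 = 0.15 QTN at
n = 199, p = 2000) rather than any exact published percentage, which
would additionally require the original genotype panel and 1000
replicates.

## Evaluation conventions

* A significant SNP within 1 kb (same chromosome) of a QTN counts as
  detecting it; each significant SNP is credited to at most its nearest
  QTN; all other significant SNPs are false positives.
* The type-1 denominator is (SNPs outside every 1 kb QTN window) x
  replicates, reported in percent. The published figures of this design
  never define their denominator; ours is stated so the number is
  reproducible.
* Per-QTN MSE averages over replicates where the QTN was detected
  (conditional MSE, the common convention); an `undetected => beta = 0`
  mode is available. Robustness is the SD of power across the four
  equal-heritability (5%) QTNs.

## Problem sizes

The shipped benchmark (tests and `scripts/acceptance.py`) uses 100
replicates at n = 199, p = 2000 — a deliberate desk-scale choice that
keeps a full study in minutes on one core while preserving the p >> n
character of the problem; null-distribution calibration uses 2000
single-marker replicates. The `simulate` command defaults to p = 10,000
(2000 per chromosome) for data generation.

## Known limitations

* Screening set sizes depend on the penalty-selection rule; with the
  refitted-EBIC default they are smaller (~5-15 per branch) than what a
  cross-validated rule produces. Power and error rates, not set sizes,
  are the calibrated quantities.
* The MI screen's equal-width binning is a choice among several defensible
  estimators; rankings can differ slightly between estimators.
* The likelihood-ratio test is applied to markers chosen by the same data
  (post-selection inference); the LOD >= 3 rule is deliberately stringent
  partly for this reason, and the null-calibration test covers the
  append-a-null-marker setting, not selection-adjusted inference.
* No support for binary traits, dominance coding, or genotype missingness
  beyond column-mode imputation.
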