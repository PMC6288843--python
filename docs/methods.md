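# Methods

## The problem

In QTL mapping of experimental crosses (F2 intercross, backcross), the
standard single-locus analysis assumes every individual has the same
residual variance. When the residual variance in fact differs
systematically between groups — driven by sex, batch, sire, or another
locus — that *background variance heterogeneity* (BVH) misweights the
observations: noisy individuals get too much influence, precise ones too
little. This costs power for detecting mean-effect loci (mQTL) and, for
variance-effect loci (vQTL), can silently inflate the false positive rate
of tests that compare a heteroskedastic alternative against a
homoskedastic null.

`mvqtl` implements *mean-variance QTL mapping*: single-locus tests that
model the mean and the log residual variance jointly, permutation
procedures that keep those tests calibrated when assumptions fail, and a
genome-wide error-rate procedure built on permutation maxima.

## Models and tests

All models assume `y_i ~ N(m_i, sigma_i^2)` with `m_i = mu + x_i'beta +
q_i'alpha`, where `q_i` is the locus encoding and `x_i` the mean
covariates. The families differ in the variance structure:

* **SLM** — `sigma_i^2 = sigma^2` (homoskedastic). Fitted by OLS with the
  maximum-likelihood variance `RSS/n`.
* **Grouped-variance model (Cao)** — `sigma_i^2 = phi_g[i]`, one free
  variance per hard genotype group. Fitted to the joint ML solution by
  alternating generalized least squares for the mean with the within-group
  moment update for `phi`; the classical two-step profile fit is the first
  iteration and is numerically indistinguishable in practice.
* **DGLM** — `sigma_i^2 = exp(z_i'gamma + q_i'theta)`, a log-linear model
  that can carry both locus (foreground) and covariate (background)
  variance effects. Fitted by alternating (a) weighted least squares for
  the mean with weights `1/sigma_i^2` and (b) a gamma-family log-link
  Fisher-scoring step on the squared residuals with dispersion fixed at 2,
  which solves the exact ML score equations for `gamma`.
* **Levene's W** — the one-way ANOVA F statistic applied to absolute
  deviations from genotype-group means, referred to `F(G-1, n-G)`.
  Mean-based deviations are used, not the median-based Brown-Forsythe
  variant. (Some write-ups print the degree-of-freedom pair in the
  opposite order; the numerator of the statistic has `G-1` df, which is
  what this package uses.)

Eight tests arise as likelihood-ratio comparisons `T = 2(l1 - l0)`:
`slm` (mQTL), `cao_m`/`cao_v`/`cao_mv`, `dglm_m`/`dglm_v`/`dglm_mv`, and
`levene`. The nulls are chosen so each test isolates one aspect: the DGLM
mQTL null *retains* the locus variance term and the vQTL null retains the
locus mean term. Asymptotic references are chi-square with 2 df (mean or
variance alone, F2) and 4 df (joint); 1 and 2 df for a backcross.

A single likelihood definition is used throughout — full ML, squared
residuals used raw with no leverage/REML-style correction — so LR
statistics between any nested pair of these models are coherent.

### Locus encoding

With known F2 genotypes the locus contributes an additive and a dominance
column. With genotype probabilities, the Haley-Knott expectations are used:
`a = 2 p(AA) + p(AB)`, `d = p(AB)`. Group-based tests (Levene, Cao) need
categorical genotypes and use the maximum-probability call, ties broken
toward the heterozygote. In the simulation study the scalar genotype
`q in {-1,0,1}` enters as the pair `(q, 1{q=0})` — affinely equivalent to
the Haley-Knott pair — so every mean/variance contrast carries 2 df and
the joint contrast 4 df, matching the chi-square references above. This is
the single most consequential reproduction choice: the study's power
values are only consistent with 2-df (not 1-df) locus contrasts.

## Significance procedures

* **standard** — asymptotic chi-square (F for Levene).
* **rint** — rank-based inverse normal transform
  `PhiInv[(rank - 3/8)/(n + 1/4)]` applied to the phenotype first; ties
  get average ranks (deterministic and seed-free).
* **residperm** — the test's own null model is fitted once; pseudo-null
  responses `m_hat + eps_hat[perm]` are built by permuting its residuals
  and the full test (both fits) is recomputed on each. Levene, having no
  likelihood null of its own, borrows the covariates-only linear model.
* **locusperm** — only the locus design columns that distinguish the
  alternative from the null are permuted (both blocks under one
  permutation for joint tests; group labels for Levene). The null model's
  log-likelihood is unchanged by construction and is computed exactly
  once.

Empirical p-values are `(1 + #{T_r >= T_obs})/(R + 1)` — never zero, and
exchangeability-valid. The default `R = 1000` matches the permutation
count used for the study's empirical nulls; desk-scale replications use
less. One root seed spawns an independent child stream per replicate, so
a run is reproducible regardless of execution order, and the permutations
actually used are returned in the `EmpiricalNull` record. Replicates whose
iterative fits fail to converge are excluded and counted, with the
effective `R` reduced accordingly.

## Genome-wide significance

The genome-permutation procedure extends locusperm to a scan: for each
replicate one permutation is applied to the locus blocks of *all* loci,
the scan-wide maximum statistic is recorded, and a generalized extreme
value (GEV) distribution is fitted to the `R` maxima by maximum
likelihood (`scipy.stats.genextreme`, shape unconstrained). FWER-adjusted
p-values are the GEV upper tail at each observed statistic — a smooth,
monotone-in-T adjustment. If the optimizer fails or returns an extreme
shape (|shape| > 1), the empirical permutation tail is used instead and
the fallback is logged. Below 100 permutations a warning is emitted
because the tail fit is unstable.

Positional uncertainty for a detected QTL is quantified by a
nonparametric bootstrap: individuals are resampled with replacement, the
chromosome rescanned, and the peak position recorded; the equal-tailed
interval of the peak positions (default level 90%) is reported.

Percent variance explained (PVE) is the ratio of the QTL
mean-contribution variance to QTL + covariate + residual variance. Under
variance heterogeneity the residual variance differs per individual, so
PVE is reported both as an average (using the mean fitted residual
variance) and per individual.

## The simulation engine

The generator reproduces the study conditions exactly: `n = 300`
individuals; genotype `q in {-1, 0, 1}` with probabilities
`{0.25, 0.5, 0.25}`; a fixed five-level covariate in contiguous blocks of
60; phenotype `y_i ~ N(q_i alpha, exp(2(z_i'gamma + q_i theta)))`. The
eight canonical scenarios cross locus type (null / mQTL / vQTL / mvQTL)
with BVH absent/present, with effect sizes `alpha` in {0, 0.22, 0.25,
0.18, 0.20}, `theta` in {0, 0.17, 0.14, 0.136} and `gamma` either zero or
`[-0.4, -0.2, 0, 0.2, 0.4]` (implying group SDs `[0.67, 0.82, 1.00, 1.22,
1.49]`). Every simulation draws from a stream keyed by
`(root seed, scenario index, simulation index)`, so any cell — or any
single simulated experiment — can be reproduced in isolation and results
are bit-identical across runs.

What the generator does *not* emulate: linkage (the study's locus is a
single marker; the fixture generator adds a simple exchangeable-
correlation chain for scan-level tests, not a genetic map model),
genotyping error, missing data, non-normal phenotypes, and polygenic
relatedness. Passing the calibration and power checks therefore
demonstrates correctness of the tests and procedures under the stated
model, not robustness to those real-data complications (the permutation
procedures are the intended protection for several of them).

Empirical rates are binomial proportions; the harness reports the simple
binomial standard error `sqrt(p(1-p)/n)` together with a 95%
Clopper-Pearson interval. (The study's source for its standard errors is
not recoverable; its printed magnitudes are of the same order.)

## Numerical choices

* Convergence: absolute change in log-likelihood `< 1e-8`, at most 50
  iterations (DGLM; 100 for the grouped-variance fit). Variance sub-model
  initialized at the homoskedastic fit. A step that would decrease the
  likelihood is halved (up to 10 times).
* Squared residuals are floored at `1e-12 * Var(y)` so the gamma-step
  working values stay finite when a point is fitted exactly.
* Non-convergence is flagged on the returned fit and, on request, raised
  as a structured error; the scan and study layers count and log it
  rather than silently accepting or discarding results.
* LR statistics in `[-1e-3, 0)` (convergence slack) are clamped to zero;
  anything more negative raises an internal-consistency error.
* Rank-deficient covariate designs are rejected, but a degenerate *locus*
  block (e.g., a monomorphic marker) falls back to a minimum-norm solve so
  the statistic degrades to ~0 instead of erroring mid-scan.
* Positions are centimorgans as given in the input; no re-mapping.

## Known discrepancy in the reproduced design

The study's stated mQTL effect size for the BVH-absent scenario
(`alpha = 0.22`) is internally inconsistent with its reported SLM power
(0.717): the noncentral chi-square power at that effect size is 0.672,
which this package reproduces. The reported power corresponds to
`alpha ~= 0.229` (the value implied by the "5% of phenotype variance"
rule applied with unit genotype variance). The published parameter table
is treated as authoritative, so the reproduction of that one power cell
sits ~0.045 below the published value; every other published cell is
consistent with its stated parameters and reproduces within Monte-Carlo
error.

## Problem sizes used in the shipped checks

The test suite reproduces asymptotic/RINT cells at 5,000 simulations and
permutation cells at 200 simulations x 150 permutations; the acceptance
script (`scripts/acceptance.py`) uses full replication (10,000) for
asymptotic/RINT cells and 1,000 simulations x 200 permutations for
permutation cells. These sizes put the Monte-Carlo standard error near
0.003-0.02 depending on the cell, which is the package's chosen
precision/runtime trade-off for routine verification.
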