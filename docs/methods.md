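# Methods

## The model

`triopoo` analyses case-parent trios: an affected child (the proband) and
its genotyped parents, at one biallelic SNP at a time.  Association is
inferred from asymmetries in allele transmission rather than from
population allele-frequency differences, which protects against
confounding by population substructure.

Founders (the parents) are assumed to be in Hardy–Weinberg equilibrium
with variant-allele frequency *q* and to mate at random within each
analysis stratum.  The child's disease risk is multiplicative in allele
dose with parent-of-origin-specific per-allele relative risks:

- `RR_mat` — relative risk per maternally inherited variant allele,
- `RR_pat` — relative risk per paternally inherited variant allele,

so a child who inherited the variant from both parents has relative risk
`RR_mat · RR_pat`; there is no separate double-dose parameter.  The
variant allele is always the *minor* allele among founders (the major
allele is the reference), so estimated ratios may naturally fall below 1.

Conditioning on the child being a case, the probability of a latent trio
configuration — parental genotypes `(g_m, g_f)` plus the origin-resolved
transmission indicators `(x_m, x_p)` — is proportional to

```
HWE(g_m; q) · HWE(g_f; q) · T(x_m | g_m) · T(x_p | g_f) · RR_mat^x_m · RR_pat^x_p
```

with `T` the Mendelian transmission probability (1/2 per heterozygous
parent).  There are 16 latent configurations; collapsing them by the
observable (mother, father, child) genotypes yields a multinomial over 15
observable trio categories.  The only observable category with two latent
refinements is (het, het, het), where the parental origin of the child's
variant allele is unresolved.

### Effect measures and tests

Within exposure stratum *S* (0 = unexposed, 1 = exposed) the
parent-of-origin relative-risk ratio is

```
RRR_PoO(S) = RR_mat(S) / RR_pat(S)
```

and the headline interaction measure is the ratio of these ratios,

```
RRR = RRR_PoO(1) / RRR_PoO(0)
```

(exposed over unexposed).  Four Wald tests are provided, all on the log
scale with two-sided normal p-values and 1.96-multiplier 95% CIs:

- **child**: log RR = 0 in a reduced model with a single per-allele RR
  (no origin distinction), both strata pooled;
- **PoO**: log RRR_PoO = 0, both strata pooled;
- **GxE**: equality of the reduced-model RRs across strata;
- **PoOxE**: equality of RRR_PoO across strata, i.e. log RRR = 0.

The stratum fits use disjoint families and are therefore independent, so
the SE of a between-stratum log contrast is `sqrt(SE_0² + SE_1²)`.
Within a stratum, `SE(log RRR_PoO)` comes from the delta method on the
correlated pair (log RR_mat, log RR_pat):
`sqrt(var_mat + var_pat − 2·cov)` — the covariance term is required for a
correct SE of the difference of correlated estimates and is always
included.

### Missing parents

Families with one or both parents ungenotyped (duos, proband-only
singletons) are retained.  The fit maximizes the *observed-data*
likelihood, summing the latent-configuration weights over all complete
configurations compatible with the observed pattern.  This gives the
same MLE as an EM algorithm over missing parental genotypes, and taking
standard errors from the observed-data information matrix (inverse
negative Hessian of the marginal log-likelihood) automatically corrects
them for the missingness — SEs from a duos-heavy fit are strictly larger
than from complete trios, which the test suite checks.  Records with a
missing *child* genotype carry no case information at that SNP and are
excluded there; trios with missing exposure are excluded from stratified
fits but contribute to pooled (child / PoO) fits.

### Numerical choices

- Optimization on the unconstrained scale `(logit q, log RR_mat,
  log RR_pat)` by BFGS with the analytic gradient; initialization at the
  logit of the crude observed allele frequency and zero log-RRs.
- Convergence when the gradient inf-norm falls below
  `1e-6 · max(1, n_trios)` (the log-likelihood scales linearly with the
  trio count).  Non-converged fits are flagged; scans report such SNPs
  with NA statistics and a reason code rather than failing.
- The Hessian is obtained by central finite differences of the analytic
  gradient (step `1e-5 · max(1, |θ_i|)`); its inverse is the reported
  covariance.  A singular or non-PSD Hessian marks the fit as
  non-converged.
- Monomorphic data (a single observed allele) is detected before
  optimization; the parameters are not identifiable and the SNP is
  skipped with reason `monomorphic`.
- Mendelian-inconsistent complete patterns have probability zero under
  every parameter value; they abort the fit with the offending family
  named.  QC is expected to remove them first.
- Allele frequency is a free nuisance parameter *per stratum* — the more
  robust choice when exposure correlates with ancestry — rather than
  being constrained equal across strata.

## Quality control

Filters and defaults (all configurable):

| filter | statistic | default threshold |
|---|---|---|
| individual call rate | missing fraction per individual | > 0.10 removed |
| SNP call rate | missing fraction per SNP | > 0.05 removed |
| founder MAF | alt-allele frequency among parents | < 0.05 removed |
| HWE | exact test on founder genotypes | p < 0.001 removed |
| SNP Mendel rate | inconsistent complete trios per SNP | > 0.10 removed |
| complete LD | adjacent-pair founder-dosage r² | = 1 (later SNP removed) |
| family Mendel rate | inconsistent SNPs per family | > 0.05 removed |

Order: individuals first (a removed parent leaves a duo; a removed
proband removes the family), then the five SNP criteria evaluated
jointly on the survivors and combined as a union, then families.  The
per-SNP Mendel default is 0.10; a 0.01 threshold is also defensible (the
two figures circulate in trio-GWAS practice) and is available via
configuration.  The exact HWE test enumerates the conditional
distribution of the heterozygote count given the allele counts and sums
the probabilities of outcomes no more probable than the observed one.

Re-applying `apply_qc` to its own output is a no-op on the fixtures used
here; in pathological cases idempotence can fail because individual call
rates are recomputed on the already-filtered SNP panel.

## q-values and QQ tables

q-values use the step-up rule `q(i) = min_{j≥i} π₀·m·p(j)/j` capped at
1, with `π₀ = 1` by default — selection at `q ≤ α` is then exactly the
Benjamini–Hochberg rejection set at level α, and the expected proportion
of true positives among SNPs selected at `q ≤ 0.1` is at least 90%.  A
Storey-type smoother estimate of π₀ (cubic fit to `π₀(λ)` over
λ = 0.05…0.95, evaluated at the largest λ) is available but the
conservative default is recommended for genome scans.  QQ tables use
plotting positions `i/(m+1)` and 95% pointwise bands from the
Beta(i, m−i+1) distribution of uniform order statistics.

## Simulator

Trios are sampled *directly* from the ascertained 15-category
multinomial implied by the stratum's parameters — mathematically
identical to prospective simulation with case ascertainment for a pure
case-trio design, and orders of magnitude faster.  Each family draws its
exposure stratum Bernoulli(exposed fraction); parents can be masked to
MISSING at configurable rates afterwards.  Defaults mirror the reference
power-study conditions: 500 trios, MAF 0.20, equally-sized strata,
complete genotyping, all relative risks 1.  The standard power-curve
scenario varies only the maternal relative risk in the exposed stratum
(`rr_mat_1 = RRR`), so the implied interaction ratio equals `RRR`.
Power estimates use 1000 replicates at significance level 0.05 by
default; each replicate has its own child seed of the master seed.

What the simulator does *not* emulate: linkage disequilibrium between
SNPs (null SNPs are independent), population stratification, maternal
genomic effects, genotyping error, and informative missingness (parents
are masked completely at random).  Passing tests therefore demonstrate
the statistical correctness of the estimator and its calibration under
the model's own assumptions, not robustness to those violations.

## Problem sizes in the test and acceptance runs

Calibration and power checks use 1000 Monte-Carlo replicates of 500
trios (the reference study size); the FDR check uses 50 replicates of
2000 SNPs, with analytic (uniform) p-values for null SNPs — justified by
the verified uniformity of null PoOxE p-values — and fitted p-values for
the 200 planted alternatives; parameter-recovery checks use 200
replicates of 5000 trios.  Exactness checks against the brute-force
enumerator are deterministic and run at tolerance 1e-10.

## Known limitations

- Autosomal biallelic SNPs only; no X-chromosome model, no haplotype or
  multi-allelic analysis.
- A single dichotomous exposure; no covariate adjustment and no trend
  tests over more than two exposure levels.
- No maternal-genomic-effect adjustment; PoO and maternal effects can be
  mutually confounded, and this package does not attempt to separate
  them.
- The Wald tests rely on asymptotic normality of the log estimates;
  with very sparse strata (few informative transmissions) the
  normal approximation and the reported CIs degrade before the fit
  formally fails.
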