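# Methods

## Models and tests

Per sex `s ∈ {F, M}`, the input is an additive per-allele effect estimate
`β̂_s` with standard error `v̂_s` (phenotype units per copy of the minor
allele), from an ordinary least-squares GWAS within that sex.  Under the
null of no association each Wald statistic `T_s = β̂_s/v̂_s` is
asymptotically standard normal, and the two strata are independent (no
shared samples).  Three sex-combined statistics are formed:

* **Effect difference** `T_Diff = (β̂_F − β̂_M)/√(v̂_F² + v̂_M²)` — tests the
  SNP×sex interaction alone; `N(0,1)` under equal effects.
* **Linear (IVW) meta** `T_1,metaL = (T_F/v̂_F + T_M/v̂_M)/√(1/v̂_F² +
  1/v̂_M²)` — the fixed-effect inverse-variance weighted combination;
  `N(0,1)` under no association.  Powerful when effects are homogeneous,
  powerless when they cancel.
* **Omnibus quadratic meta** `T_2,metaQ = T_F² + T_M²` — `χ²₂` under no
  association; direction-agnostic, so it tests the main effect and the
  interaction jointly.

The individual-level ("mega") counterparts regress the pooled phenotype on
genotype, sex, genotype×sex and covariates with *sex-specific residual
variances* `σ_F², σ_M²`.  The 2-df Wald test of `b_g = b_gs = 0` on the
joint model corresponds to `T_2,metaQ`; the 1-df Wald test of `b_g = 0` on
the main-only model corresponds to `T_1,metaL`.

## Numerical tail handling

GWAS evidence routinely exceeds the range of double-precision p-values
(−log10 p > 308).  All tail probabilities are therefore computed in log
space: two-sided normal p as `log 2 + log Φ(−|z|)` via
`scipy.special.log_ndtr`, its inverse via `ndtri_exp`, and the `χ²₂` upper
tail by its closed form `exp(−χ²/2)` (so `−log10 p = χ²/(2 ln 10)`
exactly).  Every p-value is accompanied by a `neglog10` field which stays
finite and accurate for |z| well beyond 40; the `p` field may underflow to
0.0 in that regime, which downstream comparisons avoid by operating on the
−log10 scale (genome-wide filtering included).  Signed z-inversion of a
printed p-value is exact to 1e−6 relative down to p ≈ 1e−300.

## Heteroskedastic estimation (FGLS)

The sex-specific error model fixes the estimator as iterative feasible
generalized least squares: (i) unweighted least-squares fit, (ii) per-sex
residual variance estimates, (iii) weighted refit with weights `1/σ̂_s²`,
iterated until the largest relative coefficient change falls below 1e−8
(cap 100 iterations; non-convergence returns the last iterate flagged).
The coefficient covariance is `(XᵀWX)⁻¹` at the converged weights.

Residual degrees of freedom: in **fully-stratified** covariate mode (every
covariate interacted with sex) the fit decouples into the two per-stratum
OLS problems, and each group's variance uses `n_s − k_s` with `k_s` the
parameters attributable to that stratum — this makes coefficients, SEs and
the 2-df Wald statistic *algebraically identical* to the stratified GWAS,
hence `T_2,mega ≡ T_2,metaQ` exactly (the test suite asserts agreement to
1e−6 on simulated cohorts).  In **shared** covariate mode a single
coefficient vector serves both sexes; group variances then use
proportionally allocated df `n_s − p·n_s/n`, and the meta/mega agreement is
empirical (correlation > 0.999 across simulated cohorts of n = 4,000).
Whether shared or sex-interacted covariates better mirror a given published
stratified analysis depends on that analysis; both modes are provided and
the fully-stratified mode is the exact-equivalence path.

## Synthetic data

`simulate_cohort` draws genotypes i.i.d. Binomial(2, MAF) (Hardy–Weinberg)
and phenotypes `y = μ_s + β_s·g + Xb_X + N(0, σ_s²)`; `simulate_sumstats`
shortcuts to the asymptotic sampling distribution `β̂_s ~ N(β_s, σ_s²/(2·
MAF·(1−MAF)·n_s))` with the standard error treated as known.  The two
engines agree in distribution (KS-checked) for n ≳ a few hundred per sex;
the summary engine is the default for the power study because it is
vectorized over replicates.

What the generator does *not* emulate: linkage disequilibrium between
simulated variants (single-variant tests do not need it; LD enters only
through the post-GWAS provider), genotype imputation uncertainty,
relatedness, ascertainment/participation bias, detection-limit truncation,
and non-normal residuals.  Passing tests therefore demonstrate correctness
of the statistics under the stated sampling model, not robustness to those
real-data complications (the IRNT utility exists precisely because raw
phenotypes can violate residual normality; per-group IRNT is provided but
places the groups on incompatible quantile scales, breaking the meta/mega
equivalence, which is why pooled mode is the default).

All randomness flows from explicit seeds; scenario grids spawn one
`numpy.random.SeedSequence` substream per scenario (and per replicate in
the cohort engine), so every (scenario, replicate) pair is independent and
reproducible.

## Scenario grid and power study

The preset grid covers the canonical heterogeneity configurations — null,
homogeneous, one-sex-only (both ways), opposite-equal, and
magnitude-difference — at n = 2,000 per sex, MAF 0.3, equal residual SD 1
and a sex difference in phenotype mean (0 vs 0.5).  The per-allele effect
0.1 was chosen from the closed-form power oracle so that per-sex power at
α = 0.05 is ≈ 0.83 (mid-range): large enough that method differences are
visible, small enough that nothing saturates.  The magnitude-difference
preset uses (0.05, 0.12).  With these settings the omnibus test's
worst-case power deficit from the scenario-best method is 0.086 analytic
(one-sex-only scenarios, the known cost of the second df), and its gain
over the linear meta under opposite-equal effects is ≈ 0.91.

The analytic oracle uses per-sex noncentralities `λ_s = β_s²·2·MAF·(1−MAF)·
n_s/σ_s²`: the four 1-df tests are shifted normals, and `T_2,metaQ` is
noncentral `χ²₂` with noncentrality `λ_F + λ_M`.  Monte-Carlo defaults are
20,000 summary-level replicates per scenario at α = 0.05; the genome-wide
5×10⁻⁸ level is served by the analytic path (Monte-Carlo at that level
would need ≳10⁹ replicates).

## Post-GWAS stage

Genome-wide filtering is strict `p < 5×10⁻⁸` on the −log10 scale.
Clumping is greedy by ascending p (ties broken by chromosome, position,
id, making output order-invariant to input shuffling): each index SNP
absorbs remaining same-chromosome variants within 10 Mb with `r² > 0.01`
(strict inequality).  Independent SNPs within 250 kb are then merged into
risk loci by single linkage — a chain of 200 kb gaps merges even when the
locus ends are 400 kb apart — with the gap threshold inclusive (a gap of
exactly 250 kb merges); each locus is led by its minimum-p member.
Opposite-direction flagging requires genome-wide significance in *both*
sexes plus opposite nonzero beta signs; it is deliberately independent of
the combined tests.

## Harmonization conventions

Variants are matched across the two per-sex files on (id, position); a
swapped major/minor coding in the male file flips the male beta and z signs
onto the female file's minor allele.  MAF is always stored folded to
(0, 0.5], so QC (per-sex MAF > 0.01 in both sexes, INFO > 0.8) is
orientation-free.  Strand-ambiguous (A/T, C/G) variants are kept — both
files in the intended use come from one imputation panel.  When a file
carries both SE and p and they disagree by more than 1% on the z scale, the
SE wins and a warning is logged (printed p columns are usually rounded).
A p-value printed as 0 is unparseable, by design.

## Worked-example tolerances

The packaged testosterone/urate tables print p-values to 3 significant
figures and betas to 1–4.  Recomputing the omnibus p from the two printed
per-sex p-values is exact inversion, so agreement is asserted to ±0.05 on
−log10 p; the difference and linear-meta tests additionally need standard
errors back-derived from printed betas, so their band is ±0.2.

## Known limitations

Quantitative traits and unrelated samples only; related samples would
correlate `T_F` and `T_M` and break the `χ²₂` null.  X-chromosome variants
flow through the autosomal code path (no dosage-compensation model).  The
random-effects meta-analysis (τ² estimation) is deliberately absent: with
two groups the heterogeneity variance is not reliably estimable.  Problem
sizes in the test suite (replicate counts, cohort sizes) are chosen so the
whole suite runs in a few minutes on one core while keeping binomial
Monte-Carlo error well inside the asserted bands.
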