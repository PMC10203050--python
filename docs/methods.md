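# Methods

This note documents the models implemented in `gxsex`, the choices made
where the design was genuinely open, and what the simulation-based tests
do and do not establish.

## 1. Covariance-mixture model of sex-specific effects

**Model.**  For SNP *j*, the true per-allele effects on a trait in males
and females form a pair b_j = (β_m, β_f).  We model b_j as drawn from a
finite mixture of zero-centered bivariate normals whose covariance
matrices encode hypotheses about the male/female relationship, and the
observed sex-stratified GWAS estimates as b̂_j = b_j + e_j with
e_j ~ N₂(0, S_j), S_j = diag(σ̂²_m,j, σ̂²_f,j) taken as known.  Because the
male and female GWAS samples do not overlap, the error correlation between
conditions is fixed at zero.  Marginally,

    b̂_j ~ Σ_k π_k N₂(0, ω_k U_k + S_j).

**Hypothesis grid.**  The default grid has 66 components: one null (no
effect in either sex), male-only and female-only matrices, and the outer
product of 9 between-sex correlations r ∈ {−1, −0.75, …, 0.75, 1} with 7
female:male magnitude ratios q ∈ {1/4, 1/2, 2/3, 1, 3/2, 2, 4}, each with
pattern U(r, q) = [[1, rq], [rq, q²]].  Components are labeled by
magnitude class (M>F for q<1, equal, M<F for q>1, M-only, F-only, null);
all reported summaries are driven by these category labels, not by the
identity of individual matrices, which makes them robust to the precise
grid composition.  The grid is fully configurable.

**Scale grid.**  The patterns fix only relative (co)variances, so each
non-null component is expanded over a geometric grid of overall scales ω
(ratio 2) spanning [0.25·min σ̂², 4·max(β̂²_m + β̂²_f)] for the data at
hand — the usual adaptive-shrinkage resolution of the unknown absolute
scale.  Reported weights collapse over ω.  A √2-ratio grid was checked and
changes weight summaries by <0.2 percentage points; the coarser grid is
kept for speed.

**Fitting.**  π is estimated by maximum likelihood.  The log-likelihood is
concave in π, and the EM update is the standard responsibility average.
Plain EM is slow near the optimum, so the implementation uses SQUAREM-style
extrapolation with a monotonicity safeguard: whenever the extrapolated
step would not improve the log-likelihood, the plain double-EM step is
taken instead, so the recorded trace never decreases (this is asserted in
the test suite).  Mixture entries whose proportion decays below 1e-12 are
pruned from the working set, guarded so pruning never lowers the
log-likelihood; by concavity, decayed components do not return.
Convergence is declared when the relative log-likelihood change drops
below 1e-8 (cap 5,000 iterations).  No prior penalty favoring the null
component is applied by default: the estimator is pure maximum likelihood.

**Block subsampling.**  SNP panels are correlated in real data, so weights
are learned on subsamples containing one SNP per approximately independent
LD block, the fit repeated (default 100 times) and the proportions
averaged, treating repeats as i.i.d. draws.  Within a block, SNPs are
consumed without replacement across repeats until the pool is exhausted,
then the pool resets with a fresh permutation (the natural reading of
"sampling without replacement" across repeated draws).  Synthetic cohorts
carry contiguous equal-size pseudo-blocks (default 100) purely so the
resampling code path is exercised; the simulated SNPs are actually in
linkage equilibrium.

**Posterior effects.**  Given fitted π, each SNP's posterior over b_j is a
mixture of normal-normal conjugate updates,
μ_k = Σ_k(Σ_k + S_j)⁻¹ b̂_j with covariance Σ_k(Σ_k + S_j)⁻¹ S_j
(Σ_k = ω_k U_k), combined with responsibilities ∝ π_k N₂(b̂_j; 0, Σ_k+S_j).

**Weight summaries.**  Non-null normalization divides each weight by the
total weight off the null component.  The *sex-biased amplification*
statistic is (M>F + M-only) − (M<F + F-only) on the non-null scale: the
single-sex matrices are extreme amplification and are counted with their
respective direction.

## 2. Synthetic cohorts

`simulate_cohort` draws zygote allele frequencies from a pluggable law
(default Uniform(0.01, 0.5); real imputed-panel frequency distributions
can be supplied as a callable), genotypes in Hardy-Weinberg proportions at
linkage equilibrium, and effect pairs for the causal subset from a
user-specified mixture of 2×2 covariance components.  Effects stay on
their drawn scale; the male environmental variance absorbs overall scale
by targeting the male heritability h²_m:

    Var[E|m] = Var[G|m]·(1 − h²_m)/h²_m,   Var[G|m] = Σ_i β²_m,i·2p̂_i(1−p̂_i),

evaluated at realized sample frequencies; the female environmental
variance is a fixed multiple of the male one (assigned, not sampled).
Phenotypes are y = c + Σ_i β_z,i x_ij + E_j with E_j normal given sex.
Sexes are assigned by an exact split at the configured ratio.
Degenerate configurations (h²_m = 0 with causal SNPs and no directly
assigned environmental variance, non-PSD components, weights off the
simplex) raise configuration errors.

What these cohorts deliberately lack: linkage disequilibrium, dominance,
minor-allele-frequency/effect-size coupling, covariates, participation
bias, and X-chromosome effects.  Tests passing on them establish the
estimators' statistical behaviour under the stated model, not robustness
to those real-data features.

## 3. Variance-based tests

Under the additive within-sex model Var[Y|z] = Var[G|z] + Var[E|z]:

* **Heritability bound.**  If genetic effects are equal in the sexes (so
  Var[G|m] ≈ Var[G|f]) and mean sex differences are removed, the combined
  environmental variance is a mixture of the sex-specific ones and cannot
  exceed their maximum; hence h² ≥ min(h²_m, h²_f).  An observed
  combined-sample heritability below both sex-specific values therefore
  implies sex differences in genetic variance, i.e. GxSex.
  `heritability_bound_check` reports the violation flag and a z statistic
  using independent-estimate SEs.
* **Joint amplification.**  If a shared modulator scales genetic and
  environmental effects alike (β_m = αβ_f, E_m = αE_f), then
  Var[G_m]/Var[G_f] = Var[E_m]/Var[E_f].  With Var[G_z] = h²_z Var[Y_z]
  and Var[E_z] = (1−h²_z)Var[Y_z], SEs propagate via the exact
  independent-product formula √(s²_a s²_b + a²s²_b + b²s²_a) and the
  second-order Taylor ratio formula (x/y)√(s²_x/x² + s²_y/y²); the SE of
  1−h² is taken equal to the SE of h² (exact under linearity).  The test
  statistic is Z = (Z̃−1)/SE[Z̃] for Z̃ the environmental-over-genetic
  ratio of ratios, referred to a standard normal.  The ratio-scale normal
  approximation is asymmetric under sex swap; a log-scale variant
  (`log_scale=True`) makes the antisymmetry exact and is recommended when
  the ratios are far from 1.  Phenotypic-variance SEs come from a
  bootstrap over individuals (default 100 resamples, SD with n−1
  denominator).

## 4. Polygenic-score analyses

Scores are Σ_i w_i x_i standardized to unit SD over the scored
individuals (slopes are "per PGS SD"), with no centering so the raw zero
point is preserved.  On linkage-equilibrium synthetic panels no
clumping/thresholding is applied.  Three analyses:

* **Slope ratio** — per-sex OLS slope of trait on score; male:female
  ratio with Taylor SE and a normal test of the slope difference.
* **Modulator bins** — within-sex quantile bins of a modulator (e.g.
  measured testosterone, or a testosterone PGS for the
  reverse-causation-robust variant); per-bin trait-on-PGS slope,
  optionally on trait residualized per-bin against covariates (e.g. age);
  per-sex Pearson correlation of slope with bin mean, with Fisher-z 90%
  CI.
* **Cross-validated prediction comparison** — per fold, an additive score
  from a combined-sample GWAS versus sex-specific scores from the
  posterior effects of a covariance-mixture fit on the training split;
  incremental R² on held-out individuals (equal to R² here since no
  covariates enter the synthetic cohorts) and their ratio.  A caveat
  worth stating: when all effects are perfectly correlated with a single
  shared magnitude ratio, the additive model is correctly specified up to
  scale and enjoys the full combined sample size, so the covariance-aware
  model has no expected advantage; genuine gains require heterogeneous
  architectures (e.g. sex-specific components), and the test suite plants
  exactly that.

## 5. Sexually antagonistic selection test

**Model.**  At a biallelic autosomal site with zygote frequency p equal in
both sexes, write the additive viability selection coefficient in sex z as
s_z.  First-order perturbation of Hardy-Weinberg zygotes gives the adult
frequency p_z ≈ p + p(1−p)s_z, so with p̄ ≈ p,

    F_ST = (p_m − p_f)² / (4 p̄(1−p̄)) ≈ ¼ p(1−p)(s_m − s_f)².

Taking selection linear in the additive effect in each sex, s_z = a_z β_z
(a_z ≥ 0), and frequencies at equilibrium under antagonistic selection,
s_f = −s_m (so selection favoring the allele in one sex balances selection
against it in the other), the two constraints imply
β_f = −(a_m/a_f)β_m and

    s_m − s_f = 2k(β_m − β_f),  k = a_m a_f/(a_m + a_f),

hence F_ST ≈ A·V_GxSex with V_GxSex = 2p(1−p)(β_m−β_f)² and

    A = k²/2.

For equal gradients a_m = a_f = a this is a²/8.  The constant returned by
`true_selection_constant` is verified in the test suite by exact numerical
simulation of the viability model.  The divergence generator simulates
s_f = −s_m directly (the equilibrium assumption is a constraint, not a
free parameter) and records a_m, a_f only to compute the implied A.

**Estimation.**  Per site, V̂ = 2p(1−p)(β̂_m−β̂_f)² uses the GWAS-sample
frequency; its sampling variance treats p as known and uses the exact
normal moments of (β̂_m−β̂_f)²,

    Var[V̂] = [2p(1−p)]²[2(σ⁴_m+σ⁴_f) + 4σ²_mσ²_f + 4(β̂²_mσ²_m+β̂²_fσ²_f)
              + 4(σ²_mβ̂²_f+σ²_fβ̂²_m) − 8β̂_mβ̂_f(σ²_m+σ²_f)],

with point estimates plugged in for the means.  Between-sex F_ST is
estimated from sex-specific sample frequencies and allele numbers by the
bias-corrected ratio

    F̂ST = [(p̂_m−p̂_f)² − SE²_m − SE²_f] / [4p̄(1−p̄) − SE²_m − SE²_f],

with binomial SE²_z = p̂_z(1−p̂_z)/an_z; negative values are retained
(required for approximate unbiasedness), and sites with non-positive
denominator — in practice only sites monomorphic in both sexes — are
excluded.  A is the slope of a weighted least-squares regression of F̂ST
on V̂ with weights 1/Var[V̂].  An intercept is included by default (robust
to baseline artifactual differentiation); a through-origin mode is
available since the model itself has none.  Each of 1,000 iterations
resamples the m populated LD blocks with replacement, draws one site per
resampled block, and records the WLS slope and Z = slope/SE; the estimate
is the mean Z (and mean slope), with 90% percentile CIs from 10,000
bootstrap re-samplings of the iteration values.

**Calibration caveats.**  The 90% CI of the mean over iterations measures
within-dataset subsampling spread, not across-dataset estimator error; at
high planted-selection signal it is much narrower than the estimator's
higher-order bias (weighting noise and errors-in-variables in V̂ enter at
the fraction-of-a-percent level), so recovery checks compare the mean
slope to the generative A at 2% relative tolerance.  Under the null, the
dispersion of mean Z across datasets depends on the sites-per-block
profile (≈0.96 at two sites per block in the test design, smaller with
more sites per block), so mean Z is a summary statistic with bootstrap
CIs rather than an exactly pivotal quantity.

## 6. The scaled amplification simulation study

The reference simulation design (300K individuals, 20K SNPs, 100
replicates) is scaled to desk size while preserving the per-SNP
signal-to-noise ratio h²N_sex/M ≈ 3.75: 15,000 individuals per sex, 2,000
SNPs all causal, h²_m = 0.5, female:male environmental variance ratio 1.2,
20 replicates per generative model, 250 pseudo-blocks with 40
weight-learning repeats per replicate, default 66-component grid.  Three
generative models: (A) all effects equal between sexes; (B) 86% equal,
14% with female magnitude 4× male, perfectly correlated; (C) 86% equal,
14% female-specific.  The implied amplification truth is 0 for A and −14
percentage points for B and C.

Observed behaviour at this scale: equal-effect weights and amplification
differences track the full-scale reference values, with two systematic
desk-scale effects worth knowing about.  First, single full-panel fits
concentrate more weight on the generating matrix than subsample-averaged
fits (the subsample fits are noisier and their average more diffuse).
Second, subsample averaging overestimates |amplification| under model C by
roughly 2-4 points (full-panel fits recover −14 almost exactly); the
overestimation direction matches the reference study's own report, and
shrinks as the per-fit panel grows.  `scripts/acceptance.py` recomputes
the study from scratch (seeded, ~10 minutes on one CPU).

## 7. Input formats and conventions

Summary statistics and allele-frequency tables are TSV with a header and a
configurable column-name dialect; LD blocks are BED3 (0-based half-open),
while variant positions are 1-based, so a SNP at position P belongs to
block (start, end] iff start ≤ P−1 < end.  Invalid rows are dropped with a
logged count rather than raising.  Frequency tables are harmonized to the
summary-statistics effect allele (p̂ → 1−p̂ where the counted allele is the
other allele); every selection-test statistic depends only on squared
frequency differences and p(1−p) and is invariant to allele relabeling up
to floating-point rounding (complementing a frequency is not exactly
involutive in binary arithmetic).

## 8. Known limitations

* Linkage equilibrium throughout the generators; block machinery is
  exercised on pseudo-blocks only.
* Heritabilities are consumed as external estimates (e.g. from LD score
  regression) — no internal h² estimator.
* The mixture model takes the per-SNP noise as known and diagonal;
  overlapping male/female samples would need a non-zero error
  correlation, which the likelihood supports but no interface exposes.
* The selection model is first-order in s and assumes equilibrium,
  near-1:1 sex ratio at conception and no artifactual differentiation
  beyond what the regression intercept absorbs.
* Mean-Z calibration of the selection test is design-dependent (see §5).
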