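# Methods

## The question and the design

Migraine is clinically heterogeneous: attacks differ in aura status,
pain quality, photo-/phonophobia, duration, nausea, and frequency.  A SNP
robustly associated with "migraine" may in fact be associated only with a
sub-group defined by one of these characteristics.  `migselect` tests
this *selectivity* directly.  For each SNP × characteristic pair, the
cohort is split into three groups: active migraineurs reporting the
characteristic (w), active migraineurs not reporting it (o), and
never-migraineurs (c).  Former migraineurs are excluded because they are
not sub-classified.  A special partition (`active_vs_former`) instead
compares active and former migraineurs against never-migraineurs.

## The likelihood and the six models

Within each group, genotypes are assumed to be in Hardy–Weinberg
equilibrium, so the 2·m_g alleles of the m_g retained individuals are
i.i.d. Bernoulli(p_g) and the minor-allele count k_g is
Binomial(n_g, p_g) with n_g = 2·m_g.  The log-likelihood (constants
dropped) is

    LL(p_w, p_o, p_c) = Σ_g [ k_g log p_g + (n_g − k_g) log(1 − p_g) ].

The six inheritance models are nested constraints on (p_w, p_o, p_c):
null (all equal, 1 df), basic (p_w = p_o, 2 df), subset (p_o = p_c,
2 df), inverse subset (p_w = p_c, 2 df), general (all free, 3 df), and
modifier (p_w, p_o free with p_c = w·p_w + (1−w)·p_o, 2 df).  The
modifier model encodes association with the characteristic conditional
on having migraine — cases differ by characteristic status but the
population margin is undisturbed.

All models except the modifier have closed-form MLEs (pooled sample
frequencies over the groups each parameter covers, with 0·log 0 = 0 at
boundary MLEs).  The modifier weight w is the allele-total proportion
n_w/(n_w + n_o); "weighted mean" admits other weightings, and
sample-size weighting is the natural default.  The modifier MLE is found
by L-BFGS-B on the logit scale with an analytic gradient (ftol 1e-10),
multistarted from the clipped sample frequencies and from the pooled
frequency.  The multistart matters: a start at a boundary frequency
(k_g = 0) has a vanishing logit-scale gradient and would otherwise
stall below the null log-likelihood, violating nesting.

Model selection minimizes AIC = −2LL + 2·df or BIC = −2LL + df·log N,
with N the number of individuals across the three groups (a switch
allows allele count instead).  Ties break toward fewer free parameters,
then a fixed model order.  As an optimization the modifier is only
fitted when the general model's criterion value minus the penalty
difference could beat the best closed-form model; this provably never
changes the selection.  The selected model is compared with the null by
the LLR statistic 2(LL_sel − LL_null), referred to a chi-square with
df = df_sel − df_null.  The analytic p-value is used only to *rank*
permutation replicates — any monotone convention for the reference df
yields identical empirical p-values — and a null selection reports
stat 0, p 1 by convention.

## Permutation significance

Empirical significance re-runs the entire selection procedure after
randomly reassigning genotypes to participants.  One permutation of
individuals per replicate is shared by all SNPs and characteristics,
preserving both inter-SNP correlation and the phenotype co-occurrence
structure.  A master seed spawns one child stream per replicate
(`numpy` `SeedSequence`), so results are reproducible regardless of
execution order.  Per SNP × characteristic the scan reports:

* **frac_nonnull** — the fraction of replicates selecting a non-null
  model (the chance rate of a non-null call under this criterion);
* **empirical_p** — the fraction of permuted analytic LLR p-values ≤
  the observed one.  Null-selected replicates contribute p = 1 (a
  documented switch conditions on non-null selections instead);
  fractions use the plain r/B convention, with (r+1)/(B+1) optional.
* **rank-adjusted p** — for each SNP, the observed r-th smallest
  analytic p across its 10 characteristics is compared with the
  permutation distribution of r-th smallest p-values.  The adjusted
  values are then forced monotone non-decreasing in rank (cumulative
  maximum, the standard step-down enforcement).  Without that step the
  raw rank statistic is not monotone in the observed p — raising an
  observed p can push it to a higher rank whose order-statistic
  distribution is stochastically larger — which would let a *larger*
  p-value receive a *smaller* adjusted value.
* **Šidák p** — 1 − (1 − p)^m across SNPs, default m = 12 assumed
  independent.

Because null-selected cells contribute analytic p = 1, the
selection-based empirical p has an atom at 1 and is *conservative*
(super-uniform) rather than uniform under the null; under BIC at cohort
scale the atom covers ≈ 99 % of cells.  Calibration of the permutation
machinery is therefore checked on the always-fitted 2-df general-vs-null
LLR statistic (`general_vs_null`), which is continuous and whose
permutation empirical p is exactly uniform on {1/B, …, 1} under
exchangeability; the selection-based empirical p is separately verified
to be valid (never anti-conservative).

## Stratified effects and the coded allele

Per SNP and characteristic, three unadjusted logistic regressions
compare cases against never-migraineurs on additive allele dose
(0/1/2): the with-stratum, the without-stratum, and all active
migraineurs ("actmig").  Wald standard errors and two-sided p-values
are reported; separation or non-convergence produces a flagged estimate
with a diagnostic message rather than a silent NaN, and a configurable
guard (default ≥ 10 cases and ≥ 10 controls) rejects degenerate strata.
The coded allele is chosen per SNP as the allele associated with
increased odds of *any* report of migraine (active + former vs never);
β ≥ 0 keeps the minor allele, otherwise the major allele is coded and
all betas flip sign.  No covariate adjustment is applied by default.

## Selectivity clustering

Each SNP's selectivity profile is the 10-vector
t_c = (β_with,c − β_without,c)/√(se²_with,c + se²_without,c).  Entries
are correlated because the characteristics overlap within individuals,
so distances use the Mahalanobis metric under a covariance Σ estimated
as the sample covariance of t-vectors over a panel of SNPs with no
migraine association.  In the shipped pipeline that panel is simulated
(no-association SNPs on the same cohort), with the panel size
configurable (default 1,222); a guard requires ≥ 30 panel SNPs, and a
singular Σ falls back to the Moore–Penrose pseudo-inverse with a
warning.  Agglomerative clustering uses complete linkage by default
(single/average exposed); the merge tree is exported as Newick with
merge-height differences as branch lengths, and the leaf order sorts
the effect-matrix report.  Whether distances should be squared before
clustering is an open choice; unsquared distances are used.

## The synthetic cohort

The generator emulates the study's margins: 3,003 active, 2,119 former
and 18,108 never migraineurs by default, with characteristic
prevalences equal to the published count ratios (aura 1,177/3,003 =
0.39, photophobia 0.66, duration 4–72 h 0.78, …).  Characteristics are
drawn independently per active migraineur by default; an exchangeable
latent-normal correlation ρ is available because real attack features
co-occur, but no published co-occurrence rates exist to calibrate it.
Genotypes are Binomial(2, p_g) per individual under HWE with
group-specific frequencies anchored to a single characteristic per SNP
and satisfying the generating model's constraints exactly (validated at
construction; for the modifier the weight is the anchoring
characteristic's prevalence).  Former migraineurs receive the control
frequency unless `p_former` is set.  SNPs are independent: no linkage
disequilibrium, population structure, or dosage noise is simulated, so
passing tests demonstrate correctness of the statistical machinery
under the stated model, not robustness to stratification or imputation
artefacts in real data.  Default MAFs lie in [0.2, 0.4], typical of the
common-variant panels this design targets.

A count-level sampler (`simulate_trigroup_counts`) draws
k_g ~ Binomial(2·m_g, p_g) directly — distributionally identical to
summing individual genotypes — and powers the calibration and recovery
studies at cohort scale and 10× cohort scale in seconds.

## Numerical and problem-size choices

* Likelihood comparisons need no binomial coefficients (they cancel);
  the toy oracle values in the tests use the same convention.
* Grid-search oracles refine a 2001-point grid four times, resolving
  MLEs to < 1e-6.
* The null-calibration study uses 2,000 replicates at the cohort's
  aura split (1,177/1,826/18,108) and MAF 0.3; the measured chance rate
  of non-null AIC selections is ≈ 0.35 (Monte-Carlo SE ≈ 0.011 at
  2,000 replicates).  The BIC chance rate at the same scale is < 0.01.
* Model-recovery properties run 40 replicates per generating model at
  10× cohort scale with moderate-to-strong frequency differences
  (0.03–0.09); BIC is the criterion because it is selection-consistent.
* The permutation-uniformity check uses B = 200 permutations on 200
  independent null cells of a compact cohort (60/90/300 individuals);
  uniformity of the permutation p does not depend on group sizes.
* Pipeline examples and tests use ~32–40 simulated null SNPs for the
  covariance panel; each panel SNP costs 21 logistic fits, so the
  1,222-SNP default is reserved for full-scale runs.

## Known limitations

* The likelihood is allele-based; genotype-level (multinomial)
  likelihoods and X-chromosome handling are out of scope.
* Hard calls only: imputed dosages must be rounded by the caller, and
  missing genotypes are dropped per SNP (complete case).
* The analytic LLR p after model selection has no clean chi-square
  interpretation (the selection event truncates it); it is a ranking
  device, and only the permutation quantities are inferentially
  meaningful.
* The Šidák stage assumes independent SNPs; correlated panels need a
  smaller effective m.
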