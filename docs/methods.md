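# Methods

`lassogwas` implements a two-step multi-SNP association analysis for
pedigreed populations with EBV-like phenotypes, together with the synthetic
data generators used to exercise and validate it.

## Model

For a trait vector **y** of n individuals the two steps share one model
family:

**Step 1 (single-SNP mixed-model scan).** For each SNP j,

    y = 1 mu + x_j beta_j + Z g + e,
    g ~ N(0, A sigma_g^2),    e ~ N(0, I sigma_e^2),

where x_j is the SNP's genotype column coded AA/AB/BB -> -1/0/+1 and A is
the pedigree numerator relationship matrix (Z = I; one record per
genotyped individual).  Variance components are estimated **once**, by REML
on the null polygenic model with no SNP term, and held fixed across the
scan; each per-SNP fit is then a single linear solve of the mixed-model
equations with the random effect absorbed.  Each beta_j is tested with a
two-sided t statistic (df = n - 2, variance components treated as known)
against the Bonferroni genome-wise threshold -log10(alpha/N) for N scanned
SNPs.  The K = 500 smallest-P SNPs go to step 2.

**Step 2 (multi-SNP adaptive Bayesian LASSO).** The selected SNPs are fit
jointly,

    y = 1 mu + X beta + Z g + e,

with an independent Laplace prior (lambda_j/2) exp(-lambda_j |beta_j|) on
each effect and a gamma(a, b) hyperprior on lambda_j^2/2 with
a = b = 1e-6, so each SNP carries its own data-adapted shrinkage strength.
The fit is a posterior mode obtained by expectation-maximization treating
the polygenic vector g and the Laplace scale-mixture auxiliaries tau_j^2
as missing data (beta_j | tau_j^2 ~ N(0, tau_j^2), tau_j^2 ~
Exp(lambda_j^2/2)):

- E-step: E[g | y, ...] is a mixed-model solve, done in the eigenbasis of A
  where it is diagonal; E[1/tau_j^2] = lambda_j/|beta_j| and
  E[tau_j^2] = |beta_j|/lambda_j + 1/lambda_j^2.
- M-step: (mu, beta) solves a diagonally penalized least-squares system on
  y - E[g]; lambda_j^2 <- 2(a+1)/(b + E[tau_j^2]) (the conjugate-gamma
  maximizer); sigma_g^2 and sigma_e^2 are re-maximized (below).

Each SNP's contribution is summarized as a heritability

    sigma_j^2 = 2 p_j (1 - p_j) beta_j^2,
    h_j^2 = sigma_j^2 / (sum_j sigma_j^2 + sigma_g^2 + sigma_e^2),

with p_j the +1-allele frequency on the analysis sample — the variance of
the coded genotype under HWE times the squared effect, so SNPs with
different allele frequencies are compared on a common scale.

**Significance.** The genome-wise threshold for h_j^2 is the empirical
95th percentile (type-7 interpolation) of max_j h_j^2 over phenotype
permutations (default 1000): y is shuffled against the fixed X and A,
breaking both SNP and polygenic associations, and the whole step-2 fit is
repeated per permutation.  A SNP is significant when its observed h_j^2
strictly exceeds the threshold.  Significant SNPs are annotated with the
nearest gene within 1 Mb (distance to the nearer gene boundary; 0 =
inside the gene; ties to the smaller start coordinate).

## Numerical choices

- **Objective and monotonicity.** The EM tracks the log joint posterior of
  (mu, beta, lambda, sigma_g^2, sigma_e^2) with g and tau marginalized:
  the Gaussian marginal likelihood with V = A sigma_g^2 + I sigma_e^2 plus
  sum_j [log(lambda_j/2) - lambda_j |beta_j|] plus the hyperprior term
  written as sum_j [a log(lambda_j^2/2) - b (lambda_j^2/2)] (the
  "density proportional to s^a e^(-bs)" convention, under which the
  lambda update above is the exact conditional maximizer).  Updates are
  conditional-maximization steps against expectations computed at the top
  of the iteration, so the trace is non-decreasing; the test-suite fails
  on any decrease beyond 1e-8.
- **Variance components in step 2.** By default sigma_g^2 and sigma_e^2
  are carried unchanged from the step-1 null-model REML fit
  (`update_varcomps=False`).  Re-maximizing them inside the multi-SNP
  model is available as a switch, but measurements on structured cohorts
  argue against it as a default: the K marginally selected SNPs and the
  polygenic term compete for the same family variance, the re-maximized
  sigma_g^2 can exceed the null-model value and the variance total can
  exceed var(y), deflating every h_j^2 inconsistently and (measured on
  half-sib cohorts) inflating the permutation type-I rate severalfold.
  With the step-1 values frozen, the h_j^2 denominator stays anchored to
  the null-model variance decomposition and the permutation test is
  calibrated.  (Because the null-model components already contain the
  causal variance, the frozen denominator modestly exceeds var(y) and the
  h_j^2 are slightly conservative; the permutation threshold is computed
  under the same convention, so declared significance is consistent.)  When re-maximization is enabled, it maximizes the marginal
  objective given (mu, beta) directly — a profile solve over the variance
  ratio in the eigenbasis (gamma = 0 and the current value are always
  candidates, so the step never decreases the objective; the complete-data
  EM update crawls with O(1/t) steps near the sigma_g^2 = 0 boundary) —
  and runs every 4th iteration, with convergence declared only on a
  fresh-update iteration.
- **Acceleration.** The adaptive prior produces slow "coefficient death"
  dynamics: a near-boundary effect has lambda_j growing and beta_j
  collapsing over hundreds of vanilla EM iterations.  Every second
  iteration the fit therefore proposes a joint extrapolation of
  (beta, log lambda, mu) along the current EM direction (fixed large and
  Aitken-sized steps) and accepts the best proposal only when the tracked
  objective increases — ascent stays exact, typical iteration counts drop
  3-4x, and the converged mode is unchanged.
- **Zero clamp.** Effects with |beta_j| < 1e-8 * sd(y) are frozen at
  exactly 0 and leave the active set permanently; the prior's mode at zero
  is absorbing and the clamp removes the 1/|beta_j| blow-up.
- **Initialization.** mu = mean(y); beta from the step-1 scan estimates
  when available, else per-SNP marginal regression; lambda_j = 1; variance
  components from the null REML fit.  An all-zero beta start is never
  used: it is itself a fixed point of the absorbing zero clamp, so the
  iteration would terminate immediately at beta = 0.  Permutation refits
  initialize from the single-SNP GLS effects of the *permuted* phenotype
  (one rotation each; the single-SNP workspace is permutation-invariant),
  so the permuted statistic is the same function of the phenotype vector
  as the observed fit — required for the permutation test's
  exchangeability argument to apply to the procedure actually run.
- **Convergence.** max_j |delta beta_j| < 1e-6 * sd(y), at most 1000
  iterations; a non-convergent fit is returned with a flag and a warning.
- **Null REML (step 1).** Profile restricted likelihood over the variance
  ratio in the eigenbasis of A, maximized by bounded scalar search with the
  sigma_g^2 = 0 boundary checked explicitly.  This is exact and fast at
  desk scale and has no boundary pathology.
- **Scan solve.** The per-SNP system is the mixed-model equations with g
  absorbed: P = I/sigma_e^2 - M_gg^{-1}/sigma_e^4 with
  M_gg = I/sigma_e^2 + A^{-1}/sigma_g^2 is built once per trait and reused
  by every SNP; the test-suite checks it against direct GLS with V
  inverted explicitly.
- **Kinship.** A is built by the tabular method on the topologically
  sorted pedigree; unknown parents are unrelated non-inbred founders.  The
  model subsets A to phenotyped individuals (marginalizing ancestors is
  sub-matrix extraction).  Verified against a recursive-coancestry oracle.
- **QC.** A SNP is removed when MAF < 1% or call rate < 90% or the
  Pearson 1-df HWE chi-square P < 1e-6 — strict inequalities, so
  boundary values survive.  MAF is defined on observed calls; post-QC
  missing genotypes are mean-imputed per SNP, keeping the design dense.
  Allele B (+1) is the observed minor allele (ties: the later-sorting
  allele); h_j^2 and sigma_j^2 are invariant to that orientation.

## Synthetic data: what it emulates, and what it does not

The generator produces (i) discrete-generation random-mating pedigrees and
paternal half-sib designs; (ii) founder genotypes in HWE at per-SNP MAF ~
Uniform(maf_low, maf_high), transmitted by gene dropping (one uniformly
chosen allele from each parent, independently per SNP); (iii) phenotypes
y = mu + X_causal * effects + g + e with g drawn through the Cholesky
factor of A.  It emulates family structure, Mendelian transmission, a
realistic MAF spectrum, missing calls and planted causal effects — the
features the estimator actually uses.  It does **not** emulate linkage
disequilibrium beyond pedigree co-transmission, selection, multi-breed
structure, or the shrinkage/accuracy structure of real EBVs (the phenotype
is genetic value plus noise).  Passing tests therefore demonstrate
correctness of the estimator under its own model assumptions, not
robustness to LD-induced multicollinearity among physically linked SNPs.

Default study conditions for the bundled analyses and the acceptance
script mirror a progeny-test cohort: 1000 phenotyped daughters in a
paternal half-sib design (50 sires x 20 daughters, each daughter from a
distinct dam), 1500 SNPs on 5 chromosomes, MAF ~ U(0.05, 0.5), five
causal SNPs each explaining ~3% of phenotypic variance, polygenic
variance 0.30, residual 0.50.  The half-sib structure matters beyond
realism: in a deep closed pedigree (few founder genomes), hundreds of
jointly fitted SNPs collectively tag the polygenic term, degrading both
h_j^2 ranking and permutation calibration; the half-sib design keeps SNP
columns close to independent of family structure, which is also the
regime the method was designed for.  Validation problem sizes:
permutation type-I calibration uses 50 null half-sib cohorts of n = 300
daughters with K = 100 SNPs and 200 permutations each; parameter
recovery uses 50 replicates of n = 1000 daughters with K = 500 and 50
permutations per replicate (enough for a stable 95th percentile next to
planted heritabilities several times the threshold).

## Design choices on genuinely open points

- **lambda update.** The per-SNP update lambda_j^2 = 2(a+1)/(b +
  E[tau_j^2]) is the conjugate-gamma conditional maximizer under the
  hyperprior convention above.  Its fixed point behaves like
  lambda_j ~ 2/|beta_j|, i.e. weak shrinkage on large effects and an
  absorbing zero for small ones — the intended adaptive behaviour.  A
  consequence worth knowing: on pure-noise data the fit usually keeps the
  luckiest SNP at a small nonzero effect rather than zeroing everything;
  the permutation threshold is what absorbs this, which is also why the
  threshold is nonzero.
- **What is permuted.** The phenotype vector, against fixed X and A.  This
  breaks SNP and polygenic associations simultaneously and needs no new
  factorizations per permutation.  Because shuffling also destroys the
  real polygenic covariance, the permuted fits see "extra" unstructured
  variance for SNPs to absorb, which tends to make the threshold mildly
  conservative in strongly familial cohorts — the calibration suite
  bounds this empirically.
- **Within-model variance re-estimation.** Both modes are implemented;
  the default carries the step-1 REML values (see the variance-component
  bullet above for why re-maximization is not the default).
- **t-test df.** n - 2 (intercept + SNP), variance components treated as
  known.  With n >= 200 the difference from any heavier-tailed choice is
  negligible at the thresholds used.
- **Correlation binning.** Five levels with bounds (-1, -0.66, -0.33,
  0.33, 0.66, 1); interior boundary values go to the higher-index
  interval, the outer intervals are closed at +/-1.
- **Gene coordinates.** Held 1-based inclusive; BED input (0-based
  half-open) is converted on ingestion.  Distance is SNP to nearer gene
  boundary.

## Limitations

- The polygenic solve assumes one phenotype record per individual (Z = I).
- No population-structure covariates or PCs; background structure is
  carried entirely by A.
- K (top-500) selection and the step-2 fit reuse the same data; the
  permutation threshold inherits whatever selection optimism exists, which
  is the intended behaviour of the procedure, not a bug fix left undone.
- When K marginally selected SNPs are fit jointly in a strongly pedigreed
  cohort, they collectively tag family structure, and the within-model
  sigma_g^2 can be driven to 0 with the polygenic variance reassigned to
  many small SNP effects.  The h_j^2 denominator stays close to var(y)
  either way, and the permutation threshold is computed under the same
  behaviour, so declared significance is unaffected; but the fitted
  sigma_g^2 itself should not be read as a heritability estimate.
- Dense linear algebra throughout: designed for n up to a few thousand,
  not biobank scale.
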