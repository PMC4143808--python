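# Methods

## The problem

Longitudinal cohorts measure blood pressure repeatedly on the same subjects,
and family-based sequencing studies collect those subjects in pedigrees.  Both
structures correlate observations: repeated measurements share subject-level
variation, and relatives share polygenic variation in proportion to their
kinship.  `longfam` implements the regression machinery for testing genetic
association — single common SNPs, and transcript-level burden scores of rare
functional variants — against such phenotypes, together with the design
comparisons a study planner cares about: how much power the relatives add over
the unrelated subset, and how best to use the repeated measurements (first
visit only, per-subject average, or all visits jointly).

## Models

Write `y_pit` for the (medication-preadjusted) trait of subject `i` in family
`p` at visit `t`, `S_i` for the marker (dosage or burden score), and `X_pit`
for intercept, sex, smoking, age, and optional ancestry PCs.  Five nested
models share one engine:

| id | response | random terms | marginal covariance |
|----|----------|--------------|---------------------|
| M1_linear | baseline or averaged | — | `sigma^2 I` |
| M2_subject | repeated | subject intercept `b_i` | `sigma_b^2` within subject |
| M3_family | baseline or averaged | polygenic `g_pi` | `2 psi_ii' sigma_g^2` between relatives |
| M4_family_subject | repeated | `g_pi + b_pi` | both; `sigma_g^2 + sigma_b^2` within subject |
| M5_family_reduced | repeated | `g_pi` | `sigma_g^2` within subject |

The polygenic covariance uses the pedigree kinship coefficient `psi`, computed
by the classical recursion (`psi_ii = (1 + psi_fm)/2`,
`psi_ij = (psi_fj + psi_mj)/2` with parents processed first; founders
unrelated and non-inbred).  The covariance matrix is block-diagonal by family,
which the engine exploits: every likelihood evaluation factorizes per-family
Cholesky blocks, so cost is cubic only in family size.

### Estimation and testing

Variance components are estimated by REML with the residual variance profiled
out; the remaining one or two variance *ratios* are optimized on the log scale
by Nelder-Mead simplex (derivative-free; at most two dimensions), started at
an equal partition of the phenotypic variance, with a floor of 1e-10 on each
ratio and convergence at 1e-8 on the restricted log-likelihood (at most 200
iterations per free ratio).  Ratios driven to the floor are reported as a zero
component.  Fixed effects are then GLS estimates at the fitted covariance, and
the marker is tested by a Wald statistic with standard-normal reference,
`p = 2 Phi(-|beta/se|)`.  Neither the test statistic nor the estimation
criterion is forced by the scientific setting; REML plus Wald is the standard
pairing for these models and is this package's choice.  A likelihood-ratio or
score alternative would give slightly different p-values in small samples.

Two properties of this choice worth knowing:

* **Boundary estimates.** When a true variance component is zero, its REML
  estimate is zero only about half the time on any finite dataset; otherwise
  it is a small positive number.  Consequently M4 and M5 fits on
  `sigma_b^2 = 0` data coincide exactly only when the boundary estimate lands
  at zero (or when components are held fixed); a free refit can differ in the
  second or third decimal of the p-value.  The tests check the algebraic
  coincidence at fixed components and the REML path conditionally.
* **Normal vs t reference.** The Wald normal reference is mildly
  anticonservative at small sample sizes; at the sample sizes used here
  (hundreds of subjects) the measured type-I error is within Monte-Carlo noise
  of nominal (see the calibration test).

### Scanning and the two-stage strategy

Per-marker REML is wasteful for chromosome-scale scans.  `null_model_cache`
fits the variance components once without any marker, whitens the response
and covariates with the fitted covariance, and scores each marker by GLS with
components held fixed — the familiar screening approximation in mixed-model
association.  The exact per-marker refit remains available, and the two-stage
strategy uses it: screen every marker under the cheaper reduced family model
(M5), then refit the `top_k` hits (ascending screening p, ties broken by
genomic position) under the full model (M4), reporting both p-values.

### Multiple testing and diagnostics

Bonferroni thresholds are reported both raw (`alpha/m`) and ceiling-rounded
at two significant figures; significance calls use the raw value.  The
genomic-control inflation factor is
`lambda = median(qchisq(1 - p, 1)) / 0.4549`; QQ data pairs sorted observed
`-log10 p` against uniform quantiles.

## Burden scores

Rare variants are those with minor allele frequency strictly below 5%
(computed on the full analyzed sample; a subject-subset argument exists for
founder-only frequencies).  A variant enters a transcript's burden set only if
its functional category *for that transcript* is one of: missense,
missense-near-splice, splice-3, splice-5, stop-gained, stop-lost,
stop-lost-near-splice.  Transcripts whose summed member MAF is below 0.01 are
excluded.  The burden score is the unweighted dosage sum over members;
fractional (imputed) dosages are used as-is by default, with an optional
hard-call rounding, and missing dosages are mean-imputed per variant.

## Stratification control

Common SNPs are LD-pruned (pairwise squared Pearson dosage correlation < 0.2
in a 50-SNP window advancing by 5; keep-first tie-break) among the unrelated
subjects only.  PCA standardizes each pruned SNP by `2 p-hat` and
`sqrt(2 p-hat (1 - p-hat))` estimated on the unrelated subjects,
eigendecomposes their standardized genotypes, and projects all remaining
subjects onto the SNP loadings — relatives would otherwise distort the
leading axes toward family structure.  The default of 10 components is a
convention, not an estimate; the calibration test selects nothing, it only
verifies that the projected PCs restore genomic control in a stratified null.

## The synthetic-data generator

No public data accompany this analysis class, so the generator is a
first-class module.  It emulates:

* **Pedigrees** — independent copies of a three-generation template (founder
  couple, their children, married-in founder spouses, grandchildren; default
  4+4+4 = 12 members, 4 founders) plus singleton founders.  Defaults of 20
  pedigrees and 100 singletons give 340 subjects with 180 unrelated — a
  desk-scale version of a 20-pedigree family study with an unrelated subset.
* **Genotypes** — Mendelian gene dropping at independent biallelic loci:
  founder alleles i.i.d. Bernoulli(MAF), one uniformly chosen allele
  transmitted per parent per meiosis.  Common MAFs uniform on [0.05, 0.5];
  rare MAFs log-uniform on [0.002, 0.05], grouped 8 per transcript.  An
  optional two-subpopulation mode draws founder frequencies from the
  Balding-Nichols beta (default Fst 0.05) with whole pedigrees assigned to
  subpopulations.
* **Phenotypes** — the full-model generative process: polygenic effect drawn
  from N(0, sigma_g^2 * 2 Psi) per family block, subject intercept
  N(0, sigma_b^2), i.i.d. residual N(0, sigma^2), linear age trend, sex and
  smoking effects, marker effects for designated causal variants, and an
  optional subpopulation mean shift.  Default variances (4, 2, 4) mm Hg^2,
  age slope 0.5 mm Hg/yr, sex +3, smoking +5, intercept 100 mm Hg — round
  values of plausible blood-pressure magnitude chosen once.  Ages start near
  65/40/15 by generation (plus-minus 5 uniform) and advance 5 years per visit
  (three visits by default).
* **Medication** — each record is independently medicated with probability
  0.2, and the *stored* trait subtracts the offset (10 mm Hg systolic,
  5 diastolic), so the preadjustment step recovers the latent value exactly,
  record by record.

What it does **not** emulate: linkage disequilibrium between loci (every
variant segregates independently), genotyping error and missingness (absent
by default, injectable), non-Gaussian trait tails, medication assignment
correlated with blood pressure, assortative mating, or inbreeding.  Passing
tests therefore demonstrate correctness of the estimators under their own
model assumptions and the qualitative design conclusions (relatives add
power; averaging helps under a linear trend) — not robustness to real-data
pathologies.

## Numerical and design choices

* Subject order is family-major, file order within family; the kinship matrix
  fixes the block structure the engine uses.
* The unrelated subset is greedy and deterministic: founders in file order,
  then any individual with zero kinship to everyone selected.  It is one
  defensible rule among several; nothing downstream depends on which maximal
  zero-kinship set is chosen.
* MAF folding happens at read time (sites with alternate-allele frequency
  above 0.5 are flipped and flagged), so all dosages count minor alleles.
* Zero-variance markers are flagged and skipped, never tested; collinear
  covariates raise an error naming the offending column.
* PCA signs are fixed (largest-magnitude loading positive) for
  reproducibility.
* Monte-Carlo checks of genomic-control lambda pool p-values over a few
  seeded replicate datasets: a single dataset shares one phenotype
  realization across all markers, which alone gives lambda a standard
  deviation near 0.06 — too noisy for a [0.9, 1.1] band regardless of how
  many markers are scored.
* Problem sizes in the test suite and acceptance script (40 pedigrees of 11
  for calibration and recovery, 2,000 null markers per replicate, 200
  replicates for power orderings, 800 markers for stratification) were chosen
  as the smallest scales at which the Monte-Carlo bounds above are sharp.

## Known limitations

* Unequal visit counts are supported by the covariance code but the
  generator always produces complete panels, so that path is only lightly
  exercised.
* The engine fits at most two free variance ratios; models with additional
  random effects (e.g. a linkage IBD component) are out of scope.
* Score and likelihood-ratio tests, variance-component (heritability) tests,
  weighted burden schemes, and empirical genotype-based kinship are not
  implemented.
* Exact replication of any particular published p-value is not a goal: the
  test statistic and estimation criterion are this package's documented
  choices, and restricted cohort data are not reproducible from a simulator.
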