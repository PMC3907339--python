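# Methods

This note records the models, defaults and numerical choices behind
`rarelocus`, and what the synthetic-data checks do and do not establish
about behaviour on real cohorts.

## Synthetic cohort model

**Study design.** The generator emulates a targeted re-sequencing study in
a recently expanded founder population: a large population-cohort arm and a
smaller case-control arm that overlap in covariate and genotype space. The
full-scale default is 6,123 individuals split 4,447 / 836 controls / 840
cases; tests and the reproduction script scale `n_individuals` down (300 to
5,000 depending on the check) to keep runtimes in minutes, which is
adequate because every assertion is either exact arithmetic or a
Monte-Carlo band that accounts for its own sample size.

**Allele frequencies.** Sites are independent (no haplotype structure; see
Limitations). The neutral baseline draws population minor-allele
frequencies from the density f(p) ∝ 1/p on [1/(4n), 0.5] — the
infinite-sites stationary form, folded — and conditions on segregating in
the sample by rejection with probability 1−(1−p)^2n. The default
*parametric bottleneck* mixes this with a Beta(2, 150) component (weight
0.25, mode ≈ 0.7%) concentrating mass in the 0.5–2% band: the signature of
a bottleneck-and-expansion history is fewer singletons and more
intermediate-frequency ("Goldilocks") alleles than the 1/i spectrum, and a
mixture reproduces that signature at negligible cost. An explicit
two-epoch forward Wright–Fisher mode (one generation through
`bottleneck_size`, then `generations_post` generations at
`ancestral_size`, binomial drift throughout) is available when a concrete
demographic history matters; the parametric form is the default because
the pipeline only uses the bottleneck qualitatively.

**Genotypes.** Hardy–Weinberg binomial(2, p) dosages; optional
two-subpopulation Balding–Nichols structure (Beta((1−F)/F-scaled
parameters) at `substructure_fst`, split along the cohort arms) for
stratification experiments. The only linkage the generator models is the
planted correlation between an array SNP and a partner variant
(`correlated_dosages`, haplotype-copying construction whose dosage r²
equals the squared copying probability).

**Phenotypes.** Six traits (TG, HDL-C, LDL-C, TC, FG, FI). TG, FG and FI
are generated so their *logarithm* is linear in the predictors; the
pipeline likewise log-transforms them before residualization. Trait
means/SDs and covariate coefficients are unspecified by any external
source, so the defaults are chosen once for plausibility (e.g. TC
5.2 ± 1.0 mmol/L, HDL-C higher in women, TG raised by oral-contraceptive
use; age uniform on 31–62, OC use and pregnancy only in women). Genetic
effects are specified in residual-SD units per allele copy and converted
to trait units internally; the truth object stores per-signal variance
fractions 2p(1−p)β²/Var so Σ ≤ 1 by construction.

**Replicate call sets.** Each of three centers gets the true genotypes
with independent per-genotype replacement errors at `center_error_rate`
(default 2×10⁻⁴, chosen so pairwise concordance lands near the 99.96%
regime typical of replicate calling) and no-calls at
`center_missing_rate` (0.2%). Artifact plumbing can plant multi-allelic
or discordant-ALT site records in one center to exercise consensus
exclusions.

**Randomness.** One master seed fans out to named per-stage substreams
(frequencies, genotypes, covariates, phenotypes, effects, centers), so a
stage is reproducible independently of how many draws earlier stages made.

## Consensus and QC

Majority is over genotype *values*, not alleles: a genotype enters the
consensus iff ≥ 2 centers agree on the dosage; a fully-called triple with
three distinct values is set missing. Sites are excluded outright when any
center's record is multi-allelic or the centers disagree on the
alternative allele. Concordance is reported over all pairwise
center-comparisons at mutually non-missing calls; the per-class
(hom-ref/het/hom-alt) split assigns each pair to the class of the majority
value at that cell, falling back to the first center's call when no
majority exists (the choice only affects cells that are already
discordant). Sample QC consumes a precomputed per-individual coverage
fraction — depth computation from alignments is out of scope — and applies
the inclusive gates coverage ≥ 0.70 and check-SNP concordance ≥ 0.90.

The validation ledger is pure arithmetic over the low-count validation
outcomes. One published ledger it replays is internally off by one
(tripletons 91 + doubletons 205 + singletons 366 = 662 against a printed
total of 663); the ledger derives 662, accepts the printed total as an
explicit input, and emits a warning rather than silently reconciling.

## Population-genetic summaries

The SFS is folded. Sites with missing genotypes have fewer observed
chromosomes; each is projected to the common (minimum) chromosome count by
the hypergeometric expectation before aggregation, so the spectrum refers
to one sample size. Projection distributes a count-i-of-n site's mass over
j minor alleles in m draws without replacement, discards j ∈ {0, m}
(monomorphic in the smaller sample) and refolds; projected counts are
expectation-valued. θ_W = S/(a_n L); θ_π sums the unbiased per-site
estimator 2c(n_s−c)/(n_s(n_s−1)) — genotype-level, no phasing required.
"Rare" defaults to MAF < 1% (the gene-level cutoff); the 0.5% convention
used in cross-study comparisons is available as an argument. Goldilocks
(0.5–2%) is an overlay flag, not a partition member. The functional×rare
odds ratio uses the Woolf log-OR interval with Haldane–Anscombe 0.5
correction (flagged) on zero cells.

## Association testing

Residualization fits ordinary least squares of each (possibly logged)
trait on age (centered at 45), age², sex, OC use, pregnancy and a cohort
indicator over the combined cohorts; diabetic cases are excluded from FG
and FI. A rank-based inverse-normal variant is available for sensitivity
analyses. Constant covariate columns (e.g. no pregnancies in a small
subsample) are dropped rather than allowed to singularize the design.

PCA standardizes dosages by 2p̂ and √(p̂(1−p̂)) over greedily LD-pruned
(r² < 0.5, window 50, step 5 — conventional defaults) common (MAF ≥ 1%)
SNPs, mean-imputing missing calls; the top 5 components are covariates in
every test. Single-variant tests are per-variant complete-case OLS with
exact t p-values (not the normal approximation — free exactness at
moderate n), with a strict MAF > 0.1% floor. The conditional test appends
the array-SNP dosage to the covariates; r² > 0.99 with the tested variant
is reported as non-estimable, and a constant array covariate is dropped so
conditioning on a degenerate column equals the unconditional test exactly.
Signals are called independent of the array SNP iff r² < 0.20 (strict).
The case-control scan is a logistic Wald test (MAF > 1%) with
quasi-separation flagged rather than raised.

## Gene-level tests

Gene sets are non-synonymous variants (nonsense + all missense classes)
with in-sample MAF strictly below 1%, ≥ 2 qualifying sites, restricted to
individuals with complete genotypes across the gene's sites. CMC weights
default to Madsen–Browning 1/√(n p̂(1−p̂)), with flat-weight and 0/1
carrier-collapse options; the burden statistic is the squared t of the
burden coefficient with PCs in the model, and the permutation p-value
permutes the residual vector (PCs enter the null model before
permutation). When p̂ < 10/B the permutation count escalates tenfold up to
10⁶ by default. SKAT weights default to the Beta(1, 25) density in MAF
(flat option); the mixture tail probability uses Imhof's inversion
integral (exact chi-square shortcut when all eigenvalues coincide; the
quadrature is accurate to ~10⁻⁶ absolute), falling back to the Liu
moment-matching approximation if the integral misbehaves or returns a
value below 10⁻¹², where inversion accuracy gives out. The
direction summary compares carrier vs non-carrier mean residuals per
variant.

Calibration experiments (in `rarelocus.calibration`) use directly
constructed gene sets: type-I error of both tests on 1,000 null gene sets
(n = 400, B = 1,000); the power ordering on 200 replicates per
architecture at n = 1,500 with per-allele effects of 0.25 SD
(same-direction) and ±0.35 SD (mixed) — sizes chosen so typical p-values
sit inside the permutation-resolvable range, since the ordering of two
p-values is undefined once both hit the permutation floor; and
asymptotic-vs-permutation agreement on 200 null genes.

## Model selection

The greedy search is bidirectional stepwise (add or drop one term per
step) from the base model of intercept + PCs, minimizing
BIC = n ln(RSS/n) + k ln(n) with k counting every free coefficient; PCs
are never dropped. Singletons are excluded from candidacy — a single
carrier supports no inference. Moves that would make the design singular
are skipped, and exact BIC ties break by genomic position then variant id,
so the result is invariant to candidate-column order. Under the null the
probability that the search stays empty is (1−P(χ²₁ > ln n))^m; the test
suite checks the observed empty rate against that analytic value rather
than a round number. Variance-explained accounting partials the PCs out of
the phenotype and every genotype column, then reports 100·R² for the
array SNP alone and for the array SNP plus the selected variants (nested,
so the latter is never smaller).

## Multiplicity

Single-variant and gene-level p-values pool into one family. The default
operating rule is the fixed threshold p < 0.001 (approximately FDR 0.02 on
a ~2,000-test inventory); Benjamini–Hochberg step-up and Bonferroni
cutoffs are computed explicitly and the step-up rule is cross-checked
against an exhaustive all-candidate-cutoffs implementation and
statsmodels.

## What the synthetic checks do not show

Generated sites are independent given the planted LD pairs, so the
pipeline's behaviour under realistic local LD (proxy signals, haplotype
effects) is only probed through the single planted-correlation regime.
Phenotypes are Gaussian on their analysis scale with exactly the modelled
covariates; robustness to model misspecification (skewed residuals beyond
the log traits, unmodelled covariates) is only addressed via the
inverse-normal option. Center errors are independent and unstructured,
unlike real caller errors which correlate with depth and context. Passing
calibration here therefore demonstrates correctness of the statistical
machinery under its stated assumptions, not performance guarantees on any
particular real dataset.
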