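# Methods

This note documents the statistical procedures implemented in `adaptprs`,
the choices made where the design was genuinely open, what the synthetic
cohort generator does and does not emulate, and the known limitations.

## The analysis

The pipeline asks whether the polygenic architecture of a trait tracks the
local environment across a structured cohort sampled at discrete sites.

**QC.** Variants and individuals pass a fixed-order chain: per-variant
missingness ≤ 5%, per-individual missingness ≤ 5%, MAF ≥ 1%, exact
Hardy-Weinberg test p > 10⁻⁴. Each step operates on the survivors of the
previous one, so the per-step removal counts in the QC report are
reproducible. The HWE test is the exact conditional test (two-sided by
probability mass, computed by the stable mid-out recurrence), not a
chi-square approximation: near the 10⁻⁴ cutoff with modest counts the
approximation is unreliable. HWE is tested on the pooled cohort; in a
structured sample the Wahlund effect makes this conservative toward
removing variants with excess homozygosity, which is flagged in the report.

**LD.** All LD statistics are composite r² on unphased dosages — the squared
Pearson correlation over pairwise-complete observations (no phasing stage
exists in this pipeline). Pruning for PCA is a greedy sliding window
(50 variants, step 5): scanning pairs in position order, the member of any
pair with r² ≥ 0.2 with the smaller MAF is dropped (tie: larger position).
The drop rule and scan order are not canonical across tools; they were fixed
for determinism and verified against a windowless brute-force reference.

**PCA.** Missing dosages are mean-imputed per variant; variants are centred
at 2p̂ and scaled by √(2p̂(1−p̂)) (Patterson normalization). Scores are the
top-K left singular vectors scaled by singular values, with the sign fixed
so the largest-magnitude variant loading is positive — an arbitrary but
deterministic convention so repeated runs give identical regressions.

**C+T scores.** Summary statistics are first harmonized: variants matched on
ID and allele pair, betas negated when the effect allele is the panel's ref
allele, mismatching allele pairs dropped, A/T–C/G pairs optionally dropped.
The MHC (chromosome 6, 26–34 Mb by default; the bounds are configurable
because they are build-dependent) is excluded for its long-range LD.
Clumping is greedy by ascending GWAS p (ties broken by chromosome then
position, for determinism): each index variant removes unprocessed variants
within ±250 kb with r² ≥ 0.3 against it in the target panel. The "500-kb
window" is read as a ±250-kb radius. Clumping runs once on all variants;
the twelve thresholds (5×10⁻⁸ … 1) then select index variants by GWAS p.
Scores are raw beta-weighted dosage sums with missing dosages imputed at
2p̂. A score averaged over non-missing alleles differs only by a per-column
affine map, and the association z is invariant to affine maps of the score
(asserted in the tests), so the sum was chosen as the simplest to verify by
hand.

**Association.** Each environmental variable is Box-Cox transformed
(shift 1−min when nonpositive values occur; λ maximizing the profile
log-likelihood by golden-section search on [−5, 5] to 10⁻⁵; |λ| < 10⁻⁸
treated as the log transform), broadcast from sites to individuals, and
regressed on [intercept, PRS, PCs] by OLS. Reported per cell: the PRS
t-statistic (z), two-sided p, and incremental R² over the covariates-only
model. The column is named `r2_incremental`; the analogous quantity in the
PRS literature is often labeled Nagelkerke's R², which strictly applies to
likelihood-based models — the linear-model difference in R² is what is
computed here. BH q-values are computed either over all grid cells
(default) or over the per-pair best cells only; the scope changes q, never
p, and is recorded in the output.

**Permutation null.** For a significant cell the score vector is permuted
across individuals (environment and PCs fixed), B = 10,000 times by
default, and the PRS z refitted each time via Frisch-Waugh-Lovell
residualisation (algebraically identical to the full OLS t-statistic;
cross-checked in the tests). perm_p uses the add-one estimator
(1 + #{|z_b| ≥ |z_obs|})/(B + 1), with a relative tolerance of 10⁻⁹ in the
comparison so permutations tied with the observed statistic in exact
arithmetic count as ties.

**10-vs-20-PC comparison.** The PRS coefficients from the two nested
covariate sets are compared with a Clogg-type statistic
(β_small − β_large)/√(|se_large² − se_small²| + ε), ε = 10⁻¹², referred to
the standard normal. The statistic for comparing nested-model coefficients
is not uniquely standard; this choice is documented rather than claimed
canonical.

**Driver analysis.** Within a user-named set of correlated variables, each
candidate is refitted with the remaining members as extra covariates; the
driver is the candidate whose PRS term keeps p < 0.05. Near-collinear
candidate sets (condition number > 10⁸ after standardization) are rejected
with the condition number reported.

**Enrichment.** Variants contributing to a significant cell are kept when
their own regression (transformed environment on dosage + PCs, in the
target cohort) is nominally significant with direction concordant with the
cell (sign(β_snp · β_gwas) = sign(z)). Whether "per-SNP significance"
should be assessed in the target cohort or the training GWAS is ambiguous;
the target cohort is used, consistent with how the selected variants are
interpreted (as carriers of the local signal). Selected SNPs map to genes
by eQTL links; each term is tested with an upper-tail hypergeometric test
in the universe of eQTL-linked genes, BH-corrected across terms. The
empirical null draws, per input SNP and null set, a background SNP matched
on MAF (±5 percentage points — the frequency-scale convention), gene
density within ±100 kb (±50% relative), distance to nearest gene (±50%
relative, 5-kb absolute slack at zero) and LD buddies at r² ≥ 0.3 within
±250 kb (±50% relative, absolute slack 1 at zero), sampling uniformly
without replacement within a set; if a set exhausts a SNP's candidate list
the list is reused, and a `relax` switch doubles all tolerances once. The
±100-kb density and ±250-kb buddy windows are fixed stand-ins for
LD-defined locus boundaries, configurable per run. Empirical p for the
observed count of significant terms again uses the add-one estimator.

**NOIA.** The statistical (genotype-frequency) formulation: with observed
genotype frequencies (f₀, f₁, f₂) at a locus, the additive column is
g − (f₁ + 2f₂) and the dominance column takes values (−2f₁f₂, 4f₀f₂,
−2f₀f₁)/D with D = f₀ + f₂ − (f₀ − f₂)². These columns are orthogonal to
the intercept and to each other under the observed frequencies (an exact
algebraic identity, property-tested over random frequency triples).
Multi-locus epistatic columns are element-wise products (up to 3 loci;
the small scores this stage targets have ≤ 3 variants). Frequencies are
computed on the individuals remaining after dropping anyone missing a
modeled locus. D = 0 omits the dominance column with a warning;
monomorphic loci are errors. PCs are included as covariates by default,
consistent with the main analysis, and can be switched off.

## The synthetic cohort generator

`simdata` emulates the statistical structure the analysis assumes:

- **Structure**: per-variant ancestral frequency p₀ ~ U(0.05, 0.95); deme
  frequencies Balding-Nichols Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) with F = 0.01
  by default (weak, continental-scale differentiation), 23 demes × 100
  diploids.
- **LD**: a latent Gaussian copula per block (25 variants, AR(1)
  correlation 0.8), thresholded per haplotype, so marginal dosages are
  Binomial(2, p_k) with controllable within-block r² and ~zero
  between-block r². Chosen over coalescent simulation for desk-scale speed
  and direct control of the r² that clumping and pruning see.
- **Selection**: for causal variant j and deme k, p_k shifts by s·β_j·z_k
  (clipped to [0.01, 0.99]), z_k the standardized driver value. With the
  default effect scale 0.05 and s = 0.5, the mean shift is ≈ 0.02 per SD of
  environment. This generative model of local adaptation is a synthetic
  convenience, not a claim about any real population.
- **GWAS**: an idealized external training study — se = 1/√(2n·p₀(1−p₀)),
  β̂ = β + N(0, se), Wald p; a 5% fraction of rows has swapped allele labels
  (beta negated) to force the harmonization stage. Strand flips are not
  simulated (alleles are abstract labels).
- **Environment**: site-level draws from a multivariate normal with a
  specified inter-variable correlation (default: two temperature variables
  at 0.75, precipitation at 0.3 to both, two independent variables),
  rescaled to plausible marginal units.
- **Annotation**: non-overlapping 30-kb genes at a 50-kb pitch; 1–2 eQTL
  links per SNP within ±100 kb; one planted term attached to
  causal-variant genes with probability 0.6 versus 0.05 for background
  genes.
- **Missingness** is completely at random (1%); HWE-violating variants
  (excess heterozygosity) can be injected for the QC filter to catch.

Not emulated: migration/admixture/bottlenecks, phased haplotypes, sex
chromosomes, allele-frequency-dependent effect sizes, realistic gene/term
size distributions, and any spatial smoothness of the demes (demes are
exchangeable). Consequently, passing tests demonstrate the statistical
machinery is correct under its stated assumptions — not that real data meet
those assumptions.

## Calibration and the analysis level

The environment is constant within a site, so the individual-level
regression's errors are perfectly correlated within sites. The test is
still valid if the ancestry covariates absorb all between-deme variance of
the score; with 23 *exchangeable* Balding-Nichols demes the between-deme
space has 22 equal-magnitude axes, and 10 PCs necessarily leave about half
of the score's drift variance unabsorbed, inflating the individual-level
test (empirically, rejection at nominal 0.05 is roughly 0.14 under the
global null at the default conditions). Real continental cohorts
concentrate structure on few axes, which is why a 10-PC adjustment is
defensible there; the exchangeable-deme null is the harder case. The
validation experiments therefore run the association grid in the
site-level aggregation mode (scores and PCs averaged per site; one
observation per site), which is exactly calibrated conditional on the
cohort: under the null the environment is independent, site-level errors
are independent across sites, and the OLS t is exact. The individual-level
mode remains the default because it reproduces the source design; its
inflation is a documented property, and the permutation comparison (which
shares the individual-level assumptions) is run in that mode.

## Validation experiments (`adaptprs.validation`)

Problem sizes were chosen to exercise the reference conditions while
keeping each experiment in the minutes range on one CPU:

- **Null calibration**: one cohort at 23×100, 20,000 variants, three
  traits; ten independent environment redraws (valid because environment ⊥
  genotypes under the null) give 1,800 site-level grid cells for the
  rejection rate. The KS uniformity check uses one cell per trait-variable
  pair per replicate (rotating through the twelve thresholds) because
  cells within a pair are strongly dependent across thresholds and a KS
  test on dependent draws is anti-conservative. The permutation-versus-
  parametric rank correlation uses B = 1,000 on the 180 individual-level
  cells of one replicate.
- **Power**: twenty replicates at 23×40, 3,000 variants, s = 0.5 (the
  ~0.02-per-SD shift), grid over the driver and one independent variable,
  BH over all cells; success is the driver's best cell at q < 0.05 with
  the planted sign.
- **Enrichment**: 15×40 cohort, 6,000 variants; planted and unplanted
  annotation arms with 100 matched sets each.
- **NOIA**: 1,000 random frequency triples for the orthogonality
  identities; exact-HWE genotype counts (100/200/100) for the
  dosage-slope equivalence.
- **Determinism**: a small full pipeline run twice, compared byte by byte.

## Numerical choices

- OLS via pivoted QR; rank deficiency raises with the names of the
  pivoted-out columns and the design condition number.
- Pairwise-complete r² computed by mask algebra (counts, masked sums and
  squares) so windows vectorize; pairs with < 3 complete observations or
  zero variance define r² = 0 (flagged).
- HWE het-count distribution by two-sided cumulative-product recurrence
  from the mode; tail underflow to zero is harmless. Tie inclusion uses a
  10⁻⁹ relative margin so exact rational ties survive floating point.
- Box-Cox λ snapped to 0 below 10⁻⁸; golden-section tolerance 10⁻⁵.
- Exact Spearman p (full permutation enumeration) only for n ≤ 9 sites;
  t-approximation otherwise.
- LD-buddy counts use mean-imputed standardized correlations (not
  pairwise-complete) for speed; query and background use the same routine,
  so matching compares like with like.

## Limitations

- No mixed-model or cluster-robust alternative to the site-level
  aggregation; aggregation discards within-site information by design.
- The enrichment stage has no term-hierarchy semantics (terms are flat
  labels); real ontology DAG propagation is out of scope.
- Clumping uses the target panel's LD only, as C+T tools do; no external
  LD reference is supported.
- The pipeline assumes training and target cohorts share ancestry; no
  cross-ancestry portability correction is attempted.
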