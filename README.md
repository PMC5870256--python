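# adaptprs

Polygenic-score tests of local adaptation: do the genetic scores of complex
traits track the environments populations live in?

`adaptprs` is a Python library (plus a thin CLI) for a complete
population-genetic analysis: build clumping+thresholding (C+T) polygenic
risk scores from external GWAS summary statistics, regress site-level
environmental variables on those scores with ancestry-PC adjustment across a
structured cohort, control the false discovery rate over the full
trait × variable × threshold grid, and validate every signal three ways —
permutation nulls, matched-SNP-set enrichment nulls, and orthogonal
additive/epistasis (NOIA) modeling. A first-class synthetic-data module
generates structured cohorts with planted clinal selection so the whole
stack is testable end to end with no external downloads.

## The model

For trait *t* and inclusion threshold *P_T*, each individual *i* gets the
C+T score

```
PRS_i(t, P_T) = Σ_{j ∈ C(P_T)} β̂_j · d_ij
```

where `C(P_T)` are the LD-clumped index variants with GWAS p ≤ P_T
(clumping at r² = 0.3 within a 500-kb window, MHC excluded; twelve
thresholds from 5×10⁻⁸ to 1), `β̂_j` the harmonized GWAS effect sizes and
`d_ij` the alt-allele dosage (missing values imputed at 2p̂_j). Each
environmental variable *y* (a property of the sampling site, broadcast to
its individuals) is Box-Cox normalized and fitted by OLS:

```
y = α + γ · PRS(t, P_T) + Σ_k δ_k PC_k + ε
```

The reported Z is the t-statistic of γ, with incremental R² over the
covariates-only model; q-values are Benjamini-Hochberg over the grid.
Significant cells are validated by permuting the score across individuals
(10,000 permutations by default), compared between 10- and 20-PC models
(Clogg-type coefficient test), and dissected among correlated variables by
conditioning each candidate on the others ("driver analysis"). Variants
individually supporting a significant score (nominally significant,
direction-concordant) are mapped to genes via eQTL links and tested per
annotation term with an upper-tail hypergeometric test; the significant-term
count is calibrated against 100 background SNP sets matched on MAF (±5
points), gene density (±50%), distance to nearest gene (±50%) and LD-buddy
count (±50%). Single-locus and oligogenic signals are re-modeled with the
statistical NOIA parameterization, whose additive/dominance columns are
orthogonal under the observed genotype frequencies.

## Worked example

```python
from adaptprs import (SimConfig, SummaryStats, add_q, build_prs,
                      compute_pcs, ld_prune, qc_filter, run_grid,
                      simulate_all)

cfg = SimConfig(n_populations=12, n_per_pop=40, n_variants=2500,
                n_chromosomes=6, n_causal=100, selection_gradient=0.5, seed=5)
out = simulate_all(cfg)                       # cohort + GWAS + environment
g, _ = qc_filter(out.genotypes)               # missingness, MAF, exact HWE
pcs = compute_pcs(g, ld_prune(g), K=10)       # ancestry PCs, Patterson scaling
tab = out.sumstats["trait1"]
ss = SummaryStats(tab[["id", "chrom", "pos", "effect_allele",
                       "other_allele", "beta", "p"]], trait="trait1")
prs, _, _ = build_prs(ss, g)                  # harmonize -> clump -> score
grid = add_q(run_grid({"trait1": prs}, out.environment, g.samples, pcs))
print(grid[grid["best"]][["variable", "pt", "n_snps", "z", "p", "q"]])
```

prints (the planted driver is `win_min_temp`; `win_max_temp` is its
correlated proxy):

```
     variable      pt  n_snps         z            p            q
 win_min_temp 0.10000     305 14.922429 1.808697e-41 1.085218e-39
 win_max_temp 0.50000    1198 11.295445 2.501294e-26 1.154443e-25
       precip 0.00001      47  4.070255 5.512551e-05 8.535522e-05
 pathogen_div 0.50000    1198 -4.166271 3.688079e-05 6.146798e-05
phoneme_count 0.05000     185 -5.366711 1.264100e-07 3.033840e-07
```

The planted selection gradient couples the trait's causal-variant
frequencies to winter minimum temperature: its best cell carries by far the
largest Z, with the planted positive sign, and the correlated proxy
(`win_max_temp`, generating correlation 0.75) inherits the next-strongest
signal. The remaining variables are truly unrelated to the trait, yet still
reach nominal significance: an individual-level regression of a
site-broadcast variable has errors that are perfectly correlated within
sites, so any residual between-deme structure in the score inflates Z. This
pseudo-replication is inherent to the site-broadcast design the pipeline
reproduces; `run_grid(..., site_level=True)` averages scores and components
per site and gives calibrated inference (at the cost of site-level degrees
of freedom — it needs more sites than covariates). The permutation and
matched-set nulls in the later stages are the within-design guards.
See `examples/` for one short
script per capability (simulation, QC+PCA, scoring, the association grid
with permutation and driver analysis, enrichment with matched-set nulls,
NOIA, and the one-call pipeline), and `docs/methods.md` for the statistical
details and caveats.

## Command line

```bash
adaptprs template > cfg.yaml       # annotated config template
adaptprs all --config cfg.yaml     # simulate/load -> qc -> pca -> prs ->
                                   # assoc -> permute -> enrich -> noia
```

Each stage is also a subcommand (`adaptprs qc ...`, `adaptprs assoc ...`);
stages are deterministic in the config and seed, so outputs are
byte-identical across reruns.

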