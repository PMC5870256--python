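"""Clumping + thresholding polygenic scores from GWAS summary statistics.

Harmonizes simulated summary statistics to the target panel (undoing
swapped allele labels), clumps by ascending GWAS p at r2 = 0.3 within
500 kb, and scores every individual at the twelve inclusion thresholds.
"""

from adaptprs import SimConfig, SummaryStats, build_prs, qc_filter, simulate_all

cfg = SimConfig(n_populations=8, n_per_pop=40, n_variants=2000,
                n_chromosomes=6, n_causal=80, swap_fraction=0.1, seed=11)
out = simulate_all(cfg)
g, _ = qc_filter(out.genotypes)

tab = out.sumstats["trait1"]
ss = SummaryStats(tab[["id", "chrom", "pos", "effect_allele", "other_allele",
                       "beta", "p"]], trait="trait1")
prs, clump_result, indexed = build_prs(ss, g)

print(f"clumping: {len(clump_result.index_ids)} index variants "
      f"({sum(len(v) for v in clump_result.clumped.values())} clumped away)")
print("\nvariants contributing per threshold:")
for pt, n in zip(prs.thresholds, prs.n_snps):
    print(f"  PT <= {pt:<8g} n_snps = {n}")
print("\nscore matrix:", prs.scores.shape,
      "(individuals x thresholds; raw beta-weighted dosage sums,")
print(" missing genotypes imputed at twice the panel allele frequency)")
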