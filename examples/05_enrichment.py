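"""eQTL-mediated term enrichment with a matched-SNP-set empirical null.

Selects the direction-concordant variants behind a significant score,
maps them to genes through eQTL links, tests each annotation term
hypergeometrically, and calibrates the significant-term count against 100
background SNP sets matched on MAF, gene density, distance to nearest
gene and LD-buddy count.
"""

import numpy as np

from adaptprs import (SimConfig, SummaryStats, add_q, boxcox_transform,
                      broadcast_env, build_prs, compute_pcs,
                      empirical_enrichment_null, hypergeom_enrich, ld_prune,
                      match_snps, qc_filter, run_grid, select_prs_snps,
                      simulate_all, snp_properties, snps_to_genes)

cfg = SimConfig(n_populations=12, n_per_pop=40, n_variants=4000,
                n_chromosomes=8, n_causal=120, selection_gradient=0.5, seed=9)
out = simulate_all(cfg)
g, _ = qc_filter(out.genotypes)
pcs = compute_pcs(g, ld_prune(g), K=10)
tab = out.sumstats["trait1"]
ss = SummaryStats(tab[["id", "chrom", "pos", "effect_allele", "other_allele",
                       "beta", "p"]], trait="trait1")
prs, _, indexed = build_prs(ss, g)

grid = add_q(run_grid({"trait1": prs}, out.environment, g.samples, pcs,
                      variables=[cfg.driver_variable]))
cell = grid[grid["best"]].iloc[0]
print(f"significant cell: PT={cell['pt']:g} z={cell['z']:.2f} q={cell['q']:.2g}")

y = boxcox_transform(broadcast_env(out.environment, g.samples,
                                   cfg.driver_variable))[1]
snpset = select_prs_snps(g, indexed, cell["pt"], np.sign(cell["z"]), y, pcs)
print(f"selected {len(snpset.snps)} direction-concordant variants")

obs = hypergeom_enrich(snps_to_genes(snpset.snps, out.annotation),
                       out.annotation)
sig = obs.significant_terms()
print(f"significant terms at q < 0.05: {sig} "
      f"(planted term: {out.truth.planted_term})")

background = snp_properties(g, out.annotation)
snpset.properties = background[background["snp"].isin(snpset.snps)]
matched = match_snps(snpset, background, n_sets=100, seed=2, relax=True)
matched_results = [hypergeom_enrich(snps_to_genes(s.snps, out.annotation),
                                    out.annotation) for s in matched]
null = empirical_enrichment_null(obs, matched_results)
print(f"matched-set null: {null['count_obs']} observed significant terms vs "
      f"max {null['null_counts'].max()} in 100 matched sets "
      f"-> empirical p = {null['empirical_p']:.4g}")
print("(a small empirical p says the enrichment is not explained by the "
      "variants' MAF/gene-density/LD profile alone)")
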