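"""Simulation experiments validating the statistical behaviour of the
pipeline: type-I-error calibration under the global null, power to recover a
planted selection gradient, behaviour of the matched-set enrichment null,
and the NOIA algebra.

These are the experiments a methods paper would run before trusting the
pipeline on real data; they are deterministic functions of a seed and are
exercised both by the test suite and by ``scripts/acceptance.py``.

Analysis mode. The environment is a property of the sampling site, so an
individual-level regression of a site-broadcast variable has clustered
errors; with an exchangeable-deme Balding-Nichols cohort the ancestry PCs
cannot fully absorb the score's between-deme drift variance and the
individual-level test is anti-conservative (that pseudo-replication is a
property of the source design, which the pipeline preserves as its default).
The calibration and power experiments therefore use the site-level
aggregation mode, which is the inferentially calibrated analysis for
site-resolved environments; the permutation-versus-parametric comparison
runs at the individual level, where the permutation scheme lives.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from . import assoc, enrich, noia, popstruct, prs, qc, simdata

#: reference global-null study conditions: 23 demes x 100 diploids,
#: 20,000 variants, three traits scored against five environmental variables
NULL_CONDITIONS = dict(n_populations=23, n_per_pop=100, n_variants=20_000,
                       n_traits=3, n_causal=200, selection_gradient=0.0)

#: scaled-down power-study conditions; selection_gradient 0.5 with effect
#: scale 0.05 gives per-causal-variant frequency shifts of ~0.02 per SD of
#: the driver variable (0.5 * E|beta| with E|beta| = 0.05 * sqrt(2/pi))
POWER_CONDITIONS = dict(n_populations=23, n_per_pop=40, n_variants=3_000,
                        n_chromosomes=10, n_traits=1, n_causal=150,
                        h2_like_effect_scale=0.05, selection_gradient=0.5)

#: enrichment-study conditions: moderate cohort with a rich annotation so
#: matched sets draw from a large property-matched background
ENRICH_CONDITIONS = dict(n_populations=15, n_per_pop=40, n_variants=6_000,
                         n_chromosomes=10, n_traits=1, n_causal=150,
                         h2_like_effect_scale=0.05, selection_gradient=0.5)


def _build_cohort(sim_cfg: simdata.SimConfig, pc_count: int = 10):
    """simulate -> QC -> prune -> PCs -> C+T scores for every trait."""
    out = simdata.simulate_all(sim_cfg)
    g, _ = qc.qc_filter(out.genotypes)
    pruned = qc.ld_prune(g)
    pcs = popstruct.compute_pcs(g, pruned, pc_count)
    prs_by, indexed = {}, {}
    for name, tab in out.sumstats.items():
        ss = prs.SummaryStats(
            tab[["id", "chrom", "pos", "effect_allele", "other_allele",
                 "beta", "p"]], trait=name)
        prs_by[name], _, indexed[name] = prs.build_prs(ss, g)
    return out, g, pcs, prs_by, indexed


# ---------------------------------------------------------------- calibration

def null_calibration(seed: int = 0, n_env_replicates: int = 10,
                     B: int = 1_000, conditions: dict | None = None) -> dict:
    """Type-I-error calibration under the global null (no selection).

    One cohort is simulated at the reference conditions; because the
    environment is independent of the genotypes under the null, independent
    environment redraws give independent null replicates of the full
    trait x variable x threshold grid without re-simulating genotypes.

    Returns the empirical rejection rate at alpha = 0.05 over all cells and
    replicates (site-level analysis), a Kolmogorov-Smirnov uniformity p on a
    decorrelated cell subset (one threshold per trait-variable pair per
    replicate, rotating through the twelve thresholds), and the Spearman
    rank correlation between permutation and parametric p-values across the
    individual-level grid of the first replicate.
    """
    cfg = simdata.SimConfig(**{**NULL_CONDITIONS, **(conditions or {}),
                               "seed": seed})
    out, g, pcs, prs_by, _ = _build_cohort(cfg)

    all_p = []
    subset_p = []
    for rep in range(n_env_replicates):
        rng = np.random.default_rng(seed + 1000 + rep)
        env = simdata.simulate_environment(cfg, rng)
        grid = assoc.run_grid(prs_by, env, g.samples, pcs, site_level=True)
        all_p.append(grid["p"].to_numpy())
        # one cell per trait-variable pair, threshold rotating by replicate
        pt_index = rep % 12
        sub = grid.groupby(["trait", "variable"], sort=False).nth(pt_index)
        subset_p.append(sub["p"].to_numpy())
    all_p = np.concatenate(all_p)
    subset_p = np.concatenate(subset_p)

    # permutation vs parametric comparison at the individual level
    rng = np.random.default_rng(seed + 1000)
    env0 = simdata.simulate_environment(cfg, rng)
    grid_ind = assoc.run_grid(prs_by, env0, g.samples, pcs, site_level=False)
    perm_p = np.empty(len(grid_ind))
    for variable, sub in grid_ind.groupby("variable", sort=False):
        y = assoc.boxcox_transform(
            assoc.broadcast_env(env0, g.samples, variable))[1]
        for ridx, row in sub.iterrows():
            x = prs_by[row["trait"]].column(row["pt"])
            perm_p[ridx] = assoc.permutation_null(
                x, y, pcs, B=B, seed=seed + 7 + ridx).perm_p

    return {
        "rejection_rate_alpha05": float((all_p < 0.05).mean()),
        "n_cells": int(all_p.size),
        "ks_uniform_p": float(stats.kstest(subset_p, "uniform").pvalue),
        "n_ks_cells": int(subset_p.size),
        "perm_parametric_rank_corr": float(
            stats.spearmanr(grid_ind["p"], perm_p).statistic),
        "n_perm_cells": int(len(grid_ind)),
    }


# ---------------------------------------------------------------- power

def power_analysis(seed: int = 0, n_replicates: int = 20,
                   conditions: dict | None = None) -> dict:
    """Recovery of a planted clinal-selection signal, scaled down.

    Each replicate simulates a fresh cohort with selection coupling the
    trait's causal variants to the driver variable, runs the C+T scoring and
    the site-level association grid over the driver and an independent null
    variable, and applies BH FDR over all cells. Success: the driver's
    best cell reaches q < 0.05 with the planted (positive) sign. The null
    variable's q < 0.05 rate measures false-positive leakage.
    """
    driver_hits, null_hits = 0, 0
    for rep in range(n_replicates):
        cfg = simdata.SimConfig(**{**POWER_CONDITIONS, **(conditions or {}),
                                   "seed": seed + 5000 + rep})
        out, g, pcs, prs_by, _ = _build_cohort(cfg)
        grid = assoc.run_grid(prs_by, out.environment, g.samples, pcs,
                              variables=[cfg.driver_variable, "pathogen_div"],
                              site_level=True)
        grid = assoc.add_q(grid, scope="all_cells")
        best = grid[grid["best"]].set_index("variable")
        drv = best.loc[cfg.driver_variable]
        driver_hits += bool(drv["q"] < 0.05 and drv["z"] > 0)
        null_hits += bool(best.loc["pathogen_div", "q"] < 0.05)
    return {
        "driver_recovery_rate": driver_hits / n_replicates,
        "null_variable_fdr_rate": null_hits / n_replicates,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------- enrichment

def enrichment_experiment(seed: int = 0, planted: bool = True,
                          n_matched_sets: int = 100,
                          conditions: dict | None = None) -> dict:
    """Matched-SNP-set empirical null for the eQTL-term enrichment.

    Builds a cohort with planted selection, selects the direction-concordant
    variants of the driver's best significant score, runs the hypergeometric
    enrichment, and compares against ``n_matched_sets`` property-matched
    background sets. With ``planted=True`` the annotation carries a term
    preferentially attached to causal-variant genes; with ``planted=False``
    the annotation is exchangeable and matched-set counts describe the null.
    """
    cfg = simdata.SimConfig(**{**ENRICH_CONDITIONS, **(conditions or {}),
                               "plant_enriched_term": planted,
                               "seed": seed + 9000})
    out, g, pcs, prs_by, indexed = _build_cohort(cfg)
    trait = out.truth.trait_names[0]
    grid = assoc.run_grid(prs_by, out.environment, g.samples, pcs,
                          variables=[cfg.driver_variable], site_level=True)
    grid = assoc.add_q(grid, scope="all_cells")
    cell = grid[grid["best"]].iloc[0]
    y = assoc.boxcox_transform(assoc.broadcast_env(
        out.environment, g.samples, cfg.driver_variable))[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        snpset = enrich.select_prs_snps(g, indexed[trait], cell["pt"],
                                        np.sign(cell["z"]), y, pcs)
    background = enrich.snp_properties(g, out.annotation)
    snpset.properties = background[background["snp"].isin(snpset.snps)]
    obs = enrich.hypergeom_enrich(
        enrich.snps_to_genes(snpset.snps, out.annotation), out.annotation)
    matched = enrich.match_snps(snpset, background, n_sets=n_matched_sets,
                                seed=seed + 9001, relax=True)
    matched_results = [
        enrich.hypergeom_enrich(
            enrich.snps_to_genes(s.snps, out.annotation), out.annotation)
        for s in matched]
    null = enrich.empirical_enrichment_null(obs, matched_results)
    counts = null["null_counts"]
    return {
        "cell_q": float(cell["q"]),
        "n_selected_snps": len(snpset.snps),
        "observed_significant_terms": null["count_obs"],
        "empirical_p": null["empirical_p"],
        "matched_sets_ge3_rate": float(np.mean(counts >= 3)),
        "n_matched_sets": n_matched_sets,
    }


# ---------------------------------------------------------------- NOIA

def noia_validation(seed: int = 0, n_triples: int = 1_000) -> dict:
    """NOIA algebra checks: frequency-weighted orthogonality of the
    additive/dominance columns over random genotype-frequency triples,
    exact recovery of a pure additive phenotype, and agreement of the NOIA
    additive slope with plain dosage regression under exact
    Hardy-Weinberg genotype counts."""
    rng = np.random.default_rng(seed + 11_000)
    worst = 0.0
    for _ in range(n_triples):
        f = rng.dirichlet([1.0, 1.0, 1.0])
        if f.min() < 1e-3:
            continue
        gvals = np.array([0.0, 1.0, 2.0])
        x_a = gvals - (f[1] + 2 * f[2])
        D = f[0] + f[2] - (f[0] - f[2]) ** 2
        x_d = np.array([-2 * f[1] * f[2], 4 * f[0] * f[2], -2 * f[0] * f[1]]) / D
        worst = max(worst, abs(f @ x_a), abs(f @ x_d), abs(f @ (x_a * x_d)))

    # pure additive phenotype: alpha recovered exactly, dominance zero
    g = np.repeat([0.0, 1.0, 2.0], [90, 180, 130])
    y = 0.7 * g
    fit = noia.fit_noia(noia.build_design(g), y)
    est = fit.estimates.set_index("EFFECT")["ESTIMATE"]
    additive_err = abs(est["a_locus1"] - 0.7) + abs(est["d_locus1"])

    # exact HWE counts: p = 0.5, n = 400 -> 100/200/100
    g_hwe = np.repeat([0.0, 1.0, 2.0], [100, 200, 100])
    y_hwe = 0.4 * g_hwe + rng.standard_normal(400)
    fit_hwe = noia.fit_noia(noia.build_design(g_hwe), y_hwe)
    alpha = fit_hwe.estimates.set_index("EFFECT")["ESTIMATE"]["a_locus1"]
    X = np.column_stack([np.ones(400), g_hwe])
    slope = np.linalg.lstsq(X, y_hwe, rcond=None)[0][1]
    return {
        "orthogonality_max_abs": float(worst),
        "pure_additive_recovery_err": float(additive_err),
        "hwe_additive_vs_dosage_slope_diff": float(abs(alpha - slope)),
    }


# ---------------------------------------------------------------- determinism

def determinism_check(seed: int = 0) -> dict:
    """Full-pipeline byte-level determinism plus the z-invariance
    properties (allele relabeling; affine rescaling of the score)."""
    import filecmp
    import tempfile
    from pathlib import Path

    from .genio import GenotypeMatrix
    from .pipeline import RunConfig, run_all

    sim = dict(n_populations=6, n_per_pop=20, n_variants=600,
               n_chromosomes=3, n_causal=40, selection_gradient=0.5)
    with tempfile.TemporaryDirectory() as tmp:
        identical = True
        for sub in ("a", "b"):
            cfg = RunConfig(outdir=str(Path(tmp) / sub), seed=seed + 3,
                            sim=dict(sim), permutations=50, n_matched_sets=10)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                run_all(cfg)
        fa = sorted(p.name for p in (Path(tmp) / "a").iterdir())
        fb = sorted(p.name for p in (Path(tmp) / "b").iterdir())
        identical = fa == fb and all(
            filecmp.cmp(Path(tmp) / "a" / f, Path(tmp) / "b" / f,
                        shallow=False) for f in fa)

    cfg = simdata.SimConfig(n_populations=5, n_per_pop=30, n_variants=400,
                            n_chromosomes=2, n_causal=30, seed=seed + 4)
    out = simdata.simulate_all(cfg)
    g = out.genotypes
    tab = out.sumstats["trait1"]
    ss = prs.SummaryStats(tab[["id", "chrom", "pos", "effect_allele",
                               "other_allele", "beta", "p"]], trait="t")
    p1, _, _ = prs.build_prs(ss, g, mhc=None)
    flip = np.arange(0, g.n_variants, 2)
    d2 = g.dosages.copy()
    d2[:, flip] = 2.0 - d2[:, flip]
    v2 = g.variants.copy()
    v2.loc[flip, ["ref", "alt"]] = v2.loc[flip, ["alt", "ref"]].to_numpy()
    g2 = GenotypeMatrix(d2, v2, g.samples.copy())
    p2, _, _ = prs.build_prs(ss, g2, mhc=None)
    rng = np.random.default_rng(seed + 5)
    yv = rng.standard_normal(g.n_samples)
    z1 = assoc.fit_prs_env(p1.scores[:, 9], yv).z
    z2 = assoc.fit_prs_env(p2.scores[:, 9], yv).z
    z3 = assoc.fit_prs_env(2.5 * p1.scores[:, 9] + 3.0, yv).z
    return {
        "pipeline_rerun_identical": bool(identical),
        "relabel_z_abs_diff": float(abs(z1 - z2)),
        "rescale_z_abs_diff": float(abs(z1 - z3)),
    }
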