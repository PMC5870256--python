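"""End-to-end orchestration: simulate/load -> QC -> PCA -> PRS -> association
grid -> FDR -> permutation -> PC robustness -> driver analysis -> enrichment
-> NOIA, with TSV outputs and a JSON manifest per run.

Stages always execute in pipeline order (each is a deterministic function of
the config seed and the inputs), so a single ``run_all`` or a stage-targeted
run reproduce byte-identical outputs. The manifest records the seed, the
config, and SHA-256 hashes of the inputs and outputs; it carries no
timestamps so re-runs are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, enrich, genio, noia, popstruct, prs, qc, simdata

log = logging.getLogger("adaptprs")

STAGES = ("simulate", "qc", "pca", "prs", "assoc", "permute", "enrich", "noia")


@dataclass
class RunConfig:
    outdir: str = "adaptprs_out"
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)
    genotypes: str | None = None
    genotype_format: str = "auto"
    sample_map: str | None = None
    sumstats: dict = field(default_factory=dict)   # trait -> path
    environment: str | None = None
    annotation_prefix: str | None = None
    qc: dict = field(default_factory=dict)
    prune: dict = field(default_factory=dict)
    pc_count: int = 10
    pc_count_check: int = 20
    clump: dict = field(default_factory=dict)
    thresholds: list = field(default_factory=lambda: list(prs.PT_THRESHOLDS))
    fdr_scope: str = "all_cells"
    q_max: float = 0.05
    permutations: int = 10_000
    n_matched_sets: int = 100
    relax_matching: bool = False
    driver_sets: list = field(default_factory=list)
    noia_max_snps: int = 3

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def template() -> str:  # noqa: N805 - plain helper
        return yaml.safe_dump(asdict(RunConfig()), sort_keys=False)

    def validate_paths(self) -> None:
        if self.simulate:
            return
        needed = [self.genotypes, self.sample_map, self.environment]
        needed += list(self.sumstats.values())
        for p in needed:
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"required input missing: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Pipeline:
    """Stage runner holding the in-memory state of one analysis."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        # outdir is excluded from the manifest so runs into different
        # directories remain byte-identical
        cfg_dict = {k: v for k, v in asdict(config).items() if k != "outdir"}
        self.manifest: dict = {"seed": config.seed, "config": cfg_dict,
                               "inputs": {}, "outputs": {}}
        self.results: dict = {}

    # -------------------------------------------------- helpers

    def _write(self, df: pd.DataFrame, name: str, **kw) -> Path:
        path = self.outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g", **kw)
        self.manifest["outputs"][name] = _sha256(path)
        return path

    def _save_manifest(self) -> None:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))

    # -------------------------------------------------- stages

    def load_inputs(self) -> None:
        cfg = self.config
        cfg.validate_paths()
        if cfg.simulate:
            sim_cfg = simdata.SimConfig(**{"seed": cfg.seed, **cfg.sim})
            log.info("simulating cohort: %d demes x %d, %d variants",
                     sim_cfg.n_populations, sim_cfg.n_per_pop, sim_cfg.n_variants)
            out = simdata.simulate_all(sim_cfg)
            self.sim = out
            self.g = out.genotypes
            self.env = out.environment
            self.annotation = out.annotation
            self.sumstats = {
                t: prs.SummaryStats(tab[["id", "chrom", "pos", "effect_allele",
                                         "other_allele", "beta", "p"]], trait=t)
                for t, tab in out.sumstats.items()}
        else:
            self.sim = None
            sample_map = genio.read_sample_map(cfg.sample_map)
            self.g = genio.read_genotypes(cfg.genotypes, cfg.genotype_format,
                                          sample_map=sample_map)
            self.env = genio.read_environment(cfg.environment)
            self.annotation = (genio.read_annotation(cfg.annotation_prefix)
                               if cfg.annotation_prefix else None)
            self.sumstats = {
                t: prs.SummaryStats(genio.read_sumstats(p), trait=t)
                for t, p in cfg.sumstats.items()}
            for p in [cfg.genotypes, cfg.sample_map, cfg.environment,
                      *cfg.sumstats.values()]:
                self.manifest["inputs"][p] = _sha256(Path(p))

    def stage_simulate(self) -> None:
        self.load_inputs()
        if self.sim is not None:
            genio.write_vcf(self.g, str(self.outdir / "genotypes.vcf"))
            self.manifest["outputs"]["genotypes.vcf"] = _sha256(self.outdir / "genotypes.vcf")
            genio.write_sample_map(self.g.samples, str(self.outdir / "samples.tsv"))
            genio.write_environment(self.env, str(self.outdir / "environment.tsv"))
            for t, tab in self.sim.sumstats.items():
                genio.write_sumstats(tab, str(self.outdir / f"sumstats_{t}.tsv"))
            genio.write_annotation(self.annotation.genes, self.annotation.eqtl,
                                   self.annotation.terms, str(self.outdir / "annotation"))

    def stage_qc(self) -> None:
        self.g_qc, report = qc.qc_filter(self.g, **self.config.qc)
        self.results["qc_report"] = report
        self._write(report.to_frame(), "qc_report.tsv")
        log.info("QC: %d individuals x %d variants retained",
                 self.g_qc.n_samples, self.g_qc.n_variants)
        self.pruned_ids = qc.ld_prune(self.g_qc, **self.config.prune)
        log.info("LD pruning retained %d variants", len(self.pruned_ids))

    def stage_pca(self) -> None:
        kmax = max(self.config.pc_count, self.config.pc_count_check)
        pcs_all = popstruct.compute_pcs(self.g_qc, self.pruned_ids, kmax)
        self.pcs = popstruct.PCMatrix(
            scores=pcs_all.scores[:, :self.config.pc_count],
            explained_variance=pcs_all.explained_variance[:self.config.pc_count],
            K=self.config.pc_count, sample_ids=pcs_all.sample_ids)
        self.pcs_check = pcs_all
        self._write(self.pcs.to_frame(), "pcs.tsv")
        self._write(pd.DataFrame({
            "PC": [f"PC{k+1}" for k in range(kmax)],
            "EXPLAINED_VARIANCE": pcs_all.explained_variance}),
            "explained_variance.tsv")

    def stage_prs(self) -> None:
        self.prs_by_trait = {}
        self.clumps = {}
        self.indexed = {}
        for trait, ss in self.sumstats.items():
            matrix, cr, indexed = prs.build_prs(
                ss, self.g_qc, thresholds=tuple(self.config.thresholds),
                **self.config.clump)
            self.prs_by_trait[trait] = matrix
            self.clumps[trait] = cr
            self.indexed[trait] = indexed
            prs_path = self.outdir / f"prs_{trait}.tsv"
            with open(prs_path, "w") as fh:
                for pt, n in zip(matrix.thresholds, matrix.n_snps):
                    fh.write(f"# n_snps PT_{pt:g} = {n}\n")
                matrix.to_frame().to_csv(fh, sep="\t", index=False,
                                         float_format="%.10g")
            self.manifest["outputs"][prs_path.name] = _sha256(prs_path)
            rep = pd.DataFrame({
                "INDEX_SNP": cr.index_ids,
                "P": indexed.table.set_index("id").loc[cr.index_ids, "p"].to_numpy(),
                "N_CLUMPED": [len(cr.clumped.get(i, [])) for i in cr.index_ids],
                "CLUMPED_IDS": [",".join(cr.clumped.get(i, [])) for i in cr.index_ids],
            })
            self._write(rep, f"clump_{trait}.tsv")
            log.info("PRS %s: %d index variants", trait, len(cr.index_ids))

    def stage_assoc(self) -> None:
        rho, pmat, flags = assoc.spearman_matrix(self.env)
        self._write(rho.reset_index().rename(columns={"index": "VARIABLE"}),
                    "spearman_rho.tsv")
        self._write(pmat.reset_index().rename(columns={"index": "VARIABLE"}),
                    "spearman_p.tsv")
        grid = assoc.run_grid(self.prs_by_trait, self.env, self.g_qc.samples,
                              self.pcs)
        grid = assoc.add_q(grid, scope=self.config.fdr_scope)
        self.grid = grid
        self._write(self._grid_frame(), "grid.tsv")
        n_sig = int((grid["q"] < self.config.q_max).sum())
        log.info("association grid: %d cells, %d with q < %g",
                 len(grid), n_sig, self.config.q_max)

    def _grid_frame(self) -> pd.DataFrame:
        g = self.grid.copy()
        out = pd.DataFrame({
            "TRAIT": g["trait"], "VARIABLE": g["variable"], "PT": g["pt"],
            "SNP_N": g["n_snps"], "R2_INC": g["r2_incremental"], "Z": g["z"],
            "P": g["p"], "Q": g["q"], "BEST_FLAG": g["best"].astype(int),
        })
        if "perm_p" in g:
            out["PERM_P"] = g["perm_p"]
        return out

    def significant_cells(self) -> pd.DataFrame:
        return self.grid[(self.grid["q"] < self.config.q_max)
                         & self.grid["best"]]

    def _cell_inputs(self, row) -> tuple[np.ndarray, np.ndarray]:
        y = assoc.boxcox_transform(
            assoc.broadcast_env(self.env, self.g_qc.samples, row["variable"]))[1]
        x = self.prs_by_trait[row["trait"]].column(row["pt"])
        return x, y

    def stage_permute(self) -> None:
        self.grid["perm_p"] = np.nan
        perms = {}
        for ridx, row in self.significant_cells().iterrows():
            x, y = self._cell_inputs(row)
            res = assoc.permutation_null(x, y, self.pcs,
                                         B=self.config.permutations,
                                         seed=self.config.seed + 17)
            self.grid.loc[ridx, "perm_p"] = res.perm_p
            perms[(row["trait"], row["variable"], row["pt"])] = res
            self._write(pd.DataFrame({"NULL_Z": res.null_z}),
                        f"permnull_{row['trait']}_{row['variable']}.tsv")
        self.results["permutations"] = perms
        self._write(self._grid_frame(), "grid.tsv")

        # PC robustness on the same significant cells
        comp_rows = []
        for _, row in self.significant_cells().iterrows():
            x, y = self._cell_inputs(row)
            c = assoc.compare_pc_models(x, y, self.pcs, self.pcs_check)
            comp_rows.append({"TRAIT": row["trait"], "VARIABLE": row["variable"],
                              "PT": row["pt"], "BETA_SMALL": c.beta10,
                              "BETA_LARGE": c.beta20, "STATISTIC": c.statistic,
                              "P_SMALL_VS_LARGE": c.p})
        if comp_rows:
            self._write(pd.DataFrame(comp_rows), "pc_comparison.tsv")

        for i, vset in enumerate(self.config.driver_sets):
            for _, row in self.significant_cells().iterrows():
                if row["variable"] not in vset:
                    continue
                x, _ = self._cell_inputs(row)
                drv = assoc.driver_analysis(x, self.env, self.g_qc.samples,
                                            list(vset), self.pcs)
                self._write(drv, f"driver_{row['trait']}_set{i}.tsv")

    def stage_enrich(self) -> None:
        if self.annotation is None:
            log.info("no annotation; skipping enrichment")
            return
        background = enrich.snp_properties(self.g_qc, self.annotation)
        self.results["enrichment"] = {}
        for _, row in self.significant_cells().iterrows():
            x, y = self._cell_inputs(row)
            snpset = enrich.select_prs_snps(
                self.g_qc, self.indexed[row["trait"]], row["pt"],
                np.sign(row["z"]), y, self.pcs)
            if not snpset.snps:
                continue
            snpset.properties = background[background["snp"].isin(snpset.snps)]
            genes = enrich.snps_to_genes(snpset.snps, self.annotation)
            obs = enrich.hypergeom_enrich(genes, self.annotation)
            tag = f"{row['trait']}_{row['variable']}"
            self._write(obs.table, f"enrichment_{tag}.tsv")
            matched = enrich.match_snps(
                snpset, background, n_sets=self.config.n_matched_sets,
                seed=self.config.seed + 23, relax=self.config.relax_matching)
            matched_results = [
                enrich.hypergeom_enrich(
                    enrich.snps_to_genes(s.snps, self.annotation), self.annotation)
                for s in matched]
            null = enrich.empirical_enrichment_null(obs, matched_results,
                                                    q_max=self.config.q_max)
            self._write(pd.DataFrame({"SET": np.arange(len(null["null_counts"])),
                                      "N_SIGNIFICANT": null["null_counts"]}),
                        f"matched_null_{tag}.tsv")
            self._write(pd.DataFrame({
                "SET": np.arange(len(matched)),
                "SNPS": [",".join(s.snps) for s in matched]}),
                f"matched_sets_{tag}.tsv")
            self.results["enrichment"][tag] = {
                "snpset": snpset, "observed": obs, "null": null}
            log.info("enrichment %s: %d significant terms, empirical p = %.4g",
                     tag, null["count_obs"], null["empirical_p"])

    def stage_noia(self) -> None:
        rows = []
        for _, row in self.significant_cells().iterrows():
            if row["n_snps"] > self.config.noia_max_snps or row["n_snps"] < 1:
                continue
            t = self.indexed[row["trait"]].table
            loci = list(t.loc[t["p"] <= row["pt"], "id"])
            cols = self.g_qc.variant_index().loc[loci].to_numpy()
            G = self.g_qc.dosages[:, cols].astype(float)
            _, y = self._cell_inputs(row)
            try:
                design = noia.build_design(G, loci=loci)
                fit = noia.fit_noia(design, y, covariates=self.pcs)
            except ValueError as exc:
                log.warning("NOIA skipped for %s/%s: %s",
                            row["trait"], row["variable"], exc)
                continue
            add = noia.test_additive(fit)
            for _, arow in add.iterrows():
                rows.append({"TRAIT": row["trait"], "VARIABLE": row["variable"],
                             "PT": row["pt"], "LOCI": ",".join(loci),
                             "EFFECT": f"a_{arow['LOCUS']}",
                             "ESTIMATE": arow["ESTIMATE"], "SE": arow["SE"],
                             "T": arow["T"], "P": arow["P"]})
        if rows:
            self._write(pd.DataFrame(rows), "noia.tsv")
        self.results["noia"] = rows

    # -------------------------------------------------- driver

    def run(self, upto: str = "noia") -> "Pipeline":
        order = ["simulate", "qc", "pca", "prs", "assoc", "permute", "enrich", "noia"]
        if upto not in order:
            raise ValueError(f"unknown stage {upto!r}")
        self.stage_simulate()
        for stage in order[1:order.index(upto) + 1]:
            log.info("stage: %s", stage)
            getattr(self, f"stage_{stage}")()
        self._save_manifest()
        return self


def run_all(config: RunConfig) -> Pipeline:
    """Execute the full pipeline and return the stage runner."""
    return Pipeline(config).run("noia")
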