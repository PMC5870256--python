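"""eQTL-mediated term enrichment with a matched-SNP-set empirical null.

Variants contributing to a significant polygenic-score association are
filtered to those with a nominally significant, direction-concordant
per-SNP association in the target cohort, mapped to genes through eQTL
links, and tested per term with an upper-tail hypergeometric test (BH FDR
across terms). The empirical null rebuilds the analysis on sets of
background SNPs matched to the input set on minor allele frequency
(+-5 percentage points), gene density (+-50%, relative), distance to the
nearest gene (+-50%, 5-kb absolute slack at zero) and LD-buddy count at
r2 >= 0.3 (+-50%, absolute slack 1 at zero), then asks how often a matched
set attains at least the observed number of significant terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .popstruct import PCMatrix
from ._stats import ols_fit
from .assoc import fdr_adjust


@dataclass
class AnnotationDB:
    """Gene intervals, SNP->gene eQTL links, gene->term map.

    ``genes``: columns gene, chrom, start, end (0-based half-open);
    ``eqtl``: columns snp, gene; ``terms``: columns gene, term.
    """

    genes: pd.DataFrame
    eqtl: pd.DataFrame
    terms: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.genes["start"] >= self.genes["end"]).any():
            bad = self.genes[self.genes["start"] >= self.genes["end"]].iloc[0]
            raise ValueError(f"malformed interval for gene {bad['gene']!r}")
        known = set(self.genes["gene"])
        for name, df, col in (("eqtl", self.eqtl, "gene"), ("terms", self.terms, "gene")):
            unknown = set(df[col]) - known
            if unknown:
                raise ValueError(f"{name} references unknown genes: {sorted(unknown)[:5]}")

    def snp_genes(self, snps) -> set[str]:
        return set(self.eqtl.loc[self.eqtl["snp"].isin(set(snps)), "gene"])

    def term_map(self) -> dict[str, set[str]]:
        return {t: set(sub["gene"]) for t, sub in self.terms.groupby("term")}


@dataclass
class SNPSet:
    """SNP IDs with the matching properties used by the empirical null."""

    snps: list[str]
    properties: pd.DataFrame = field(default_factory=pd.DataFrame)
    # properties columns: snp, maf, gene_density, dist_nearest_gene, ld_buddies


# ---------------------------------------------------------------- properties

def snp_properties(g: GenotypeMatrix, db: AnnotationDB,
                   snp_ids: list[str] | None = None,
                   density_kb: float = 100.0, buddy_kb: float = 250.0,
                   buddy_r2: float = 0.3) -> pd.DataFrame:
    """MAF, gene density, distance to nearest gene, LD-buddy count.

    Gene density counts genes overlapping +-density_kb around the SNP;
    distance is 0 for intragenic SNPs; LD buddies are panel SNPs within
    +-buddy_kb with r2 >= buddy_r2 (mean-imputed standardized dosages,
    consistent between query and background so matching is coherent).
    """
    v = g.variants
    if snp_ids is None:
        snp_ids = list(v["id"])
    want = set(snp_ids)

    X = g.imputed()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.inf
    Z = (X - mu) / sd
    n = Z.shape[0]

    maf = g.maf()
    rows = {}
    for chrom, sub in v.groupby("chrom", sort=False):
        gsub = db.genes[db.genes["chrom"].astype(str) == str(chrom)]
        starts = gsub["start"].to_numpy()
        ends = gsub["end"].to_numpy()
        order = np.argsort(starts)
        starts_s, ends_s = starts[order], ends[order]
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        zero_pos = pos - 1                      # 0-based coordinate of the site
        for t, j in enumerate(idx):
            snp = v.at[j, "id"]
            if snp not in want:
                continue
            w = density_kb * 1000.0
            density = int(np.sum((starts < zero_pos[t] + w + 1) & (ends > zero_pos[t] - w)))
            inside = (starts <= zero_pos[t]) & (ends > zero_pos[t])
            if inside.any():
                dist = 0
            elif len(starts) == 0:
                dist = np.inf
            else:
                d_up = np.where(starts > zero_pos[t], starts - zero_pos[t], np.inf)
                d_dn = np.where(ends <= zero_pos[t], zero_pos[t] - ends + 1, np.inf)
                dist = int(min(d_up.min(), d_dn.min()))
            lo = np.searchsorted(pos, pos[t] - buddy_kb * 1000.0, side="left")
            hi = np.searchsorted(pos, pos[t] + buddy_kb * 1000.0, side="right")
            win = idx[lo:hi]
            win = win[win != j]
            if len(win):
                r = Z[:, win].T @ Z[:, j] / n
                buddies = int(np.sum(r * r >= buddy_r2))
            else:
                buddies = 0
            rows[snp] = (maf[j], density, dist, buddies)
    out = pd.DataFrame(
        [(s, *rows[s]) for s in snp_ids if s in rows],
        columns=["snp", "maf", "gene_density", "dist_nearest_gene", "ld_buddies"])
    return out


# ---------------------------------------------------------------- SNP selection

def select_prs_snps(g: GenotypeMatrix, indexed_ss, cell_pt: float,
                    cell_z_sign: float, env_values: np.ndarray,
                    pcs: PCMatrix | None = None,
                    alpha: float = 0.05) -> SNPSet:
    """Variants in a significant score that individually support the signal.

    Candidates are the clump-index variants contributing at the cell's
    threshold. Each is regressed (transformed environment on dosage + PCs,
    in the target cohort); kept if per-SNP p < alpha and
    sign(beta_snp * beta_gwas) matches the sign of the cell's z.
    """
    t = indexed_ss.table
    cand = t[t["p"] <= cell_pt]
    if len(cand) == 0:
        warnings.warn("no candidate variants at this threshold")
        return SNPSet(snps=[])
    vidx = g.variant_index()
    y = np.asarray(env_values, dtype=float)
    n = len(y)
    cov_cols = [np.ones(n)]
    if pcs is not None:
        cov_cols.append(pcs.scores)
    Xcov = np.column_stack(cov_cols)
    D = g.imputed()
    kept = []
    for snp, beta_gwas in zip(cand["id"], cand["beta"]):
        x = D[:, vidx[snp]]
        if np.ptp(x) == 0:
            continue
        fit = ols_fit(np.column_stack([Xcov[:, :1], x, Xcov[:, 1:]]), y)
        if fit.p[1] < alpha and np.sign(fit.beta[1] * beta_gwas) == np.sign(cell_z_sign):
            kept.append(snp)
    if not kept:
        warnings.warn("no variants pass the concordance filter; empty set")
    return SNPSet(snps=kept)


# ---------------------------------------------------------------- enrichment

@dataclass
class EnrichmentResult:
    table: pd.DataFrame        # TERM, K, k, N, n, P, Q
    query_genes: set[str]
    universe: set[str]

    def significant_terms(self, q_max: float = 0.05) -> list[str]:
        t = self.table
        return list(t.loc[t["Q"] < q_max, "TERM"])


def snps_to_genes(snps, db: AnnotationDB) -> set[str]:
    """Union of eQTL-linked genes of a SNP set."""
    return db.snp_genes(snps)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); the per-term test."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(query_genes: set[str], db: AnnotationDB,
                     background_snps=None) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of each term in the query genes.

    The universe is the set of genes eQTL-linked to at least one background
    SNP (all panel SNPs in the eQTL table by default); the query is clipped
    to the universe. q-values are BH over all tested terms.
    """
    if background_snps is None:
        universe = set(db.eqtl["gene"])
    else:
        universe = db.snp_genes(background_snps)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query_genes) & universe
    N, n = len(universe), len(query)
    rows = []
    for term, genes in sorted(db.term_map().items()):
        tg = genes & universe
        K = len(tg)
        if K == 0:
            continue
        k = len(tg & query)
        rows.append((term, K, k, hypergeom_upper_tail(k, N, K, n)))
    table = pd.DataFrame(rows, columns=["TERM", "K", "k", "P"])
    table["N"], table["n"] = N, n
    table["Q"] = fdr_adjust(table["P"].to_numpy()) if len(table) else []
    table = table[["TERM", "K", "k", "N", "n", "P", "Q"]]
    return EnrichmentResult(table=table, query_genes=query, universe=universe)


# ---------------------------------------------------------------- matching

DEFAULT_TOLERANCES = {
    "maf": 0.05,             # absolute, percentage points on the frequency scale
    "gene_density": 0.5,     # relative
    "dist_nearest_gene": 0.5,  # relative; 5-kb absolute slack at 0
    "ld_buddies": 0.5,       # relative; absolute slack 1 at 0
}


def _candidates(row: pd.Series, background: pd.DataFrame,
                tol: dict[str, float]) -> np.ndarray:
    ok = np.abs(background["maf"].to_numpy() - row["maf"]) <= tol["maf"]
    for prop, slack0 in (("gene_density", 0.0), ("dist_nearest_gene", 5000.0),
                         ("ld_buddies", 1.0)):
        x = float(row[prop])
        b = background[prop].to_numpy(dtype=float)
        margin = tol[prop] * x if x > 0 else slack0
        ok &= np.abs(b - x) <= margin
    return np.where(ok)[0]


def match_snps(input_set: SNPSet, background: pd.DataFrame,
               tolerances: dict[str, float] | None = None,
               n_sets: int = 100, seed: int = 0,
               relax: bool = False) -> list[SNPSet]:
    """Build matched null SNP sets by property-constrained sampling.

    For each input SNP, each null set samples (uniformly, without
    replacement within the set) a background SNP inside the matching
    tolerances. Background SNPs also in the input set are excluded first.
    ``relax`` doubles every tolerance once when a SNP has no candidates.
    """
    tol = dict(DEFAULT_TOLERANCES if tolerances is None else tolerances)
    props = input_set.properties
    if props.empty:
        raise ValueError("input SNPSet has no precomputed properties")
    bg = background[~background["snp"].isin(set(input_set.snps))]
    bg = bg.sort_values("snp", kind="mergesort").reset_index(drop=True)

    cand_lists = {}
    for _, row in props.iterrows():
        cand = _candidates(row, bg, tol)
        if len(cand) == 0 and relax:
            cand = _candidates(row, bg, {k: 2 * v for k, v in tol.items()})
        if len(cand) == 0:
            raise ValueError(
                f"no matched candidates for SNP {row['snp']!r} with properties "
                f"maf={row['maf']:.3f} gene_density={row['gene_density']} "
                f"dist_nearest_gene={row['dist_nearest_gene']} "
                f"ld_buddies={row['ld_buddies']} (try relax=True)")
        cand_lists[row["snp"]] = cand
    rng = np.random.default_rng(seed)
    bg_snps = bg["snp"].to_numpy()
    sets = []
    for _ in range(n_sets):
        used: set[int] = set()
        chosen = []
        for snp in props["snp"]:
            avail = [c for c in cand_lists[snp] if c not in used]
            pool = avail if avail else list(cand_lists[snp])
            pick = int(rng.choice(pool))
            used.add(pick)
            chosen.append(bg_snps[pick])
        sets.append(SNPSet(snps=chosen,
                           properties=bg.set_index("snp").loc[chosen].reset_index()))
    return sets


def empirical_enrichment_null(observed: EnrichmentResult,
                              matched_results: list[EnrichmentResult],
                              q_max: float = 0.05) -> dict:
    """Empirical probability of matching the observed number of significant
    terms under the matched null.

    Returns the add-one empirical p for >= count_obs significant terms, the
    per-set counts, and the pooled matched-set q distribution.
    """
    if len(matched_results) < 20:
        warnings.warn(f"only {len(matched_results)} matched sets; the empirical "
                      "p resolution is coarse")
    count_obs = len(observed.significant_terms(q_max))
    counts = np.array([len(r.significant_terms(q_max)) for r in matched_results])
    n_sets = len(matched_results)
    emp_p = (1.0 + np.sum(counts >= count_obs)) / (n_sets + 1.0)
    pooled_q = np.concatenate([r.table["Q"].to_numpy() for r in matched_results]) \
        if matched_results else np.array([])
    return {"count_obs": count_obs, "null_counts": counts,
            "empirical_p": float(emp_p), "pooled_q": pooled_q}
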