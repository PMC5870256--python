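"""Synthetic structured cohorts with optional planted clinal selection.

Generates everything the analysis pipeline consumes, with the statistical
structure the method assumes, so the full stack is testable without any
external download:

* a diploid cohort sampled from ``n_populations`` demes whose allele
  frequencies follow the Balding-Nichols model around a shared ancestral
  frequency (differentiation controlled by ``fst``; the default 0.01 is the
  weak, European-scale differentiation regime);
* within-block linkage disequilibrium induced by a latent Gaussian copula
  with AR(1) correlation ``ld_rho`` inside blocks of ``ld_block_size``
  variants, thresholded to per-haplotype allele indicators so the marginal
  dosage distribution at each variant is Binomial(2, p_k);
* local adaptation planted as a frequency cline: for each causal variant j
  the frequency in deme k is shifted by ``s * beta_j * z_k`` where z_k is
  the standardized value of a designated environmental driver at site k;
* GWAS summary statistics for each simulated trait from an idealized
  external training study of ``n_gwas`` individuals (Wald test, per-variant
  standard error 1/sqrt(2 n p0 (1-p0))), with a configurable fraction of
  rows emitted with swapped allele labels to exercise harmonization;
* a site x variable environment table with a specified inter-variable
  correlation matrix; and
* a gene/eQTL/term annotation with one planted "enriched" term whose genes
  are preferentially linked to causal variants.

Everything is a deterministic function of ``SimConfig.seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .genio import GenotypeMatrix

DEFAULT_ENV_VARIABLES = [
    "win_min_temp", "win_max_temp", "precip", "pathogen_div", "phoneme_count",
]
# winter minimum and maximum temperature strongly correlated (rho ~ 0.75),
# precipitation weakly coupled to temperature; pathogen diversity and
# phonological complexity independent of climate
DEFAULT_ENV_CORR = np.array([
    [1.00, 0.75, 0.30, 0.00, 0.00],
    [0.75, 1.00, 0.30, 0.00, 0.00],
    [0.30, 0.30, 1.00, 0.00, 0.00],
    [0.00, 0.00, 0.00, 1.00, 0.00],
    [0.00, 0.00, 0.00, 0.00, 1.00],
])
# marginal units: degrees C, degrees C, mm, species counts, phoneme counts
DEFAULT_ENV_LOC = np.array([-2.0, 5.0, 700.0, 20.0, 35.0])
DEFAULT_ENV_SCALE = np.array([4.0, 4.0, 180.0, 5.0, 8.0])


@dataclass
class SimConfig:
    """Parameters of the synthetic study. Defaults are the reference
    conditions: 23 demes x 100 diploids, 20,000 variants on 22 chromosomes,
    FST 0.01, LD blocks of 25 variants at rho 0.8, 200 causal variants per
    trait, a training GWAS of 50,000."""

    n_populations: int = 23
    n_per_pop: int = 100
    n_variants: int = 20_000
    n_chromosomes: int = 22
    fst: float = 0.01
    ld_block_size: int = 25
    ld_rho: float = 0.8
    n_traits: int = 1
    n_causal: int = 200
    h2_like_effect_scale: float = 0.05
    selection_gradient: float = 0.0
    n_gwas: int = 50_000
    env_variables: list[str] = field(default_factory=lambda: list(DEFAULT_ENV_VARIABLES))
    env_corr: np.ndarray = field(default_factory=lambda: DEFAULT_ENV_CORR.copy())
    env_loc: np.ndarray = field(default_factory=lambda: DEFAULT_ENV_LOC.copy())
    env_scale: np.ndarray = field(default_factory=lambda: DEFAULT_ENV_SCALE.copy())
    driver_variable: str = "win_min_temp"
    missing_rate: float = 0.01
    swap_fraction: float = 0.05
    hwe_violation_rate: float = 0.0
    variant_spacing_bp: int = 5_000
    n_terms: int = 50
    plant_enriched_term: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must be in (0,1), got {self.fst}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho must be in [0,1), got {self.ld_rho}")
        if self.n_per_pop < 2:
            raise ValueError("n_per_pop must be >= 2")
        if not 0.0 <= self.missing_rate < 0.1:
            raise ValueError("missing_rate must be in [0, 0.1)")
        if self.selection_gradient < 0:
            raise ValueError("selection_gradient must be >= 0")
        C = np.asarray(self.env_corr, dtype=float)
        if C.shape != (len(self.env_variables),) * 2:
            raise ValueError("env_corr shape does not match env_variables")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("env_corr is not positive semi-definite")

    @property
    def site_ids(self) -> list[str]:
        return [f"S{k + 1:02d}" for k in range(self.n_populations)]


@dataclass
class Truth:
    """Generative truth: ancestral frequencies, per-deme frequencies after
    any selection shift, causal flags and true effect sizes per trait."""

    variants: pd.DataFrame          # id, chrom, pos, ref, alt
    p0: np.ndarray                  # (m,) ancestral frequencies
    pop_freqs: np.ndarray           # (n_populations, m)
    causal: np.ndarray              # (n_traits, m) bool
    beta: np.ndarray                # (n_traits, m) true per-allele effects
    site_ids: list[str]
    trait_names: list[str]
    planted_term: str | None = None


@dataclass
class SimOutput:
    genotypes: GenotypeMatrix
    truth: Truth
    sumstats: dict[str, pd.DataFrame]
    environment: pd.DataFrame
    annotation: object                # AnnotationDB
    config: SimConfig


# ---------------------------------------------------------------- layout

def variant_layout(config: SimConfig) -> pd.DataFrame:
    """Variant IDs, chromosomes and evenly spaced 1-based positions."""
    m = config.n_variants
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    chroms = np.repeat([str(c + 1) for c in range(config.n_chromosomes)], per_chrom)
    pos = np.concatenate([
        10_000 + config.variant_spacing_bp * np.arange(k) for k in per_chrom])
    return pd.DataFrame({
        "id": [f"rs{j + 1:06d}" for j in range(m)],
        "chrom": chroms, "pos": pos.astype(np.int64),
        "ref": "A", "alt": "G",
    })


def _blocks(config: SimConfig, variants: pd.DataFrame) -> list[np.ndarray]:
    """Contiguous LD blocks of at most ld_block_size variants, never
    spanning a chromosome boundary."""
    out = []
    for _, sub in variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        for start in range(0, len(idx), config.ld_block_size):
            out.append(idx[start:start + config.ld_block_size])
    return out


# ---------------------------------------------------------------- truth

def draw_truth(config: SimConfig, rng: np.random.Generator) -> Truth:
    """Balding-Nichols deme frequencies plus causal variants and effects."""
    m = config.n_variants
    F = config.fst
    p0 = rng.uniform(0.05, 0.95, size=m)
    a = p0 * (1.0 - F) / F
    b = (1.0 - p0) * (1.0 - F) / F
    pop_freqs = rng.beta(a, b, size=(config.n_populations, m))
    pop_freqs = np.clip(pop_freqs, 1e-6, 1.0 - 1e-6)

    traits = [f"trait{t + 1}" for t in range(config.n_traits)]
    causal = np.zeros((config.n_traits, m), dtype=bool)
    beta = np.zeros((config.n_traits, m))
    for t in range(config.n_traits):
        idx = rng.choice(m, size=config.n_causal, replace=False)
        causal[t, idx] = True
        beta[t, idx] = rng.normal(0.0, config.h2_like_effect_scale, size=config.n_causal)
    return Truth(variants=variant_layout(config), p0=p0, pop_freqs=pop_freqs,
                 causal=causal, beta=beta, site_ids=config.site_ids,
                 trait_names=traits)


def apply_selection_gradient(truth: Truth, environment: pd.DataFrame,
                             s: float, driver: str = "win_min_temp",
                             trait: int = 0) -> Truth:
    """Shift causal-variant deme frequencies along the driver variable.

    For causal variant j and deme k: p_k <- clip(p_k + s*beta_j*z_k,
    0.01, 0.99), z_k the standardized driver value at site k. s = 0 is the
    identity; non-causal variants are never touched.
    """
    if s < 0:
        raise ValueError("selection gradient s must be >= 0")
    if s == 0:
        return truth
    if driver not in environment.columns:
        raise ValueError(f"driver variable {driver!r} not in environment table")
    z = environment.loc[truth.site_ids, driver].to_numpy(dtype=float)
    z = (z - z.mean()) / z.std()
    cc = truth.causal[trait]
    shift = s * np.outer(z, truth.beta[trait, cc])
    freqs = truth.pop_freqs.copy()
    freqs[:, cc] = np.clip(freqs[:, cc] + shift, 0.01, 0.99)
    return replace(truth, pop_freqs=freqs)


# ---------------------------------------------------------------- genotypes

def _ar1_chol(rho: float, size: int) -> np.ndarray:
    idx = np.arange(size)
    C = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(C)


def draw_genotypes(truth: Truth, config: SimConfig,
                   rng: np.random.Generator) -> GenotypeMatrix:
    """Sample diploid dosages from the deme frequencies with block LD.

    Two latent Gaussian haplotype vectors per individual, correlated AR(1)
    within each block, are thresholded at Phi^{-1}(p_k) per variant; the
    dosage is the sum of the two allele indicators.
    """
    K, m = truth.pop_freqs.shape
    n = config.n_per_pop
    blocks = _blocks(config, truth.variants)
    chol_cache = {len(b): _ar1_chol(config.ld_rho, len(b)) for b in blocks}

    dosages = np.empty((K * n, m), dtype=np.float32)
    for k in range(K):
        thresh = ndtri(truth.pop_freqs[k])
        Z = rng.standard_normal((2 * n, m))
        for b in blocks:
            L = chol_cache[len(b)]
            Z[:, b] = Z[:, b] @ L.T
        alleles = Z < thresh           # marginal Bernoulli(p_k) per haplotype
        dosages[k * n:(k + 1) * n] = (
            alleles[:n].astype(np.float32) + alleles[n:].astype(np.float32))

    if config.hwe_violation_rate > 0:
        n_bad = int(round(config.hwe_violation_rate * m))
        bad = rng.choice(m, size=n_bad, replace=False)
        for j in bad:
            # excess heterozygosity: het with prob 0.9 regardless of freq
            for k in range(K):
                p = truth.pop_freqs[k, j]
                u = rng.random(n)
                col = np.where(u < 0.9, 1.0,
                               np.where(rng.random(n) < p, 2.0, 0.0))
                dosages[k * n:(k + 1) * n, j] = col

    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    samples = pd.DataFrame({
        "id": [f"I{k + 1:02d}_{i + 1:04d}" for k in range(K) for i in range(n)],
        "site_id": [truth.site_ids[k] for k in range(K) for _ in range(n)],
    })
    return GenotypeMatrix(dosages, truth.variants.copy(), samples)


def simulate_cohort(config: SimConfig,
                    truth: Truth | None = None) -> tuple[GenotypeMatrix, Truth]:
    """Draw truth (no selection) and genotypes from the config seed."""
    rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = draw_truth(config, rng)
    g = draw_genotypes(truth, config, rng)
    return g, truth


# ---------------------------------------------------------------- sumstats

def simulate_sumstats(truth: Truth, n_gwas: int, trait: int = 0,
                      swap_fraction: float = 0.0,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Idealized external-GWAS summary statistics for one trait.

    se_j = 1/sqrt(2 n p0 (1-p0)); beta_hat = beta_true + N(0, se); two-sided
    Wald p. A ``swap_fraction`` of rows is emitted with effect/other alleles
    exchanged and beta negated, which downstream harmonization must undo.
    """
    if n_gwas < 100:
        raise ValueError(f"n_gwas must be >= 100, got {n_gwas}")
    if rng is None:
        rng = np.random.default_rng(0)
    p0 = truth.p0
    se = 1.0 / np.sqrt(2.0 * n_gwas * p0 * (1.0 - p0))
    beta_hat = truth.beta[trait] + rng.normal(0.0, se)
    z = beta_hat / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)

    v = truth.variants
    ea = np.array(v["alt"], dtype=object)
    oa = np.array(v["ref"], dtype=object)
    beta_out = beta_hat.copy()
    if swap_fraction > 0:
        swap = rng.random(len(v)) < swap_fraction
        ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
        beta_out[swap] = -beta_out[swap]
    return pd.DataFrame({
        "id": v["id"], "chrom": v["chrom"], "pos": v["pos"],
        "effect_allele": ea, "other_allele": oa,
        "beta": beta_out, "p": p, "se": se,
    })


# ---------------------------------------------------------------- environment

def simulate_environment(config: SimConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Site x variable table: correlated Gaussian draws, rescaled to the
    per-variable marginal location/scale."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    C = np.asarray(config.env_corr, dtype=float)
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-10:
        raise ValueError("env_corr is not positive semi-definite")
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    Z = rng.standard_normal((config.n_populations, C.shape[0])) @ L.T
    values = config.env_loc + config.env_scale * Z
    return pd.DataFrame(values, index=pd.Index(config.site_ids, name="SITE_ID"),
                        columns=config.env_variables)


# ---------------------------------------------------------------- annotation

def simulate_annotation(config: SimConfig, truth: Truth,
                        rng: np.random.Generator | None = None):
    """Gene intervals, SNP->gene eQTL links, and a gene->term map.

    Genes are non-overlapping 30-kb intervals tiled at a 50-kb pitch along
    each chromosome's variant span. Each SNP is eQTL-linked to one or two
    genes within +-100 kb. When ``plant_enriched_term`` is set, genes linked
    to causal variants (trait 1) carry the term "T_ENRICHED" with high
    probability, background genes with low probability, so a true enrichment
    signal exists for the matched-set null to detect.
    """
    from .enrich import AnnotationDB

    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    gene_len, pitch = 30_000, 50_000
    genes = []
    v = truth.variants
    for chrom, sub in v.groupby("chrom", sort=False):
        lo, hi = int(sub["pos"].min()), int(sub["pos"].max())
        start = max(lo - pitch, 0)
        gi = 0
        while start < hi + pitch:
            genes.append((f"G{chrom}_{gi:04d}", str(chrom), start, start + gene_len))
            start += pitch
            gi += 1
    genes_df = pd.DataFrame(genes, columns=["gene", "chrom", "start", "end"])

    eqtl_rows = []
    for chrom, sub in v.groupby("chrom", sort=False):
        gsub = genes_df[genes_df["chrom"] == str(chrom)]
        centers = ((gsub["start"] + gsub["end"]) // 2).to_numpy()
        gnames = gsub["gene"].to_numpy()
        for pos, snp in zip(sub["pos"].to_numpy(), sub["id"].to_numpy()):
            near = np.where(np.abs(centers - pos) <= 100_000)[0]
            if len(near) == 0:
                continue
            k = 1 + int(rng.random() < 0.4)
            pick = rng.choice(near, size=min(k, len(near)), replace=False)
            for gi in pick:
                eqtl_rows.append((snp, gnames[gi]))
    eqtl_df = pd.DataFrame(eqtl_rows, columns=["snp", "gene"])

    term_names = [f"T{t + 1:03d}" for t in range(config.n_terms)]
    causal_snps = set(v.loc[truth.causal[0], "id"])
    causal_genes = set(eqtl_df.loc[eqtl_df["snp"].isin(causal_snps), "gene"])
    term_rows = []
    planted = None
    if config.plant_enriched_term:
        planted = "T_ENRICHED"
        for gene in genes_df["gene"]:
            pr = 0.6 if gene in causal_genes else 0.05
            if rng.random() < pr:
                term_rows.append((gene, planted))
    for gene in genes_df["gene"]:
        k = 1 + rng.poisson(1.0)
        for t in rng.choice(config.n_terms, size=min(k, config.n_terms), replace=False):
            term_rows.append((gene, term_names[t]))
    terms_df = pd.DataFrame(term_rows, columns=["gene", "term"]).drop_duplicates()

    truth.planted_term = planted
    return AnnotationDB(genes=genes_df, eqtl=eqtl_df, terms=terms_df)


# ---------------------------------------------------------------- full bundle

def simulate_all(config: SimConfig) -> SimOutput:
    """Environment -> truth -> selection -> genotypes -> sumstats -> annotation,
    all driven by one generator seeded from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    environment = simulate_environment(config, rng)
    truth = draw_truth(config, rng)
    if config.selection_gradient > 0:
        truth = apply_selection_gradient(
            truth, environment, config.selection_gradient,
            driver=config.driver_variable)
    genotypes = draw_genotypes(truth, config, rng)
    sumstats = {
        name: simulate_sumstats(truth, config.n_gwas, trait=t,
                                swap_fraction=config.swap_fraction, rng=rng)
        for t, name in enumerate(truth.trait_names)
    }
    annotation = simulate_annotation(config, truth, rng)
    return SimOutput(genotypes=genotypes, truth=truth, sumstats=sumstats,
                     environment=environment, annotation=annotation,
                     config=config)
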