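"""Quality control: missingness/MAF/HWE filters, exact HWE test, LD pruning.

The filter chain mirrors standard pre-imputation GWAS QC on a diploid cohort:
per-variant missingness <= 5%, per-individual missingness <= 5%, minor allele
frequency >= 1%, and an exact Hardy-Weinberg test at p > 1e-4. The HWE test
is the exact conditional test (two-sided by probability mass) rather than a
chi-square approximation: with small per-site counts the chi-square is
unreliable exactly where the cutoff bites. HWE is tested on the pooled
cohort, which in a structured sample is conservative (Wahlund effect inflates
homozygosity); the report flags this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import pairwise_complete_r2
from .genio import GenotypeMatrix


# ---------------------------------------------------------------- HWE exact test

def _het_probs(n: int, n_alt: int) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of heterozygote counts given n diploids and n_alt alleles.

    Returns (het_counts, probabilities) for the conditional distribution of
    the number of heterozygotes given the allele counts, computed by the
    stable mid-out recurrence. Heterozygote counts share the parity of the
    rare-allele count.
    """
    n_rare = min(n_alt, 2 * n - n_alt)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    if len(hets) == 0:
        hets = np.array([0])
    # start near the mode and apply the two-sided recurrence via cumulative
    # products (vectorized; extreme-tail underflow to 0 is harmless)
    mid = n_rare * (2 * n - n_rare) / (2 * n - 1) if n > 0 else 0
    start = int(np.argmin(np.abs(hets - mid)))
    h = hets.astype(np.float64)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    probs = np.empty(len(hets))
    probs[start] = 1.0
    if start > 0:
        # P(h-2)/P(h) = h(h-1) / (4 (hom_r + 1)(hom_c + 1)), applied downward
        ratio_down = (h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0)))[start:0:-1]
        probs[start - 1::-1] = np.cumprod(ratio_down)
    if start < len(hets) - 1:
        # P(h+2)/P(h) = 4 hom_r hom_c / ((h+2)(h+1)), applied upward
        ratio_up = (4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0)))[start:-1]
        probs[start + 1:] = np.cumprod(ratio_up)
    probs /= probs.sum()
    return hets, probs


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Sums the probabilities of all heterozygote counts whose conditional
    probability (given the allele counts) does not exceed that of the
    observed count.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("all genotype counts are zero")
    n_alt = n_het + 2 * n_hom_alt
    hets, probs = _het_probs(n, n_alt)
    p_obs = probs[np.searchsorted(hets, n_het)]
    p = probs[probs <= p_obs * (1.0 + 1e-9)].sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------- QC filter

@dataclass
class QCReport:
    """Per-step removal counts for the fixed-order filter chain."""

    steps: list[tuple[str, int]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def removed(self, step: str) -> int:
        return dict(self.steps).get(step, 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["STEP", "REMOVED"])


def genotype_counts(dosages: np.ndarray) -> np.ndarray:
    """(n_variants, 3) counts of dosage 0/1/2 ignoring missing."""
    out = np.empty((dosages.shape[1], 3), dtype=np.int64)
    for g in (0, 1, 2):
        out[:, g] = np.nansum(dosages == g, axis=0)
    return out


def qc_filter(g: GenotypeMatrix, maf_min: float = 0.01,
              miss_var_max: float = 0.05, miss_ind_max: float = 0.05,
              hwe_p_min: float = 1e-4) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC chain in fixed order, each step on the survivors.

    Order: per-variant missingness -> per-individual missingness -> MAF ->
    HWE exact test (pooled across sites).
    """
    if g.n_variants == 0 or g.n_samples == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport()
    report.notes.append("HWE tested on the pooled cohort, not per site")

    miss_var = np.isnan(g.dosages).mean(axis=0)
    keep_v = miss_var <= miss_var_max
    report.steps.append(("variant_missingness", int((~keep_v).sum())))
    g = g.subset(variant_idx=np.where(keep_v)[0])

    miss_ind = np.isnan(g.dosages).mean(axis=1)
    keep_i = miss_ind <= miss_ind_max
    report.steps.append(("individual_missingness", int((~keep_i).sum())))
    g = g.subset(sample_idx=np.where(keep_i)[0])

    keep_maf = g.maf() >= maf_min
    report.steps.append(("maf", int((~keep_maf).sum())))
    g = g.subset(variant_idx=np.where(keep_maf)[0])

    counts = genotype_counts(g.dosages)
    hwe_p = np.array([
        hwe_exact_test(*row) if row.sum() > 0 else 1.0 for row in counts])
    keep_hwe = hwe_p > hwe_p_min
    report.steps.append(("hwe", int((~keep_hwe).sum())))
    g = g.subset(variant_idx=np.where(keep_hwe)[0])

    if g.n_variants == 0:
        raise ValueError("QC removed every variant")
    if g.n_samples == 0:
        raise ValueError("QC removed every individual")
    return g, report


# ---------------------------------------------------------------- LD

def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise complete.

    Composite LD on unphased dosages. Zero variance in either vector on the
    complete subset is defined as r2 = 0 (with a warning).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    both = np.isfinite(x) & np.isfinite(y)
    if both.sum() < 3:
        raise ValueError(f"only {int(both.sum())} complete pairs; need >= 3")
    xs, ys = x[both], y[both]
    vx, vy = xs.var(), ys.var()
    if vx == 0 or vy == 0:
        warnings.warn("zero variance in dosage vector; r2 defined as 0")
        return 0.0
    c = np.cov(xs, ys, bias=True)[0, 1]
    return float(min(c * c / (vx * vy), 1.0))


def ld_prune(g: GenotypeMatrix, r2_max: float = 0.2, window: int = 50,
             step: int = 5) -> list[str]:
    """Greedy sliding-window LD pruning; returns retained variant IDs.

    Within each window, pairs are scanned in position order; for any pair
    with r2 >= r2_max the member with smaller MAF is dropped (tie: larger
    position). Windows advance by ``step`` variants within each chromosome.
    """
    maf = g.maf()
    removed = np.zeros(g.n_variants, dtype=bool)
    pos = g.variants["pos"].to_numpy()
    for chrom, sub in g.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        m = len(idx)
        for start in range(0, max(m - 1, 1), step):
            win = idx[start:start + window]
            alive = win[~removed[win]]
            if len(alive) < 2:
                continue
            r2 = pairwise_complete_r2(g.dosages[:, alive])
            for a in range(len(alive)):
                if removed[alive[a]]:
                    continue
                for b in range(a + 1, len(alive)):
                    if removed[alive[b]] or removed[alive[a]]:
                        continue
                    if r2[a, b] >= r2_max:
                        ia, ib = alive[a], alive[b]
                        drop = _prune_victim(ia, ib, maf, pos)
                        removed[drop] = True
            if start + window >= m:
                break
    return list(g.variants.loc[~removed, "id"])


def _prune_victim(ia: int, ib: int, maf: np.ndarray, pos: np.ndarray) -> int:
    if maf[ia] < maf[ib]:
        return ia
    if maf[ib] < maf[ia]:
        return ib
    return ia if pos[ia] > pos[ib] else ib
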