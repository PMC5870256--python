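"""Clumping + thresholding polygenic scores from GWAS summary statistics.

The C+T recipe: harmonize external summary statistics to the target panel so
every effect counts the panel's alt-dosage allele, drop the MHC (long-range
LD), greedily clump by ascending GWAS p-value with an r2 cutoff of 0.3
inside a 500-kb window, then score each individual at twelve inclusion
thresholds (PT = 5e-8 ... 1). Scores are raw beta-weighted dosage sums with
missing genotypes mean-imputed (2 * panel alt frequency); the association
z-statistic downstream is invariant to this choice of sum versus average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import r2_one_vs_many
from .genio import GenotypeMatrix

#: the twelve GWAS p-value inclusion thresholds used throughout
PT_THRESHOLDS = (5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.3, 0.5, 1.0)

#: default MHC bounds on chromosome 6, inclusive (build-agnostic stand-in)
MHC_CHROM = "6"
MHC_START = 26_000_000
MHC_END = 34_000_000

AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class SummaryStats:
    """Per-variant effect sizes and p-values for one trait."""

    table: pd.DataFrame    # id, chrom, pos, effect_allele, other_allele, beta, p
    trait: str = "trait"

    def __post_init__(self) -> None:
        t = self.table
        if t["id"].duplicated().any():
            raise ValueError(f"duplicate variant ID {t['id'][t['id'].duplicated()].iloc[0]!r}")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        if (t["effect_allele"].astype(str) == t["other_allele"].astype(str)).any():
            raise ValueError("effect and other allele must differ")
        self.table = t.reset_index(drop=True)


@dataclass
class ClumpResult:
    index_ids: list[str]                       # ordered by ascending GWAS p
    clumped: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        removed = {x for v in self.clumped.values() for x in v}
        if removed & set(self.index_ids):
            raise ValueError("index and clumped sets overlap")


@dataclass
class PRSMatrix:
    scores: np.ndarray          # individuals x thresholds
    thresholds: tuple[float, ...]
    n_snps: np.ndarray          # contributing variants per threshold
    sample_ids: list[str]
    trait: str = "trait"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.n_snps) < 0):
            raise ValueError("n_snps must be non-decreasing across thresholds")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def column(self, pt: float) -> np.ndarray:
        return self.scores[:, self.thresholds.index(pt)]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PT_{pt:g}": self.scores[:, i]
                for i, pt in enumerate(self.thresholds)}
        return pd.DataFrame({"IID": self.sample_ids, **cols})


# ---------------------------------------------------------------- harmonize

def harmonize(ss: SummaryStats, g: GenotypeMatrix,
              drop_ambiguous: bool = False) -> SummaryStats:
    """Align summary statistics to the target panel's alt-dosage allele.

    Variants are matched on ID and allele pair; when the effect allele is the
    panel's ref allele the beta is negated. Allele-pair mismatches are
    dropped (logged via warning); ``drop_ambiguous`` also removes A/T and
    C/G pairs. Panel chromosome/position replace the GWAS coordinates so
    clumping windows live in panel space.
    """
    panel = g.variants.set_index("id")
    t = ss.table
    present = t["id"].isin(panel.index)
    t = t[present]
    if len(t) == 0:
        raise ValueError("no summary-statistic variants overlap the panel")
    ref = panel.loc[t["id"], "ref"].to_numpy(dtype=object)
    alt = panel.loc[t["id"], "alt"].to_numpy(dtype=object)
    ea = t["effect_allele"].to_numpy(dtype=object)
    oa = t["other_allele"].to_numpy(dtype=object)
    same = (ea == alt) & (oa == ref)
    flipped = (ea == ref) & (oa == alt)
    keep = same | flipped
    if drop_ambiguous:
        amb = np.array([frozenset((a, b)) in AMBIGUOUS_PAIRS
                        for a, b in zip(ea, oa)])
        keep &= ~amb
    n_drop = int((~keep).sum())
    if n_drop:
        warnings.warn(f"harmonize: dropped {n_drop} variants "
                      "(allele mismatch or ambiguous pair)")
    t = t[keep]
    if len(t) == 0:
        raise ValueError("no variants survive allele harmonization")
    flip = flipped[keep]
    beta = np.where(flip, -t["beta"].to_numpy(), t["beta"].to_numpy())
    out = pd.DataFrame({
        "id": t["id"].to_numpy(),
        "chrom": panel.loc[t["id"], "chrom"].to_numpy(),
        "pos": panel.loc[t["id"], "pos"].to_numpy(),
        "effect_allele": alt[keep], "other_allele": ref[keep],
        "beta": beta, "p": t["p"].to_numpy(),
    })
    return SummaryStats(table=out, trait=ss.trait)


def exclude_mhc(ss: SummaryStats, chrom: str = MHC_CHROM,
                start: int = MHC_START, end: int = MHC_END) -> SummaryStats:
    """Drop variants inside the MHC interval (inclusive bounds)."""
    t = ss.table
    inside = (t["chrom"].astype(str) == str(chrom)) & \
             (t["pos"] >= start) & (t["pos"] <= end)
    return SummaryStats(table=t[~inside].reset_index(drop=True), trait=ss.trait)


# ---------------------------------------------------------------- clumping

def clump(ss: SummaryStats, g: GenotypeMatrix, r2_cut: float = 0.3,
          window_kb: float = 500.0) -> ClumpResult:
    """p-value-informed greedy clumping against the target panel's LD.

    Variants are processed by ascending GWAS p (ties: chromosome, then
    position). Each index removes unprocessed variants on the same
    chromosome within +-window_kb/2 whose r2 with it is >= r2_cut.
    """
    t = ss.table
    vidx = g.variant_index()
    missing = ~t["id"].isin(vidx.index)
    if missing.any():
        raise ValueError(
            f"variants absent from panel (harmonize first): "
            f"{list(t.loc[missing, 'id'].head())}")

    order = t.sort_values(
        ["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    ids = order["id"].to_numpy()
    chroms = order["chrom"].astype(str).to_numpy()
    pos = order["pos"].to_numpy()
    cols = vidx.loc[ids].to_numpy()
    half_window = window_kb * 1000.0 / 2.0

    # per-chromosome position-sorted views for window lookups
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(chroms):
        rows = np.where(chroms == c)[0]
        srt = rows[np.argsort(pos[rows], kind="mergesort")]
        by_chrom[c] = (pos[srt], srt)

    removed = np.zeros(len(ids), dtype=bool)
    done = np.zeros(len(ids), dtype=bool)
    index_ids: list[str] = []
    clumped: dict[str, list[str]] = {}
    for i in range(len(ids)):
        if removed[i] or done[i]:
            continue
        done[i] = True
        index_ids.append(ids[i])
        cpos, crows = by_chrom[chroms[i]]
        lo = np.searchsorted(cpos, pos[i] - half_window, side="left")
        hi = np.searchsorted(cpos, pos[i] + half_window, side="right")
        cand = crows[lo:hi]
        cand = cand[~removed[cand] & ~done[cand]]
        if len(cand) == 0:
            clumped[ids[i]] = []
            continue
        r2 = r2_one_vs_many(g.dosages[:, cols[i]], g.dosages[:, cols[cand]])
        hit = cand[r2 >= r2_cut]
        removed[hit] = True
        clumped[ids[i]] = sorted(ids[hit])
    return ClumpResult(index_ids=index_ids, clumped=clumped)


# ---------------------------------------------------------------- scoring

def score(ss: SummaryStats, clump_result: ClumpResult, g: GenotypeMatrix,
          thresholds: tuple[float, ...] = PT_THRESHOLDS,
          average: bool = False) -> PRSMatrix:
    """Beta-weighted dosage sums at each inclusion threshold.

    The contributing set at threshold PT is the clump-index variants with
    GWAS p <= PT. Missing dosages are replaced by 2 * panel alt frequency.
    ``average=True`` divides each column by its variant count; with mean
    imputation the two conventions differ by a per-column constant factor,
    so downstream association statistics are identical.
    """
    t = ss.table.set_index("id")
    idx_ids = [v for v in clump_result.index_ids]
    p = t.loc[idx_ids, "p"].to_numpy()
    beta = t.loc[idx_ids, "beta"].to_numpy()
    cols = g.variant_index().loc[idx_ids].to_numpy()
    D = g.dosages[:, cols].astype(np.float64)
    fill = np.nanmean(D, axis=0)     # = 2 * panel alt frequency
    miss = np.isnan(D)
    D[miss] = np.broadcast_to(fill, D.shape)[miss]

    scores = np.zeros((g.n_samples, len(thresholds)))
    n_snps = np.zeros(len(thresholds), dtype=np.int64)
    for j, pt in enumerate(thresholds):
        sel = p <= pt
        n_snps[j] = int(sel.sum())
        if n_snps[j] == 0:
            warnings.warn(f"no variants pass PT={pt:g}; score column is zero")
            continue
        scores[:, j] = D[:, sel] @ beta[sel]
        if average:
            scores[:, j] /= n_snps[j]
    return PRSMatrix(scores=scores, thresholds=tuple(thresholds),
                     n_snps=n_snps, sample_ids=list(g.samples["id"]),
                     trait=ss.trait)


def build_prs(ss: SummaryStats, g: GenotypeMatrix, *,
              drop_ambiguous: bool = False, r2_cut: float = 0.3,
              window_kb: float = 500.0,
              thresholds: tuple[float, ...] = PT_THRESHOLDS,
              mhc: tuple[str, int, int] | None = (MHC_CHROM, MHC_START, MHC_END),
              ) -> tuple[PRSMatrix, ClumpResult, SummaryStats]:
    """Full C+T chain: harmonize -> MHC exclusion -> clump -> score."""
    aligned = harmonize(ss, g, drop_ambiguous=drop_ambiguous)
    if mhc is not None:
        aligned = exclude_mhc(aligned, *mhc)
    cr = clump(aligned, g, r2_cut=r2_cut, window_kb=window_kb)
    keep = aligned.table["id"].isin(cr.index_ids)
    indexed = SummaryStats(aligned.table[keep].reset_index(drop=True),
                           trait=aligned.trait)
    prs = score(indexed, cr, g, thresholds=thresholds)
    return prs, cr, indexed
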