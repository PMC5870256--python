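"""Genotype, summary-statistic, environment and annotation I/O.

The in-memory genotype container stores alt-allele dosages (0/1/2, NaN for
missing) as a dense float32 matrix with pandas metadata tables for variants
and samples. On disk, genotypes are either VCF v4.2 with GT fields (read via
cyvcf2) or a plain dosage-matrix TSV dialect: a header row of variant IDs and
one row per individual (IID followed by dosages, "NA" for missing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Individuals x variants alt-allele dosage store with metadata.

    dosages: (n_samples, n_variants) float32, values {0,1,2}, NaN = missing.
    variants: DataFrame with columns id, chrom, pos (1-based), ref, alt;
        dosage counts the alt allele.
    samples: DataFrame with columns id, site_id.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        n, m = self.dosages.shape
        if len(self.samples) != n or len(self.variants) != m:
            raise ValueError(
                f"dimension mismatch: dosages {n}x{m}, "
                f"{len(self.samples)} samples, {len(self.variants)} variants"
            )
        ids = self.variants["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant ID: {dup!r}")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        bad = (self.variants["ref"].astype(str) == self.variants["alt"].astype(str))
        if bad.any():
            raise ValueError(f"ref == alt for variant {self.variants.loc[bad, 'id'].iloc[0]!r}")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self) -> pd.Series:
        """Map variant id -> column index."""
        return pd.Series(np.arange(self.n_variants), index=self.variants["id"])

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset(self, *, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        d = self.dosages
        s = self.samples
        v = self.variants
        if sample_idx is not None:
            d = d[np.asarray(sample_idx)]
            s = s.iloc[np.asarray(sample_idx)]
        if variant_idx is not None:
            d = d[:, np.asarray(variant_idx)]
            v = v.iloc[np.asarray(variant_idx)]
        return GenotypeMatrix(d.copy(), v.copy(), s.copy())

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by 2 * alt frequency."""
        out = self.dosages.astype(np.float64).copy()
        fill = 2.0 * self.allele_freq()
        idx = np.where(np.isnan(out))
        out[idx] = fill[idx[1]]
        return out


def read_sample_map(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"IID", "SITE_ID"} <= set(df.columns):
        raise ValueError(f"{path}: sample map needs IID and SITE_ID columns")
    return pd.DataFrame({"id": df["IID"], "site_id": df["SITE_ID"]})


def write_sample_map(samples: pd.DataFrame, path: str) -> None:
    pd.DataFrame({"IID": samples["id"], "SITE_ID": samples["site_id"]}).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------- VCF

def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write genotypes as VCF v4.2 with GT fields (unphased)."""
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples["id"]) + "\n")
        dos = g.dosages
        for j, row in enumerate(g.variants.itertuples(index=False)):
            col = dos[:, j]
            gts = "\t".join(
                "./." if np.isnan(x) else gt_codes[int(x)] for x in col)
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path: str, sample_map: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (GT parsed as alt-allele count)."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    sample_ids = list(vcf.samples)
    rows = []
    dosage_cols = []
    seen: set[str] = set()
    for rec_no, var in enumerate(vcf, start=1):
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        if vid in seen:
            raise ValueError(f"{path} record {rec_no}: duplicate variant ID {vid!r}")
        seen.add(vid)
        if len(var.ALT) != 1:
            raise ValueError(f"{path} record {rec_no}: variant {vid!r} is not biallelic")
        rows.append((vid, str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
        # gts012: 0/1/2 = alt count, 3 = unknown
        gt = var.gt_types.astype(np.float32)
        gt[gt == 3] = np.nan
        dosage_cols.append(gt)
    vcf.close()
    if not rows:
        raise ValueError(f"{path}: no variant records")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = np.column_stack(dosage_cols).astype(np.float32)
    samples = _resolve_samples(sample_ids, sample_map, path)
    return GenotypeMatrix(dosages, variants, samples)


def _resolve_samples(sample_ids: list[str], sample_map: pd.DataFrame | None,
                     path: str) -> pd.DataFrame:
    if sample_map is None:
        return pd.DataFrame({"id": sample_ids, "site_id": ["NA"] * len(sample_ids)})
    lut = dict(zip(sample_map["id"], sample_map["site_id"]))
    missing = [s for s in sample_ids if s not in lut]
    if missing:
        raise ValueError(f"{path}: samples absent from sample map: {missing[:5]}")
    return pd.DataFrame({"id": sample_ids, "site_id": [lut[s] for s in sample_ids]})


# ---------------------------------------------------------------- matrix TSV

def write_matrix(g: GenotypeMatrix, path: str) -> None:
    """Dosage-matrix TSV: header of variant IDs, one row per individual."""
    with open(path, "w") as fh:
        fh.write("IID\t" + "\t".join(g.variants["id"]) + "\n")
        for i, iid in enumerate(g.samples["id"]):
            vals = ("NA" if np.isnan(x) else str(int(x)) for x in g.dosages[i])
            fh.write(iid + "\t" + "\t".join(vals) + "\n")


def read_matrix(path: str, variants: pd.DataFrame,
                sample_map: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read the dosage-matrix TSV dialect.

    ``variants`` supplies the metadata (id, chrom, pos, ref, alt) for the
    columns named in the header; the dialect itself carries IDs only.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.columns[0] != "IID":
        raise ValueError(f"{path} line 1: first column must be IID")
    ids = list(df.columns[1:])
    if len(set(ids)) != len(ids):
        dup = next(x for x in ids if ids.count(x) > 1)
        raise ValueError(f"{path} line 1: duplicate variant ID {dup!r}")
    meta = variants.set_index("id")
    unknown = [v for v in ids if v not in meta.index]
    if unknown:
        raise ValueError(f"{path} line 1: variants missing metadata: {unknown[:5]}")
    vmeta = meta.loc[ids].reset_index()[VARIANT_COLUMNS]
    dosages = df.iloc[:, 1:].to_numpy(dtype=np.float32)
    bad = ~(np.isnan(dosages) | np.isin(dosages, [0.0, 1.0, 2.0]))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"{path} line {i + 2}: invalid dosage {dosages[i, j]} "
                         f"for variant {ids[j]!r}")
    samples = _resolve_samples(list(df["IID"].astype(str)), sample_map, path)
    return GenotypeMatrix(dosages, vmeta, samples)


def read_genotypes(path: str, fmt: str = "auto",
                   sample_map: pd.DataFrame | None = None,
                   variants: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Dispatch on format: 'vcf', 'matrix', or 'auto' (by extension)."""
    if fmt == "auto":
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "matrix"
    if fmt == "vcf":
        return read_vcf(path, sample_map)
    if fmt == "matrix":
        if variants is None:
            raise ValueError("matrix format requires a variant metadata table")
        return read_matrix(path, variants, sample_map)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_genotypes(g: GenotypeMatrix, path: str, fmt: str = "auto") -> None:
    if fmt == "auto":
        fmt = "vcf" if path.endswith(".vcf") else "matrix"
    (write_vcf if fmt == "vcf" else write_matrix)(g, path)


# ---------------------------------------------------------------- sumstats / env / annotation

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "P"]


def write_sumstats(table: pd.DataFrame, path: str) -> None:
    out = pd.DataFrame({
        "SNP": table["id"], "CHR": table["chrom"], "BP": table["pos"],
        "A1": table["effect_allele"], "A2": table["other_allele"],
        "BETA": table["beta"], "P": table["p"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_sumstats(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sumstats columns {missing}")
    return pd.DataFrame({
        "id": df["SNP"].astype(str), "chrom": df["CHR"].astype(str),
        "pos": df["BP"].astype(int), "effect_allele": df["A1"].astype(str),
        "other_allele": df["A2"].astype(str),
        "beta": df["BETA"].astype(float), "p": df["P"].astype(float),
    })


def write_environment(env: pd.DataFrame, path: str) -> None:
    """Site x variable table; index holds site IDs."""
    env.to_csv(path, sep="\t", index_label="SITE_ID")


def read_environment(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="SITE_ID")


def write_annotation(genes: pd.DataFrame, eqtl: pd.DataFrame,
                     terms: pd.DataFrame, prefix: str) -> None:
    out = genes.copy()
    out["START"] = out["start"] + 1          # 1-based inclusive on disk
    pd.DataFrame({"GENE": out["gene"], "CHR": out["chrom"],
                  "START": out["START"], "END": out["end"]}).to_csv(
        prefix + ".genes.tsv", sep="\t", index=False)
    pd.DataFrame({"SNP": eqtl["snp"], "GENE": eqtl["gene"]}).to_csv(
        prefix + ".eqtl.tsv", sep="\t", index=False)
    pd.DataFrame({"GENE": terms["gene"], "TERM": terms["term"]}).to_csv(
        prefix + ".terms.tsv", sep="\t", index=False)


def read_annotation(prefix: str):
    from .enrich import AnnotationDB

    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t", dtype={"CHR": str})
    genes = pd.DataFrame({"gene": genes["GENE"], "chrom": genes["CHR"],
                          "start": genes["START"] - 1, "end": genes["END"]})
    eqtl = pd.read_csv(prefix + ".eqtl.tsv", sep="\t")
    eqtl = pd.DataFrame({"snp": eqtl["SNP"].astype(str), "gene": eqtl["GENE"]})
    terms = pd.read_csv(prefix + ".terms.tsv", sep="\t")
    terms = pd.DataFrame({"gene": terms["GENE"], "term": terms["TERM"]})
    return AnnotationDB(genes=genes, eqtl=eqtl, terms=terms)
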