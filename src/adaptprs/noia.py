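"""NOIA: genotype-frequency-orthogonal additive/dominance/epistasis model.

The statistical formulation of the natural and orthogonal interactions
model parameterizes single-locus effects so that, under the observed
genotype frequencies (f0, f1, f2) of the analyzed individuals, the additive
and dominance predictors are orthogonal to the intercept and to each other:

    x_a(g) = g - (f1 + 2 f2)
    x_d(0) = -2 f1 f2 / D,  x_d(1) = 4 f0 f2 / D,  x_d(2) = -2 f0 f1 / D
    with D = f0 + f2 - (f0 - f2)^2.

Multi-locus epistatic predictors (a x a, a x d, d x d, ...) are element-wise
products of the single-locus columns (the Kronecker structure of the
statistical formulation), orthogonal under linkage equilibrium. Fitting is
ordinary least squares of the (Box-Cox-transformed) environmental variable
on the NOIA design plus ancestry covariates; the additive test reports the
two-sided t-test p for each locus's additive term.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import ols_fit
from .popstruct import PCMatrix


@dataclass
class NOIADesign:
    loci: list[str]
    genotype_freqs: list[tuple[float, float, float]]
    design: np.ndarray                  # individuals x effects (no intercept)
    effect_names: list[str]
    kept_rows: np.ndarray               # indices of individuals retained


@dataclass
class NOIAFit:
    estimates: pd.DataFrame             # EFFECT, ESTIMATE, SE, T, P
    df_resid: int
    loci: list[str]


def _single_locus_columns(g: np.ndarray, label: str,
                          ) -> tuple[list[np.ndarray], list[str], tuple]:
    n = len(g)
    f0 = float(np.mean(g == 0))
    f1 = float(np.mean(g == 1))
    f2 = float(np.mean(g == 2))
    if f0 == 1.0 or f1 == 1.0 or f2 == 1.0:
        raise ValueError(f"locus {label} is monomorphic in the analyzed individuals")
    x_a = g - (f1 + 2.0 * f2)
    cols = [x_a]
    names = [f"a_{label}"]
    D = f0 + f2 - (f0 - f2) ** 2
    if abs(D) < 1e-12:
        warnings.warn(f"locus {label}: dominance scale D = 0 (degenerate genotype "
                      "pattern); dominance column omitted")
    else:
        vals = {0: -2.0 * f1 * f2 / D, 1: 4.0 * f0 * f2 / D, 2: -2.0 * f0 * f1 / D}
        x_d = np.vectorize(vals.get)(g.astype(int)).astype(float)
        cols.append(x_d)
        names.append(f"d_{label}")
    return cols, names, (f0, f1, f2)


def build_design(genotypes: np.ndarray, loci: list[str] | None = None,
                 max_order: int = 2, effects: str = "full") -> NOIADesign:
    """NOIA design for 1-3 loci from raw dosages (0/1/2, NaN missing).

    Individuals missing any modeled locus are dropped; genotype frequencies
    are computed on the retained individuals. ``effects='additive'`` omits
    dominance (and hence all dominance-bearing interactions); ``max_order``
    bounds the interaction order of the element-wise product terms.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, L = G.shape
    if not 1 <= L <= 3:
        raise ValueError(f"NOIA design supports 1-3 loci, got {L}")
    if loci is None:
        loci = [f"locus{j + 1}" for j in range(L)]
    keep = ~np.isnan(G).any(axis=1)
    G = G[keep]
    if len(G) == 0:
        raise ValueError("no individuals with complete genotypes")

    per_locus_cols: list[list[np.ndarray]] = []
    per_locus_names: list[list[str]] = []
    freqs = []
    for j in range(L):
        cols, names, f = _single_locus_columns(G[:, j], loci[j])
        if effects == "additive":
            cols, names = cols[:1], names[:1]
        per_locus_cols.append(cols)
        per_locus_names.append(names)
        freqs.append(f)

    design_cols = []
    design_names = []
    for order in range(1, min(max_order, L) + 1):
        for combo in itertools.combinations(range(L), order):
            for pick in itertools.product(*(range(len(per_locus_cols[j]))
                                            for j in combo)):
                col = np.ones(len(G))
                parts = []
                for j, c in zip(combo, pick):
                    col = col * per_locus_cols[j][c]
                    parts.append(per_locus_names[j][c])
                design_cols.append(col)
                design_names.append("x".join(parts))
    return NOIADesign(loci=list(loci), genotype_freqs=freqs,
                      design=np.column_stack(design_cols),
                      effect_names=design_names,
                      kept_rows=np.where(keep)[0])


def fit_noia(design: NOIADesign, phenotype: np.ndarray,
             covariates: PCMatrix | np.ndarray | None = None) -> NOIAFit:
    """OLS of the phenotype on [intercept, NOIA effects, covariates]."""
    y = np.asarray(phenotype, dtype=float)[design.kept_rows]
    n = len(y)
    cols = [np.ones(n), design.design]
    names = ["mean"] + design.effect_names
    if covariates is not None:
        C = covariates.scores if isinstance(covariates, PCMatrix) else np.asarray(covariates)
        C = np.atleast_2d(C)
        if C.shape[0] != len(design.kept_rows) and C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            C = C[design.kept_rows]
        cols.append(C)
        names += [f"cov{j + 1}" for j in range(C.shape[1])]
    X = np.column_stack(cols)
    fit = ols_fit(X, y, names=names)
    k = 1 + len(design.effect_names)
    est = pd.DataFrame({
        "EFFECT": names[:k], "ESTIMATE": fit.beta[:k], "SE": fit.se[:k],
        "T": fit.t[:k], "P": fit.p[:k],
    })
    return NOIAFit(estimates=est, df_resid=fit.df_resid, loci=design.loci)


def test_additive(fit: NOIAFit) -> pd.DataFrame:
    """Two-sided t-test p for each locus's additive effect."""
    t = fit.estimates
    mask = t["EFFECT"].str.fullmatch(r"a_.*")
    out = t[mask][["EFFECT", "ESTIMATE", "SE", "T", "P"]].copy()
    out["LOCUS"] = out["EFFECT"].str.removeprefix("a_")
    return out[["LOCUS", "ESTIMATE", "SE", "T", "P"]].reset_index(drop=True)
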