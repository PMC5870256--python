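"""Ancestry principal components on the LD-pruned genotype matrix.

Missing dosages are mean-imputed per variant; each variant is centred at
2*p and scaled by sqrt(2*p*(1-p)) (Patterson normalisation), so the
covariance eigenstructure reflects drift rather than allele-frequency scale.
Scores are the top-K left singular vectors scaled by their singular values,
with a deterministic sign convention (the largest-magnitude variant loading
is positive) so downstream regressions are reproducible run to run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix


@dataclass
class PCMatrix:
    scores: np.ndarray            # individuals x K
    explained_variance: np.ndarray  # fraction per component
    K: int
    sample_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{k + 1}": self.scores[:, k] for k in range(self.K)}
        return pd.DataFrame({"IID": self.sample_ids, **cols})


def compute_pcs(g: GenotypeMatrix, pruned_ids: list[str] | None, K: int) -> PCMatrix:
    """Top-K genotype principal components (Patterson normalisation)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if pruned_ids is not None:
        if len(pruned_ids) == 0:
            raise ValueError("pruned variant set is empty")
        idx = g.variant_index()
        g = g.subset(variant_idx=idx.loc[list(pruned_ids)].to_numpy())

    X = g.imputed()                       # mean imputation per variant
    p = X.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    ok = scale > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} zero-variance variants from PCA")
        X, p, scale = X[:, ok], p[ok], scale[ok]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic variants for PCA")
    Z = (X - 2.0 * p) / scale

    n, m = Z.shape
    # eigendecomposition of the n x n sample covariance (n << m here)
    C = (Z @ Z.T) / m
    evals, evecs = np.linalg.eigh(C)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    evals = np.clip(evals, 0.0, None)
    rank = int((evals > evals[0] * n * np.finfo(float).eps).sum()) if evals[0] > 0 else 0
    if rank == 0:
        raise ValueError("zero-variance genotype matrix: all individuals identical")
    if K > rank:
        raise ValueError(f"K={K} exceeds matrix rank {rank}")

    scores = evecs[:, :K] * np.sqrt(np.maximum(evals[:K] * m, 0.0))
    # sign convention: largest-magnitude variant loading positive
    for k in range(K):
        if evals[k] <= 0:
            continue
        loading = Z.T @ evecs[:, k]
        j = int(np.argmax(np.abs(loading)))
        if loading[j] < 0:
            scores[:, k] = -scores[:, k]
    explained = evals[:K] / evals.sum()
    return PCMatrix(scores=scores, explained_variance=explained, K=K,
                    sample_ids=list(g.samples["id"]))
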