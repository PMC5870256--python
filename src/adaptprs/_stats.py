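"""Shared numeric primitives: OLS with rank diagnostics and masked pairwise r2.

These are deliberately small, dependency-light routines: the association and
permutation machinery needs direct access to the QR factorisation (for
Frisch-Waugh-Lovell residualisation), and the LD routines need
pairwise-complete correlations over dosage matrices with missing entries,
neither of which maps cleanly onto a single statsmodels/numpy call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy import stats


@dataclass
class OLSResult:
    """Coefficients and inference for an ordinary least-squares fit."""

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int
    r_squared: float
    resid: np.ndarray
    names: list[str]


def ols_fit(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> OLSResult:
    """Fit y = X b by least squares with classical (homoskedastic) inference.

    Raises ``ValueError`` naming the collinear columns when the design is
    rank-deficient, including the design condition number in the message.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")

    # pivoted QR exposes which columns are linearly dependent
    Q, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(n, k) * np.finfo(np.float64).eps if diag[0] > 0 else 0.0
    rank = int(np.sum(diag > tol))
    if rank < k:
        bad = sorted(names[j] for j in piv[rank:])
        cond = np.linalg.cond(X)
        raise ValueError(
            f"rank-deficient design (rank {rank} < {k} columns, condition number "
            f"{cond:.3g}); collinear columns: {', '.join(bad)}"
        )

    beta_piv = scipy.linalg.solve_triangular(R, Q.T @ y)
    beta = np.empty(k)
    beta[piv] = beta_piv
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    Rinv = scipy.linalg.solve_triangular(R, np.eye(k))
    cov_piv = sigma2 * (Rinv @ Rinv.T)
    se = np.empty(k)
    se[piv] = np.sqrt(np.diag(cov_piv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(resid @ resid)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return OLSResult(beta=beta, se=se, t=t, p=p, df_resid=df, r_squared=r2,
                     resid=resid, names=list(names))


def orthonormal_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal column basis of X (for projection/residualisation)."""
    Q, R = np.linalg.qr(np.asarray(X, dtype=np.float64))
    keep = np.abs(np.diag(R)) > np.abs(R).max() * max(X.shape) * np.finfo(float).eps
    return Q[:, keep]


def pairwise_complete_r2(W: np.ndarray, min_pairs: int = 3) -> np.ndarray:
    """Pairwise squared Pearson correlation over complete pairs.

    ``W`` is observations x variables with NaN marking missing entries
    (composite LD on unphased dosages). Pairs with fewer than ``min_pairs``
    complete observations, or with zero variance on the complete subset,
    yield r2 = 0.
    """
    W = np.asarray(W, dtype=np.float64)
    M = np.isfinite(W)
    A = np.where(M, W, 0.0)
    Mf = M.astype(np.float64)
    C = Mf.T @ Mf                 # complete-pair counts
    S1 = A.T @ Mf                 # S1[i, j] = sum of x_i over pairs complete with x_j
    S2 = A.T @ A
    SQ = (A * A).T @ Mf
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = S1 / C
        cov = S2 / C - mu * mu.T
        var = SQ / C - mu ** 2    # var[i, j] = variance of x_i on overlap(i, j)
        denom = var * var.T
        r2 = np.where(denom > 0, cov ** 2 / denom, 0.0)
    r2[C < min_pairs] = 0.0
    np.fill_diagonal(r2, 1.0)
    return np.clip(r2, 0.0, 1.0)


def r2_one_vs_many(x: np.ndarray, Y: np.ndarray, min_pairs: int = 3) -> np.ndarray:
    """r2 between one dosage vector and each column of Y, pairwise complete."""
    x = np.asarray(x, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    mx = np.isfinite(x)
    MY = np.isfinite(Y)
    both = mx[:, None] & MY
    n = both.sum(axis=0).astype(np.float64)
    xz = np.where(mx, x, 0.0)
    Yz = np.where(MY, Y, 0.0)
    bf = both.astype(np.float64)
    sx = xz @ bf
    sy = (Yz * bf).sum(axis=0)
    sxx = (xz * xz) @ bf
    syy = (Yz * Yz * bf).sum(axis=0)
    sxy = xz @ (Yz * bf)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy / n - (sx / n) * (sy / n)
        vx = sxx / n - (sx / n) ** 2
        vy = syy / n - (sy / n) ** 2
        denom = vx * vy
        r2 = np.where(denom > 0, cov ** 2 / denom, 0.0)
    r2[n < min_pairs] = 0.0
    return np.clip(r2, 0.0, 1.0)
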