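"""PRS-environment association with ancestry adjustment and its validations.

Each environmental variable (a property of the sampling site, broadcast to
the individuals sampled there) is Box-Cox normalized and regressed on a
polygenic score plus the top ancestry principal components. The full test
grid is traits x variables x twelve inclusion thresholds; multiple testing
is handled by Benjamini-Hochberg FDR, and significant cells are validated by
permuting the score vector across individuals. Because the environment is
constant within a site, individual-level regression carries the site-level
pseudo-replication of the underlying design; an optional site-level
aggregation mode averages scores and components per site before fitting.

Supporting analyses: 10-vs-20-PC robustness comparison (Clogg-type
coefficient difference test), a driver analysis that conditions each member
of a correlated variable set on the others, and the Spearman correlation
matrix among environmental variables with Bonferroni flags.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import ols_fit, orthonormal_basis
from .popstruct import PCMatrix
from .prs import PRSMatrix


# ---------------------------------------------------------------- Box-Cox

@dataclass
class BoxCoxFit:
    lam: float
    shift: float
    loglik: float


def _boxcox_apply(y: np.ndarray, lam: float) -> np.ndarray:
    if abs(lam) < 1e-8:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def boxcox_transform(values: np.ndarray,
                     lam: float | None = None) -> tuple[BoxCoxFit, np.ndarray]:
    """Box-Cox power transform with profile-likelihood lambda.

    A shift of (1 - min) is added when the minimum is non-positive. Lambda
    maximizes the profile log-likelihood over [-5, 5] by golden-section
    search (tolerance 1e-5); |lambda| < 1e-8 is treated as the log transform.
    Passing ``lam`` skips the search.
    """
    y = np.asarray(values, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("constant input cannot be Box-Cox transformed")
    if len(np.unique(y)) < 5:
        warnings.warn("fewer than 5 distinct values; lambda is poorly identified")
    shift = 0.0 if y.min() > 0 else 1.0 - y.min()
    ys = y + shift
    if lam is None:
        lam = _golden_max(lambda l: stats.boxcox_llf(l, ys), -5.0, 5.0, tol=1e-5)
    if abs(lam) < 1e-8:
        lam = 0.0
    fit = BoxCoxFit(lam=lam, shift=shift, loglik=float(stats.boxcox_llf(lam, ys)))
    return fit, _boxcox_apply(ys, lam)


def _golden_max(f, a: float, b: float, tol: float = 1e-5) -> float:
    """Golden-section maximization on [a, b]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


# ---------------------------------------------------------------- single fit

@dataclass
class AssociationResult:
    trait: str
    variable: str
    pt: float
    n_snps: int
    z: float
    r2_incremental: float
    p: float
    beta: float
    se: float
    df_resid: int
    q: float | None = None
    perm_p: float | None = None
    best: bool = False


def broadcast_env(env: pd.DataFrame, samples: pd.DataFrame,
                  variable: str) -> np.ndarray:
    """Site-level variable propagated to individuals via their site_id."""
    if variable not in env.columns:
        raise ValueError(f"variable {variable!r} not in environment table")
    missing = set(samples["site_id"]) - set(env.index)
    if missing:
        raise ValueError(f"sites absent from environment table: {sorted(missing)}")
    return env.loc[samples["site_id"], variable].to_numpy(dtype=float)


def aggregate_by_site(values: np.ndarray, site_ids: pd.Series) -> np.ndarray:
    """Mean of an individual-level vector within each site (sites in first-
    appearance order). The site-level analysis mode averages the PRS and PC
    scores per site before fitting, removing the pseudo-replication that the
    individual-level design inherits from broadcasting a site-level
    environment to individuals."""
    v = np.asarray(values, dtype=float)
    df = pd.DataFrame({"site": np.asarray(site_ids), "v": v})
    order = list(dict.fromkeys(df["site"]))
    means = df.groupby("site", sort=False)["v"].mean()
    return means.loc[order].to_numpy()


def _covariate_design(n: int, pcs: PCMatrix | None,
                      extra: np.ndarray | None) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(n)]
    names = ["intercept"]
    if pcs is not None:
        for k in range(pcs.K):
            cols.append(pcs.scores[:, k])
            names.append(f"PC{k + 1}")
    if extra is not None:
        extra = np.atleast_2d(np.asarray(extra, dtype=float))
        if extra.shape[0] != n:
            extra = extra.T
        for j in range(extra.shape[1]):
            cols.append(extra[:, j])
            names.append(f"extra{j + 1}")
    return np.column_stack(cols), names


def fit_prs_env(prs_column: np.ndarray, env_values: np.ndarray,
                pcs: PCMatrix | None = None,
                extra_covariates: np.ndarray | None = None,
                trait: str = "trait", variable: str = "env",
                pt: float = float("nan"), n_snps: int = 0) -> AssociationResult:
    """OLS of (transformed) environment on [intercept, PRS, PCs, extras].

    z is the t-statistic of the PRS coefficient; r2_incremental is the R2
    difference against the covariates-only model.
    """
    y = np.asarray(env_values, dtype=float)
    x = np.asarray(prs_column, dtype=float)
    n = len(y)
    Xcov, names = _covariate_design(n, pcs, extra_covariates)
    X = np.column_stack([Xcov[:, :1], x, Xcov[:, 1:]])
    full = ols_fit(X, y, names=["intercept", "PRS"] + names[1:])
    reduced = ols_fit(Xcov, y, names=names) if Xcov.shape[1] > 1 else None
    r2_red = reduced.r_squared if reduced is not None else 0.0
    r2_inc = max(full.r_squared - r2_red, 0.0)
    return AssociationResult(
        trait=trait, variable=variable, pt=pt, n_snps=n_snps,
        z=float(full.t[1]), r2_incremental=float(r2_inc), p=float(full.p[1]),
        beta=float(full.beta[1]), se=float(full.se[1]),
        df_resid=full.df_resid)


# ---------------------------------------------------------------- grid

def run_grid(prs_by_trait: dict[str, PRSMatrix], env: pd.DataFrame,
             samples: pd.DataFrame, pcs: PCMatrix | None,
             variables: list[str] | None = None,
             boxcox: bool = True, site_level: bool = False) -> pd.DataFrame:
    """Fit every (trait, variable, PT) cell; flag the best (smallest p)
    cell per trait-variable pair. Returns a tidy grid DataFrame.

    ``site_level=True`` averages scores and principal components within each
    site and fits at site resolution (one observation per site); the default
    individual-level fit preserves the site-broadcast design of the source
    analysis, including its pseudo-replication.
    """
    if variables is None:
        variables = list(env.columns)
    if site_level:
        sites = samples["site_id"]
        pcs_used = PCMatrix(
            scores=np.column_stack([
                aggregate_by_site(pcs.scores[:, k], sites)
                for k in range(pcs.K)]),
            explained_variance=pcs.explained_variance, K=pcs.K,
            sample_ids=list(dict.fromkeys(sites))) if pcs is not None else None
    else:
        pcs_used = pcs
    rows = []
    for variable in variables:
        y_raw = broadcast_env(env, samples, variable)
        if site_level:
            y_raw = aggregate_by_site(y_raw, samples["site_id"])
        y = boxcox_transform(y_raw)[1] if boxcox else y_raw
        for trait, prs in prs_by_trait.items():
            for j, pt in enumerate(prs.thresholds):
                x = prs.scores[:, j]
                if site_level:
                    x = aggregate_by_site(x, samples["site_id"])
                try:
                    res = fit_prs_env(x, y, pcs_used,
                                      trait=trait, variable=variable,
                                      pt=pt, n_snps=int(prs.n_snps[j]))
                except ValueError as exc:
                    raise ValueError(
                        f"grid cell trait={trait} variable={variable} "
                        f"PT={pt:g}: {exc}") from exc
                rows.append(res)
    grid = pd.DataFrame([{
        "trait": r.trait, "variable": r.variable, "pt": r.pt,
        "n_snps": r.n_snps, "z": r.z, "r2_incremental": r.r2_incremental,
        "p": r.p, "beta": r.beta, "se": r.se,
    } for r in rows])
    grid["best"] = False
    for (_, _), sub in grid.groupby(["trait", "variable"], sort=False):
        grid.loc[sub["p"].idxmin(), "best"] = True
    return grid


def fdr_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def add_q(grid: pd.DataFrame, scope: str = "all_cells") -> pd.DataFrame:
    """Attach BH q-values over all grid cells or only the best cells.

    With ``best_cells`` scope, non-best cells get q = NaN: the correction
    family is the per-pair best associations.
    """
    out = grid.copy()
    if scope == "all_cells":
        out["q"] = fdr_adjust(out["p"].to_numpy())
    elif scope == "best_cells":
        out["q"] = np.nan
        mask = out["best"].to_numpy()
        out.loc[mask, "q"] = fdr_adjust(out.loc[mask, "p"].to_numpy())
    else:
        raise ValueError(f"unknown FDR scope {scope!r}")
    return out


# ---------------------------------------------------------------- permutation

@dataclass
class PermutationResult:
    perm_p: float
    z_obs: float
    null_z: np.ndarray
    degenerate: bool = False


def permutation_null(prs_column: np.ndarray, env_values: np.ndarray,
                     pcs: PCMatrix | None = None,
                     extra_covariates: np.ndarray | None = None,
                     B: int = 10_000, seed: int = 0) -> PermutationResult:
    """Permutation null for one cell: shuffle the score across individuals.

    The environment and covariates stay fixed; each permutation refits the
    model (via Frisch-Waugh-Lovell residualisation, algebraically identical
    to the full OLS t-statistic) and records the PRS z. The add-one
    estimator perm_p = (1 + #{|z_b| >= |z_obs|}) / (B + 1) avoids zero
    p-values.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 100:
        warnings.warn(f"B={B} permutations is very small; p resolution is 1/{B + 1}")
    y = np.asarray(env_values, dtype=float)
    x = np.asarray(prs_column, dtype=float)
    n = len(y)
    if np.ptp(x) == 0:
        return PermutationResult(perm_p=1.0, z_obs=float("nan"),
                                 null_z=np.full(B, np.nan), degenerate=True)
    Xcov, _ = _covariate_design(n, pcs, extra_covariates)
    Q = orthonormal_basis(Xcov)
    k_cov = Q.shape[1]
    df = n - k_cov - 1
    y_res = y - Q @ (Q.T @ y)
    ynorm = float(np.sqrt(y_res @ y_res))

    def z_of(xvec: np.ndarray) -> float:
        x_res = xvec - Q @ (Q.T @ xvec)
        xnorm = float(np.sqrt(x_res @ x_res))
        if xnorm == 0 or ynorm == 0:
            return 0.0
        r = float(x_res @ y_res) / (xnorm * ynorm)
        r = min(max(r, -1.0), 1.0)
        denom = max(1.0 - r * r, np.finfo(float).tiny)
        return r * math.sqrt(df) / math.sqrt(denom)

    z_obs = z_of(x)
    rng = np.random.default_rng(seed)
    null_z = np.empty(B)
    for b in range(B):
        null_z[b] = z_of(x[rng.permutation(n)])
    # tolerance so permutations tied with the observed statistic in exact
    # arithmetic (e.g. order reversals) count as ties despite float error
    tol = 1e-9 * max(1.0, abs(z_obs))
    perm_p = (1.0 + np.sum(np.abs(null_z) >= abs(z_obs) - tol)) / (B + 1.0)
    return PermutationResult(perm_p=float(perm_p), z_obs=z_obs, null_z=null_z)


# ---------------------------------------------------------------- PC robustness

@dataclass
class PCComparison:
    beta10: float
    se10: float
    beta20: float
    se20: float
    statistic: float
    p: float


def compare_pc_models(prs_column: np.ndarray, env_values: np.ndarray,
                      pcs_small: PCMatrix, pcs_large: PCMatrix,
                      eps: float = 1e-12) -> PCComparison:
    """Clogg-type test for a PRS-coefficient difference between nested
    covariate sets (e.g., 10 vs 20 ancestry PCs).

    statistic = (b_small - b_large) / sqrt(|se_large^2 - se_small^2| + eps),
    referred to the standard normal (two-sided).
    """
    fit_s = fit_prs_env(prs_column, env_values, pcs_small)
    fit_l = fit_prs_env(prs_column, env_values, pcs_large)
    denom = math.sqrt(abs(fit_l.se ** 2 - fit_s.se ** 2) + eps)
    stat = (fit_s.beta - fit_l.beta) / denom
    p = 2.0 * stats.norm.sf(abs(stat))
    return PCComparison(beta10=fit_s.beta, se10=fit_s.se,
                        beta20=fit_l.beta, se20=fit_l.se,
                        statistic=float(stat), p=float(p))


# ---------------------------------------------------------------- driver analysis

def driver_analysis(prs_column: np.ndarray, env: pd.DataFrame,
                    samples: pd.DataFrame, candidate_vars: list[str],
                    pcs: PCMatrix | None = None,
                    boxcox: bool = True) -> pd.DataFrame:
    """Condition each correlated variable on the remaining set members.

    For each candidate v, refit the PRS association on v with the other
    candidates as extra covariates; the driver is the candidate whose PRS
    term retains p < 0.05. A single candidate reduces to the plain fit.
    """
    if len(candidate_vars) < 1:
        raise ValueError("need at least one candidate variable")
    transformed = {}
    for v in candidate_vars:
        raw = broadcast_env(env, samples, v)
        transformed[v] = boxcox_transform(raw)[1] if boxcox else raw
    if len(candidate_vars) > 1:
        M = np.column_stack([transformed[v] for v in candidate_vars])
        M = (M - M.mean(axis=0)) / M.std(axis=0)
        cond = np.linalg.cond(M)
        if cond > 1e8:
            raise ValueError(
                f"candidate variables are (near-)collinear: condition number "
                f"{cond:.3g} among {candidate_vars}")
    rows = []
    for v in candidate_vars:
        others = [w for w in candidate_vars if w != v]
        extra = (np.column_stack([transformed[w] for w in others])
                 if others else None)
        res = fit_prs_env(prs_column, transformed[v], pcs,
                          extra_covariates=extra, variable=v)
        rows.append({"variable": v, "z": res.z, "p": res.p,
                     "beta": res.beta, "se": res.se,
                     "conditioned_on": ",".join(others),
                     "driver": res.p < 0.05})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- Spearman

def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumeration over all permutations (n <= 9)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        rp = ry[list(perm)]
        r = np.corrcoef(rx, rp)[0, 1]
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def spearman_matrix(env: pd.DataFrame, alpha: float = 0.05,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho among environmental variables.

    Average ranks for ties; exact two-sided p (full enumeration) for
    n <= 9 sites, t-approximation otherwise; Bonferroni flags over the
    upper triangle at family level ``alpha``. Constant variables yield
    NaN rho and are flagged by a warning.
    """
    if len(env) < 4:
        raise ValueError("need at least 4 sites for Spearman correlations")
    cols = list(env.columns)
    m = len(cols)
    rho = pd.DataFrame(np.eye(m), index=cols, columns=cols)
    pmat = pd.DataFrame(np.ones((m, m)), index=cols, columns=cols)
    flags = pd.DataFrame(np.zeros((m, m), dtype=bool), index=cols, columns=cols)
    n_pairs = m * (m - 1) // 2
    n = len(env)
    for i in range(m):
        for j in range(i + 1, m):
            x = env[cols[i]].to_numpy(dtype=float)
            y = env[cols[j]].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"constant variable in pair ({cols[i]}, {cols[j]}); "
                              "rho undefined")
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(x, y)
                if n <= 9:
                    p = _exact_spearman_p(x, y, r)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
            sig = bool(np.isfinite(p) and p * n_pairs < alpha)
            flags.iloc[i, j] = flags.iloc[j, i] = sig
    return rho, pmat, flags
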