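"""Box-Cox, the PRS-environment fit against closed-form OLS, BH FDR against
a brute-force step-up, permutation nulls against exhaustive enumeration,
PC-model comparison, driver analysis and Spearman matrices."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from adaptprs.assoc import (aggregate_by_site, boxcox_transform,
                            compare_pc_models, driver_analysis, fdr_adjust,
                            fit_prs_env, permutation_null, run_grid,
                            spearman_matrix)
from adaptprs.popstruct import PCMatrix


def make_pcs(scores):
    scores = np.asarray(scores, dtype=float)
    return PCMatrix(scores=scores, explained_variance=np.ones(scores.shape[1]),
                    K=scores.shape[1],
                    sample_ids=[str(i) for i in range(len(scores))])


class TestBoxCox:
    def test_lambda_one_is_shifted_identity(self):
        y = np.array([1.0, 2.0, 3.0, 4.5, 7.0])
        fit, t = boxcox_transform(y, lam=1.0)
        np.testing.assert_allclose(t, y - 1.0)

    def test_lambda_zero_is_log(self):
        y = np.array([1.0, 2.0, 3.0, 4.5, 7.0])
        fit, t = boxcox_transform(y, lam=0.0)
        np.testing.assert_allclose(t, np.log(y), atol=1e-12)

    def test_lognormal_recovers_lambda_near_zero(self):
        rng = np.random.default_rng(0)
        y = np.exp(rng.standard_normal(500))
        fit, _ = boxcox_transform(y)
        assert -0.2 <= fit.lam <= 0.2

    def test_matches_scipy_optimizer(self):
        rng = np.random.default_rng(1)
        y = rng.gamma(2.0, 1.5, size=400)
        fit, _ = boxcox_transform(y)
        _, lam_scipy = stats.boxcox(y)
        assert fit.lam == pytest.approx(lam_scipy, abs=1e-3)

    def test_nonpositive_values_shifted(self):
        y = np.array([-3.0, -1.0, 0.0, 2.0, 5.0])
        fit, t = boxcox_transform(y)
        assert fit.shift == 4.0
        assert np.isfinite(t).all()

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            boxcox_transform(np.ones(10))


class TestFit:
    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(2)
        n = 50
        x = rng.standard_normal(n)
        pcs = make_pcs(rng.standard_normal((n, 2)))
        y = 0.4 * x + pcs.scores @ [0.2, -0.1] + rng.standard_normal(n)
        res = fit_prs_env(x, y, pcs)
        X = sm.add_constant(np.column_stack([x, pcs.scores]))
        ref = sm.OLS(y, X).fit()
        assert res.z == pytest.approx(ref.tvalues[1], abs=1e-8)
        assert res.p == pytest.approx(ref.pvalues[1], abs=1e-8)
        red = sm.OLS(y, sm.add_constant(pcs.scores)).fit()
        assert res.r2_incremental == pytest.approx(
            ref.rsquared - red.rsquared, abs=1e-10)

    def test_orthogonal_prs_gives_zero(self):
        n = 40
        rng = np.random.default_rng(3)
        y = rng.standard_normal(n)
        y -= y.mean()
        x = rng.standard_normal(n)
        x -= x.mean()
        x -= (x @ y) / (y @ y) * y     # exactly orthogonal to y and intercept
        res = fit_prs_env(x, y)
        assert abs(res.beta) < 1e-10
        assert res.r2_incremental < 1e-10

    def test_env_equals_prs_r2_one(self):
        x = np.arange(30, dtype=float)
        res = fit_prs_env(x, x.copy())
        assert res.r2_incremental == pytest.approx(1.0)

    def test_collinear_design_rejected(self):
        n = 30
        rng = np.random.default_rng(4)
        x = rng.standard_normal(n)
        pcs = make_pcs(np.column_stack([x, rng.standard_normal(n)]))
        with pytest.raises(ValueError, match="collinear"):
            fit_prs_env(x, rng.standard_normal(n), pcs)


class TestFDR:
    @staticmethod
    def brute_force_bh(p):
        """Quadratic-time step-up: q_i = min over j with p_j >= p_i of
        m * p_j / rank_j."""
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            q[i] = running
        return q

    def test_single_p(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal(self):
        q = fdr_adjust([0.2, 0.2, 0.2])
        np.testing.assert_allclose(q, 0.2)

    def test_printed_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = int(rng.integers(1, 400))
            p = rng.random(m)
            np.testing.assert_allclose(fdr_adjust(p), self.brute_force_bh(p),
                                       atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 0.0])


class TestPermutation:
    def test_observed_extreme_gives_min_p(self):
        rng = np.random.default_rng(6)
        n = 30
        x = np.linspace(0, 1, n)
        y = x * 10 + rng.standard_normal(n) * 1e-3
        res = permutation_null(x, y, B=199, seed=1)
        assert res.perm_p == pytest.approx(1.0 / 200.0)

    def test_constant_prs_degenerate(self):
        res = permutation_null(np.ones(20), np.random.default_rng(7).standard_normal(20),
                               B=100, seed=2)
        assert res.degenerate
        assert res.perm_p == 1.0

    def test_matches_exhaustive_enumeration_n4(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([0.3, -0.5, 1.1, 0.9])

        def tstat(xv):
            X = sm.add_constant(xv)
            return sm.OLS(y, X).fit().tvalues[1]

        z_obs = abs(tstat(x))
        exact_hits = sum(abs(tstat(np.array(p))) >= z_obs - 1e-12
                         for p in itertools.permutations(x))
        exact_p = exact_hits / 24
        res = permutation_null(x, y, B=4000, seed=3)
        mc_se = np.sqrt(exact_p * (1 - exact_p) / 4000)
        assert res.perm_p == pytest.approx(exact_p, abs=2 * mc_se + 2 / 4001)

    def test_fwl_z_equals_full_ols_z(self):
        rng = np.random.default_rng(8)
        n = 25
        x = rng.standard_normal(n)
        pcs = make_pcs(rng.standard_normal((n, 3)))
        y = rng.standard_normal(n)
        res = permutation_null(x, y, pcs, B=1, seed=4)
        ref = fit_prs_env(x, y, pcs)
        assert res.z_obs == pytest.approx(ref.z, abs=1e-10)

    def test_tiny_b_rejected_and_warned(self):
        with pytest.raises(ValueError):
            permutation_null(np.arange(5.0), np.arange(5.0), B=0)
        with pytest.warns(UserWarning, match="very small"):
            permutation_null(np.arange(10.0),
                             np.random.default_rng(0).standard_normal(10), B=50)


class TestPCComparison:
    def test_identical_sets_give_zero(self):
        rng = np.random.default_rng(9)
        n = 40
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        pcs = make_pcs(rng.standard_normal((n, 3)))
        c = compare_pc_models(x, y, pcs, pcs)
        assert c.statistic == pytest.approx(0.0, abs=1e-10)
        assert c.p == pytest.approx(1.0)

    def test_orthogonal_extra_pcs_leave_beta(self):
        rng = np.random.default_rng(10)
        n = 60
        x = rng.standard_normal(n)
        base = rng.standard_normal((n, 2))
        y = 0.5 * x + rng.standard_normal(n)
        # extra columns orthogonal to everything in the model
        M = np.column_stack([np.ones(n), x, base, y])
        Q, _ = np.linalg.qr(np.column_stack([M, rng.standard_normal((n, 2))]))
        extra = Q[:, -2:]
        c = compare_pc_models(x, y, make_pcs(base),
                              make_pcs(np.column_stack([base, extra])))
        assert c.beta10 == pytest.approx(c.beta20, abs=1e-10)

    def test_confounder_on_extra_pc_detected(self):
        rng = np.random.default_rng(11)
        n = 500
        conf = rng.standard_normal(n)
        x = conf + 0.3 * rng.standard_normal(n)
        y = 2.0 * conf + 0.3 * rng.standard_normal(n)
        base = rng.standard_normal((n, 2))
        c = compare_pc_models(x, y, make_pcs(base),
                              make_pcs(np.column_stack([base, conf])))
        assert c.p < 0.01


class TestDriver:
    def test_planted_driver_vs_proxy(self):
        """The true driver keeps p < 0.05 when conditioned on a 0.9-correlated
        proxy; the proxy mostly does not."""
        rng = np.random.default_rng(12)
        wins_driver, wins_proxy = 0, 0
        n_sites, n_per = 23, 20
        reps = 60
        for _ in range(reps):
            driver = rng.standard_normal(n_sites)
            proxy = 0.9 * driver + np.sqrt(1 - 0.81) * rng.standard_normal(n_sites)
            sites = np.repeat([f"S{k}" for k in range(n_sites)], n_per)
            x = np.repeat(driver, n_per) * 0.8 + rng.standard_normal(n_sites * n_per)
            env = pd.DataFrame({"driver": driver, "proxy": proxy},
                               index=pd.Index([f"S{k}" for k in range(n_sites)],
                                              name="SITE_ID"))
            samples = pd.DataFrame({"id": np.arange(len(sites)).astype(str),
                                    "site_id": sites})
            out = driver_analysis(x, env, samples, ["driver", "proxy"],
                                  boxcox=False)
            res = out.set_index("variable")
            wins_driver += res.loc["driver", "p"] < 0.05
            wins_proxy += res.loc["proxy", "p"] < 0.05
        assert wins_driver / reps >= 0.8
        assert wins_proxy / reps < wins_driver / reps

    def test_single_variable_reduces_to_plain_fit(self):
        rng = np.random.default_rng(13)
        sites = [f"S{k}" for k in range(8)]
        env = pd.DataFrame({"v": rng.standard_normal(8)},
                           index=pd.Index(sites, name="SITE_ID"))
        samples = pd.DataFrame({"id": list("abcdefgh"), "site_id": sites})
        x = rng.standard_normal(8)
        out = driver_analysis(x, env, samples, ["v"], boxcox=False)
        ref = fit_prs_env(x, env["v"].to_numpy())
        assert out["p"].iloc[0] == pytest.approx(ref.p)

    def test_perfect_collinearity_rejected(self):
        rng = np.random.default_rng(14)
        sites = [f"S{k}" for k in range(10)]
        v = rng.standard_normal(10)
        env = pd.DataFrame({"a": v, "b": 2 * v},
                           index=pd.Index(sites, name="SITE_ID"))
        samples = pd.DataFrame({"id": [str(i) for i in range(10)],
                                "site_id": sites})
        with pytest.raises(ValueError, match="collinear|condition"):
            driver_analysis(rng.standard_normal(10), env, samples, ["a", "b"],
                            boxcox=False)


class TestSpearman:
    def frame(self, data):
        return pd.DataFrame(data)

    def test_monotone_pair_is_one(self):
        env = self.frame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 9, 16, 30]})
        rho, p, flags = spearman_matrix(env)
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_ties_match_rank_then_pearson(self):
        env = self.frame({"a": [1.0, 2, 2, 3, 4], "b": [5.0, 3, 3, 2, 2]})
        rho, _, _ = spearman_matrix(env)
        ra = stats.rankdata(env["a"])
        rb = stats.rankdata(env["b"])
        expect = np.corrcoef(ra, rb)[0, 1]
        assert rho.loc["a", "b"] == pytest.approx(expect, abs=1e-12)

    def test_exact_small_n_p_matches_enumeration_probability(self):
        rng = np.random.default_rng(15)
        env = self.frame({"a": rng.standard_normal(6),
                          "b": rng.standard_normal(6)})
        rho, p, _ = spearman_matrix(env)
        # independent recount of the permutation tail
        ra = stats.rankdata(env["a"])
        rb = stats.rankdata(env["b"])
        obs = abs(np.corrcoef(ra, rb)[0, 1])
        hits = sum(abs(np.corrcoef(ra, np.array(perm))[0, 1]) >= obs - 1e-12
                   for perm in itertools.permutations(rb))
        assert p.loc["a", "b"] == pytest.approx(hits / 720)

    def test_bonferroni_flag(self):
        rng = np.random.default_rng(16)
        n = 40
        base = rng.standard_normal(n)
        data = {f"v{j}": rng.standard_normal(n) for j in range(4)}
        data["w"] = base
        data["x"] = base + 0.1 * rng.standard_normal(n)
        env = self.frame(data)
        rho, p, flags = spearman_matrix(env)
        m = 15  # 6 variables -> 15 pairs
        assert flags.loc["w", "x"]
        assert p.loc["w", "x"] * m < 0.05

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            spearman_matrix(self.frame({"a": [1.0, 2, 3], "b": [3.0, 2, 1]}))


def test_aggregate_by_site_means():
    v = np.array([1.0, 3.0, 10.0, 20.0, 5.0])
    sites = pd.Series(["A", "A", "B", "B", "C"])
    np.testing.assert_allclose(aggregate_by_site(v, sites), [2.0, 15.0, 5.0])


def test_run_grid_bookkeeping(null_sim):
    from adaptprs.prs import SummaryStats, build_prs
    from adaptprs.qc import qc_filter
    from adaptprs.popstruct import compute_pcs
    from adaptprs.assoc import add_q

    g, _ = qc_filter(null_sim.genotypes)
    pcs = compute_pcs(g, None, 3)
    prs_by = {}
    for t in ["t1", "t2"]:
        tab = null_sim.sumstats["trait1"]
        ss = SummaryStats(tab[["id", "chrom", "pos", "effect_allele",
                               "other_allele", "beta", "p"]], trait=t)
        prs_by[t], _, _ = build_prs(ss, g)
    grid = run_grid(prs_by, null_sim.environment.iloc[:, :3], g.samples, pcs)
    assert len(grid) == 2 * 3 * 12
    assert grid["best"].sum() == 6
    # determinism under fixed inputs
    grid2 = run_grid(prs_by, null_sim.environment.iloc[:, :3], g.samples, pcs)
    pd.testing.assert_frame_equal(grid, grid2)
    for scope in ("all_cells", "best_cells"):
        q = add_q(grid, scope)
        sub = q["q"].dropna()
        assert ((sub > 0) & (sub <= 1)).all()
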