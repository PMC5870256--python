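"""Hypergeometric enrichment against exhaustive draw enumeration, SNP
selection rules, property matching tolerances and the matched-set null."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from adaptprs.enrich import (AnnotationDB, SNPSet, empirical_enrichment_null,
                             hypergeom_enrich, match_snps, select_prs_snps,
                             snp_properties, snps_to_genes)


def tiny_db(n_genes=20, term_genes=None, extra_terms=None):
    genes = pd.DataFrame({
        "gene": [f"g{i}" for i in range(n_genes)],
        "chrom": "1",
        "start": np.arange(n_genes) * 10_000,
        "end": np.arange(n_genes) * 10_000 + 5_000,
    })
    eqtl = pd.DataFrame({"snp": [f"s{i}" for i in range(n_genes)],
                         "gene": [f"g{i}" for i in range(n_genes)]})
    rows = []
    for g in (term_genes or []):
        rows.append((g, "T1"))
    for g, t in (extra_terms or []):
        rows.append((g, t))
    terms = pd.DataFrame(rows, columns=["gene", "term"])
    return AnnotationDB(genes=genes, eqtl=eqtl, terms=terms)


class TestHypergeom:
    def test_query_equals_universe_all_p_one(self):
        db = tiny_db(term_genes=["g0", "g1", "g2"])
        res = hypergeom_enrich(set(db.genes["gene"]), db)
        assert (res.table["P"] == 1.0).all()

    def test_zero_overlap_p_one(self):
        db = tiny_db(term_genes=["g0", "g1"])
        res = hypergeom_enrich({"g5", "g6"}, db)
        assert res.table["P"].iloc[0] == 1.0

    def test_matches_exhaustive_draw_enumeration(self):
        # N=20, K=5, n=5: count draws with >= k term genes over all C(20,5)
        db = tiny_db(term_genes=[f"g{i}" for i in range(5)])
        query = {"g0", "g1", "g2", "g3", "g10"}   # k = 4
        res = hypergeom_enrich(query, db)
        hits = 0
        total = 0
        for combo in itertools.combinations(range(20), 5):
            k = sum(1 for i in combo if i < 5)
            hits += k >= 4
            total += 1
        assert total == math.comb(20, 5)
        assert res.table["P"].iloc[0] == pytest.approx(hits / total, rel=1e-10)

    def test_exact_combinatoric_oracle_small_universes(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(2, 26))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            db = tiny_db(n_genes=N, term_genes=[f"g{i}" for i in range(K)])
            query = {f"g{i}" for i in rng.choice(N, size=n, replace=False)}
            res = hypergeom_enrich(query, db)
            k = len(query & {f"g{i}" for i in range(K)})
            expect = sum(math.comb(K, j) * math.comb(N - K, n - j)
                         for j in range(k, min(K, n) + 1)) / math.comb(N, n)
            assert res.table["P"].iloc[0] == pytest.approx(expect, rel=1e-9)

    def test_empty_universe_rejected(self):
        db = tiny_db(term_genes=["g0"])
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrich({"g0"}, db, background_snps=["nonexistent"])


class TestSelection:
    def build(self, small_sim):
        from adaptprs.assoc import boxcox_transform, broadcast_env
        from adaptprs.popstruct import compute_pcs
        from adaptprs.prs import SummaryStats, build_prs
        from adaptprs.qc import qc_filter

        g, _ = qc_filter(small_sim.genotypes)
        pcs = compute_pcs(g, None, 5)
        tab = small_sim.sumstats["trait1"]
        ss = SummaryStats(tab[["id", "chrom", "pos", "effect_allele",
                               "other_allele", "beta", "p"]], trait="t")
        prsm, cr, indexed = build_prs(ss, g)
        y = boxcox_transform(broadcast_env(
            small_sim.environment, g.samples, "win_min_temp"))[1]
        return g, pcs, prsm, indexed, y

    def test_selected_set_enriched_for_causal_variants(self, small_sim):
        from adaptprs.assoc import fit_prs_env

        g, pcs, prsm, indexed, y = self.build(small_sim)
        pt = 0.05
        cell = fit_prs_env(prsm.column(pt), y, pcs)
        snpset = select_prs_snps(g, indexed, pt, np.sign(cell.z), y, pcs)
        assert snpset.snps
        truth = small_sim.truth
        causal = set(truth.variants.loc[truth.causal[0], "id"])
        cand = set(indexed.table.loc[indexed.table["p"] <= pt, "id"])
        sel = set(snpset.snps)
        in_rate = len(sel & causal) / len(sel)
        base_rate = len(cand & causal) / len(cand)
        # odds-ratio style comparison against the candidate background
        odds = (in_rate / (1 - in_rate + 1e-12)) / (base_rate / (1 - base_rate))
        assert odds >= 2.0

    def test_concordance_rule(self, toy_factory):
        """A strongly associated SNP is kept only when its target-cohort
        direction agrees with the GWAS direction times the cell sign."""
        from adaptprs.prs import SummaryStats

        rng = np.random.default_rng(1)
        n = 200
        x = rng.integers(0, 3, n).astype(np.float32)
        g = toy_factory(x[:, None])
        y = 0.5 * x + rng.standard_normal(n) * 0.5
        tab = pd.DataFrame({
            "id": ["v0"], "chrom": ["1"], "pos": [1000],
            "effect_allele": ["G"], "other_allele": ["A"],
            "beta": [0.3], "p": [1e-6],
        })
        indexed = SummaryStats(tab, trait="t")
        kept = select_prs_snps(g, indexed, 0.05, +1.0, y, None)
        assert kept.snps == ["v0"]
        with pytest.warns(UserWarning):
            dropped = select_prs_snps(g, indexed, 0.05, -1.0, y, None)
        assert dropped.snps == []


class TestProperties:
    def test_properties_on_toy_layout(self, toy_factory):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(100, 3)).astype(np.float32)
        d[:, 1] = d[:, 0]          # perfect buddy pair
        g = toy_factory(d, pos=[50_000, 60_000, 380_000])
        genes = pd.DataFrame({"gene": ["gA", "gB"], "chrom": ["1", "1"],
                              "start": [40_000, 300_000],
                              "end": [45_000, 310_000]})
        db = AnnotationDB(genes=genes,
                          eqtl=pd.DataFrame({"snp": ["v0"], "gene": ["gA"]}),
                          terms=pd.DataFrame({"gene": ["gA"], "term": ["T"]}))
        props = snp_properties(g, db).set_index("snp")
        assert props.loc["v0", "gene_density"] == 1      # gA within 100 kb
        assert props.loc["v0", "dist_nearest_gene"] == 50_000 - 45_000
        assert props.loc["v0", "ld_buddies"] == 1        # v1 duplicates v0
        assert props.loc["v2", "gene_density"] == 1      # gB within 100 kb
        assert props.loc["v2", "dist_nearest_gene"] == 380_000 - 1 - 310_000 + 1
        assert props.loc["v2", "ld_buddies"] == 0
        # intragenic SNP: inside gB
        g2 = toy_factory(d, pos=[50_000, 60_000, 305_000])
        props2 = snp_properties(g2, db).set_index("snp")
        assert props2.loc["v2", "dist_nearest_gene"] == 0


class TestMatching:
    def background_props(self, n=200, seed=3):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "snp": [f"b{i}" for i in range(n)],
            "maf": rng.uniform(0.05, 0.5, n),
            "gene_density": rng.integers(1, 8, n),
            "dist_nearest_gene": rng.integers(0, 50_000, n),
            "ld_buddies": rng.integers(0, 10, n),
        })

    def input_set(self, bg):
        props = bg.iloc[:5].copy()
        props["snp"] = [f"q{i}" for i in range(5)]
        return SNPSet(snps=list(props["snp"]), properties=props)

    def test_matched_sets_respect_tolerances(self):
        bg = self.background_props()
        inp = self.input_set(bg)
        sets = match_snps(inp, bg, n_sets=20, seed=4)
        assert len(sets) == 20
        for s in sets:
            assert len(s.snps) == 5
            assert len(set(s.snps)) == 5       # without replacement
            for (_, want), (_, got) in zip(inp.properties.iterrows(),
                                           s.properties.iterrows()):
                assert abs(got["maf"] - want["maf"]) <= 0.05 + 1e-12
                for prop, slack0 in (("gene_density", 0.0),
                                     ("dist_nearest_gene", 5000.0),
                                     ("ld_buddies", 1.0)):
                    x = want[prop]
                    margin = 0.5 * x if x > 0 else slack0
                    assert abs(got[prop] - x) <= margin + 1e-9

    def test_infinite_tolerances_uniform_draws(self):
        bg = self.background_props()
        inp = self.input_set(bg)
        tol = {"maf": np.inf, "gene_density": np.inf,
               "dist_nearest_gene": np.inf, "ld_buddies": np.inf}
        sets = match_snps(inp, bg, tolerances=tol, n_sets=50, seed=5)
        seen = {s for st in sets for s in st.snps}
        assert len(seen) > 100       # draws spread over the background

    def test_no_candidates_errors_and_relax_helps(self):
        bg = self.background_props()
        props = pd.DataFrame({
            "snp": ["q0"], "maf": [0.25], "gene_density": [3],
            "dist_nearest_gene": [10_000], "ld_buddies": [200]})
        inp = SNPSet(snps=["q0"], properties=props)
        with pytest.raises(ValueError, match="q0"):
            match_snps(inp, bg, n_sets=5, seed=6)

    def test_deterministic_and_background_order_independent(self):
        bg = self.background_props()
        inp = self.input_set(bg)
        a = match_snps(inp, bg, n_sets=10, seed=7)
        b = match_snps(inp, bg.sample(frac=1, random_state=9), n_sets=10, seed=7)
        assert [s.snps for s in a] == [s.snps for s in b]


class TestEmpiricalNull:
    def fake_result(self, qvals):
        table = pd.DataFrame({"TERM": [f"T{i}" for i in range(len(qvals))],
                              "K": 1, "k": 1, "N": 10, "n": 5,
                              "P": qvals, "Q": qvals})
        return type("R", (), {"table": table,
                              "significant_terms":
                              lambda self, q_max=0.05: list(
                                  table.loc[table["Q"] < q_max, "TERM"])})()

    def test_observed_exceeds_all(self):
        obs = self.fake_result([0.01, 0.02, 0.5])
        matched = [self.fake_result([0.5, 0.9]) for _ in range(100)]
        out = empirical_enrichment_null(obs, matched)
        assert out["empirical_p"] == pytest.approx(1 / 101)

    def test_observed_zero_gives_one(self):
        obs = self.fake_result([0.5])
        matched = [self.fake_result([0.9]) for _ in range(50)]
        out = empirical_enrichment_null(obs, matched)
        assert out["empirical_p"] == 1.0


def test_snps_to_genes_union():
    db = tiny_db(term_genes=["g0"])
    assert snps_to_genes(["s0", "s3"], db) == {"g0", "g3"}
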