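import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from pathherit.errors import AnalysisError, ParameterError
from pathherit.io import PathwayDB
from pathherit.pathway import (
    adjust_gene_scores,
    bh_fdr,
    bonferroni,
    gene_min_p,
    grass_gene_eigensnps,
    grass_pathway_test,
    magenta_enrichment,
)

from conftest import make_geno


class TestBhFdr:
    def test_stepup_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        # direct step-up arithmetic: q_i = min_{j >= i} p_(j) * n / j
        n = len(p)
        srt = np.sort(p)
        oracle = [min(srt[j] * n / (j + 1) for j in range(i, n)) for i in range(n)]
        got = bh_fdr(p)
        np.testing.assert_allclose(got, oracle)
        np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_capped_at_one(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_against_statsmodels(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_fdr(p), ref, atol=1e-12)

    def test_elementwise_at_least_input(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        assert (bh_fdr(p) >= p - 1e-15).all()

    def test_empty(self):
        assert bh_fdr([]).size == 0

    def test_domain_check(self):
        with pytest.raises(ParameterError):
            bh_fdr([1.5])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_properties_hold_for_any_input(self, p):
        p = np.asarray(p)
        q = bh_fdr(p)
        assert (q <= 1.0).all()
        assert (q >= p - 1e-12).all()
        # monotone: sorted p gives sorted q
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)


class TestBonferroni:
    def test_replication_five_tests(self):
        assert bonferroni(9.90e-3, 5) == pytest.approx(4.95e-2)

    def test_cap(self):
        assert bonferroni(0.3, 5) == 1.0

    def test_nine_tests_three_sigfig(self):
        got = float(bonferroni(2.59e-3, 9))
        assert float(f"{got:.3g}") == pytest.approx(2.33e-2)

    def test_elementwise_at_least_input(self):
        p = np.array([0.001, 0.2, 0.9])
        assert (bonferroni(p, 3) >= p).all()

    def test_bad_n(self):
        with pytest.raises(ParameterError):
            bonferroni(0.1, 0)


def _gene_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


class TestGeneMinP:
    def test_minimum(self):
        summary = pd.DataFrame({"P": [0.2, 0.01, 0.5]})
        genes = _gene_frame([("g", "1", 1, 3000)])
        out = gene_min_p(summary, {"g": np.array([0, 1, 2])}, genes)
        assert out["min_p"].iloc[0] == pytest.approx(0.01)

    def test_single_snp_identity(self):
        summary = pd.DataFrame({"P": [0.42]})
        genes = _gene_frame([("g", "1", 1, 100)])
        out = gene_min_p(summary, {"g": np.array([0])}, genes)
        assert out["min_p"].iloc[0] == pytest.approx(0.42)

    def test_three_by_three_bruteforce(self):
        pvals = [0.5, 0.03, 0.9, 0.2, 0.11, 0.45, 0.08, 0.77, 0.6]
        summary = pd.DataFrame({"P": pvals})
        gmap = {
            "g0": np.array([0, 1, 2]),
            "g1": np.array([3, 4, 5]),
            "g2": np.array([6, 7, 8]),
        }
        genes = _gene_frame([(f"g{i}", "1", 1, 1000) for i in range(3)])
        out = gene_min_p(summary, gmap, genes).set_index("gene_id")
        for g, idx in gmap.items():
            oracle = min(pvals[i] for i in idx)
            assert out.loc[g, "min_p"] == pytest.approx(oracle)

    def test_empty_genes_dropped_and_counted(self):
        summary = pd.DataFrame({"P": [0.1]})
        genes = _gene_frame([("a", "1", 1, 10), ("b", "1", 20, 30)])
        out = gene_min_p(summary, {"a": np.array([0])}, genes)
        assert len(out) == 1 and out.attrs["n_dropped"] == 1

    def test_all_empty_rejected(self):
        summary = pd.DataFrame({"P": [0.1]})
        genes = _gene_frame([("a", "1", 1, 10)])
        with pytest.raises(AnalysisError):
            gene_min_p(summary, {}, genes)


class TestAdjustGeneScores:
    def _table(self, min_p, n_snps, kb):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(min_p))],
                "min_p": min_p,
                "n_snps": n_snps,
                "length_kb": kb,
            }
        )

    def test_identical_sizes_keep_raw_ranking(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=40)
        with pytest.warns(UserWarning):
            out = adjust_gene_scores(self._table(p, [5] * 40, [10.0] * 40))
        raw_rank = np.argsort(np.argsort(p))
        adj_rank = np.argsort(np.argsort(out["adj_p"].to_numpy()))
        np.testing.assert_array_equal(raw_rank, adj_rank)

    def test_snp_count_penalised_under_minp_inflation(self):
        # null where min-p shrinks with SNP count: a big gene with the same
        # raw p as a small one must get the worse adjusted p
        rng = np.random.default_rng(3)
        n_snps = rng.integers(1, 200, size=98)
        min_p = np.array([rng.uniform(size=k).min() for k in n_snps])
        tab = self._table(
            np.concatenate([min_p, [0.01, 0.01]]),
            np.concatenate([n_snps, [100, 10]]),
            np.concatenate([n_snps * 1.0, [100.0, 10.0]]),
        )
        out = adjust_gene_scores(tab).set_index("gene_id")
        big, small = out.loc["g98", "adj_p"], out.loc["g99", "adj_p"]
        assert big > small

    def test_rank_formula(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.1, 1.0, size=99)
        p[7] = 1e-9  # clear best gene
        out = adjust_gene_scores(self._table(p, [3] * 99, [5.0] * 99))
        assert out["adj_p"].min() == pytest.approx(1 / 100)
        assert out["adj_p"].iloc[7] == pytest.approx(0.01)

    def test_too_few_genes(self):
        with pytest.raises(ParameterError):
            adjust_gene_scores(self._table([0.1] * 10, [1] * 10, [1.0] * 10))


class TestMagenta:
    def _adjusted(self, n_genes, seed=0):
        rng = np.random.default_rng(seed)
        adj = rng.permutation(np.arange(1, n_genes + 1)) / (n_genes + 1)
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n_genes)], "adj_p": adj}
        )

    def test_maximal_enrichment(self):
        adjusted = self._adjusted(1000, seed=5)
        best = adjusted.nsmallest(10, "adj_p")["gene_id"]
        db = PathwayDB(pathways={"top": set(best)})
        out = magenta_enrichment(adjusted, db, n_null=1000, seed=6)
        row = out.iloc[0]
        assert row["obs_count"] == row["eff_gene_size"] == 10
        assert row["p"] == pytest.approx(1 / 1001)

    def test_expected_count_arithmetic(self):
        adjusted = self._adjusted(400, seed=7)
        members = set(adjusted["gene_id"].iloc[:8])
        db = PathwayDB(pathways={"pw": members})
        out = magenta_enrichment(adjusted, db, cutoff_pct=95, n_null=1000, seed=8)
        assert out["exp_count"].iloc[0] == pytest.approx(0.4)

    def test_null_calibration(self):
        # 200 random pathways under a global null: p roughly uniform.
        # large pathways keep the count statistic from being too discrete
        adjusted = self._adjusted(2000, seed=9)
        rng = np.random.default_rng(10)
        genes = adjusted["gene_id"].to_numpy()
        db = PathwayDB(
            pathways={
                f"pw{k}": set(rng.choice(genes, size=100, replace=False))
                for k in range(200)
            }
        )
        out = magenta_enrichment(adjusted, db, n_null=1000, seed=11)
        frac = (out["p"] <= 0.05).mean()
        assert 0.02 <= frac <= 0.09

    def test_monotone_invariance_of_observed(self):
        adjusted = self._adjusted(300, seed=12)
        db = PathwayDB(pathways={"pw": set(adjusted["gene_id"].iloc[:15])})
        out1 = magenta_enrichment(adjusted, db, n_null=1000, seed=13)
        squashed = adjusted.copy()
        squashed["adj_p"] = np.sqrt(squashed["adj_p"])  # monotone transform
        out2 = magenta_enrichment(squashed, db, n_null=1000, seed=13)
        assert out1["obs_count"].iloc[0] == out2["obs_count"].iloc[0]

    def test_unmapped_pathway_skipped(self):
        adjusted = self._adjusted(100, seed=14)
        db = PathwayDB(pathways={"ok": {"g1", "g2"}, "ghost": {"zzz"}})
        with pytest.warns(UserWarning, match="ghost"):
            out = magenta_enrichment(adjusted, db, n_null=1000, seed=15)
        assert list(out["pathway"]) == ["ok"]


class TestEigenSnps:
    def test_identical_columns_single_component(self):
        rng = np.random.default_rng(16)
        col = rng.integers(0, 3, size=50).astype(float)
        g = make_geno(np.column_stack([col, col, col]))
        comps = grass_gene_eigensnps(g, [0, 1, 2], var_explained=0.95)
        assert comps.shape[1] == 1

    def test_orthogonal_snps_no_compression(self):
        # two exactly uncorrelated columns
        x1 = np.array([0, 0, 2, 2, 0, 0, 2, 2], dtype=float)
        x2 = np.array([0, 2, 0, 2, 0, 2, 0, 2], dtype=float)
        assert abs(np.corrcoef(x1, x2)[0, 1]) < 1e-12
        g = make_geno(np.column_stack([x1, x2]))
        comps = grass_gene_eigensnps(g, [0, 1], var_explained=0.95)
        assert comps.shape[1] == 2

    def test_cumulative_variance_oracle(self):
        rng = np.random.default_rng(17)
        g = make_geno(rng.integers(0, 3, size=(80, 5)).astype(float))
        comps = grass_gene_eigensnps(g, range(5), var_explained=0.95)
        Z = g.standardized()
        Zc = (g.dosages - g.dosages.mean(0)) / g.dosages.std(0)
        evals = np.sort(np.linalg.eigvalsh(Zc.T @ Zc))[::-1]
        k = comps.shape[1]
        assert evals[:k].sum() / evals.sum() >= 0.95
        if k > 1:
            assert evals[: k - 1].sum() / evals.sum() < 0.95

    def test_monomorphic_gene_rejected(self):
        g = make_geno(np.full((10, 2), 2.0))
        with pytest.raises(AnalysisError):
            grass_gene_eigensnps(g, [0, 1])


class TestGrassTest:
    def test_observed_exceeds_all_perms(self):
        # strong signal, tiny n_perm: p = (0+1)/(B+1)
        rng = np.random.default_rng(18)
        n = 200
        x = rng.integers(0, 3, size=(n, 4)).astype(float)
        y = (x[:, 0] + rng.standard_normal(n) * 0.2 > 1).astype(float)
        g = make_geno(x)
        res = grass_pathway_test(
            g, y, None, {"g0": np.arange(4)}, n_perm=99, seed=19, penalty=1.0
        )
        assert res.p == pytest.approx(1 / 100)

    def test_single_class_rejected(self):
        g = make_geno(np.random.default_rng(20).integers(0, 3, (60, 3)).astype(float))
        with pytest.raises(AnalysisError):
            grass_pathway_test(g, np.ones(60), None, {"g": np.arange(3)},
                               n_perm=99, seed=0)

    def test_power_small_scale(self):
        # a pathway whose single gene carries a SNP explaining ~5% of a
        # continuous-liability-driven binary trait is detected
        rng = np.random.default_rng(21)
        hits = 0
        reps = 10
        for r in range(reps):
            n = 1000
            x = rng.integers(0, 3, size=(n, 6)).astype(float)
            liab = 0.45 * (x[:, 0] - x[:, 0].mean()) + rng.standard_normal(n)
            y = (liab > np.quantile(liab, 0.5)).astype(float)
            g = make_geno(x)
            res = grass_pathway_test(
                g, y, None, {"g0": np.arange(6)}, n_perm=999, seed=r, penalty=1.0
            )
            hits += res.p <= 0.001
        assert hits >= 9
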