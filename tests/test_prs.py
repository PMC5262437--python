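import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathherit.errors import AnalysisError, ParameterError
from pathherit.prs import (
    auc,
    build_bin_matrix,
    clump,
    compute_prs,
    logistic_eval,
    nagelkerke_r2,
    prs_bin_lmm,
    weights_from_summary,
)
from pathherit.vc import GRM

from conftest import make_geno


def _weights(snps, alleles, ws, ps):
    return pd.DataFrame({"SNP": snps, "A1": alleles, "weight": ws, "P": ps})


class TestWeights:
    def test_log_or(self):
        summ = pd.DataFrame(
            {"SNP": ["s0"], "A1": ["A"], "OR": [1.5], "P": [0.1]}
        )
        w = weights_from_summary(summ)
        assert w["weight"].iloc[0] == pytest.approx(np.log(1.5))

    def test_beta_fallback(self):
        summ = pd.DataFrame(
            {"SNP": ["s0"], "A1": ["A"], "BETA": [0.3], "P": [0.1]}
        )
        assert weights_from_summary(summ)["weight"].iloc[0] == pytest.approx(0.3)

    def test_nonfinite_rejected(self):
        summ = pd.DataFrame({"SNP": ["s0"], "A1": ["A"], "OR": [0.0], "P": [0.1]})
        with pytest.raises(ParameterError):
            weights_from_summary(summ)


class TestClump:
    def test_uncorrelated_all_kept(self):
        rng = np.random.default_rng(0)
        g = make_geno(rng.integers(0, 3, size=(200, 4)).astype(float))
        summ = pd.DataFrame(
            {"SNP": [f"s{i}" for i in range(4)], "P": [0.4, 0.1, 0.3, 0.2]}
        )
        kept = clump(summ, g, r2_threshold=0.25, window_kb=10)
        assert set(kept) == {"s0", "s1", "s2", "s3"}

    def test_perfect_proxy_smaller_p_kept(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=100).astype(float)
        g = make_geno(np.column_stack([col, col]))
        summ = pd.DataFrame({"SNP": ["s0", "s1"], "P": [0.5, 0.01]})
        kept = clump(summ, g, r2_threshold=0.25, window_kb=10)
        assert kept == ["s1"]

    def test_hand_executed_greedy(self):
        # 4 SNPs: s0-s1 perfectly correlated, s2 = noisy copy of s0, s3 indep
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, size=400).astype(float)
        noise = rng.integers(0, 3, size=400).astype(float)
        s2col = np.where(rng.random(400) < 0.8, a, noise)
        d = rng.integers(0, 3, size=400).astype(float)
        g = make_geno(np.column_stack([a, a, s2col, d]))
        p = [0.2, 0.01, 0.05, 0.5]
        summ = pd.DataFrame({"SNP": [f"s{i}" for i in range(4)], "P": p})
        # hand-executed greedy at r2 > 0.25 within the window:
        # pick s1 (p=.01) -> removes s0 (r2=1) and s2 (r2~0.5); pick s3
        r_s1s2 = np.corrcoef(a, s2col)[0, 1] ** 2
        assert r_s1s2 > 0.25
        kept = clump(summ, g, r2_threshold=0.25, window_kb=10)
        assert kept == ["s1", "s3"]

    def test_window_limits_removal(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 3, size=100).astype(float)
        g = make_geno(np.column_stack([col, col]),
                      positions=[1, 2_000_000])
        summ = pd.DataFrame({"SNP": ["s0", "s1"], "P": [0.5, 0.01]})
        kept = clump(summ, g, r2_threshold=0.25, window_kb=250)
        assert set(kept) == {"s0", "s1"}  # proxy outside the window survives


class TestComputePrs:
    def test_zero_weights(self, tiny_geno):
        w = _weights(["s0", "s1"], ["A", "A"], [0.0, 0.0], [0.01, 0.01])
        scores, used = compute_prs(tiny_geno, w, 1.0)
        np.testing.assert_array_equal(scores, 0.0)
        assert used == 2

    def test_hand_arithmetic_cutoff(self):
        g = make_geno([[2.0, 1.0, 0.0]])
        w = _weights(
            ["s0", "s1", "s2"],
            ["A", "A", "A"],
            [np.log(1.2), np.log(0.8), np.log(1.5)],
            [0.1, 0.3, 0.6],
        )
        scores, used = compute_prs(g, w, p_cutoff=0.2)
        assert used == 1
        assert scores[0] == pytest.approx(2 * np.log(1.2))
        assert scores[0] == pytest.approx(0.3646, abs=2e-4)

    def test_no_filtering_matches_matrix_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 3, size=(30, 8)).astype(float)
        g = make_geno(X)
        ws = rng.standard_normal(8)
        w = _weights([f"s{i}" for i in range(8)], ["A"] * 8, ws,
                     rng.uniform(size=8))
        scores, used = compute_prs(g, w, p_cutoff=1.0)
        np.testing.assert_allclose(scores, X @ ws)
        assert used == 8

    def test_allele_flip(self):
        g = make_geno([[2.0], [0.0]])
        w = _weights(["s0"], ["G"], [1.0], [0.01])  # panel a2 -> flip
        scores, _ = compute_prs(g, w, 1.0)
        np.testing.assert_allclose(scores, [0.0, 2.0])

    def test_mismatched_allele_dropped(self):
        g = make_geno([[2.0]])
        w = _weights(["s0"], ["T"], [1.0], [0.01])
        with pytest.warns(UserWarning, match="dropped"):
            scores, used = compute_prs(g, w, 1.0)
        assert used == 0 and scores[0] == 0.0

    def test_cutoff_subset_difference(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(50, 20)).astype(float)
        g = make_geno(X)
        ps = rng.uniform(size=20)
        ws = rng.standard_normal(20)
        w = _weights([f"s{i}" for i in range(20)], ["A"] * 20, ws, ps)
        c1, c2 = 0.3, 0.7
        s1, _ = compute_prs(g, w, c1)
        s2, _ = compute_prs(g, w, c2)
        between = (ps > c1) & (ps <= c2)
        oracle = X[:, between] @ ws[between]
        np.testing.assert_allclose(s2 - s1, oracle)


class TestLogisticEval:
    def test_constant_prs_zero_delta(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, size=100).astype(float)
        out = logistic_eval(y, np.ones(100), rng.standard_normal((100, 2)))
        assert out.delta_r2 == 0.0

    def test_nagelkerke_hand_example(self):
        # n=4, y=(1,1,0,0), full probs (.9,.8,.2,.1), null probs all .5
        l1 = np.log(0.9 * 0.8 * 0.8 * 0.9)
        l0 = np.log(0.5**4)
        assert nagelkerke_r2(l1, l0, 4) == pytest.approx(0.8704, abs=1e-4)

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        n = 300
        prs = rng.standard_normal(n)
        y = (prs + rng.standard_normal(n) > 0).astype(float)
        cov = rng.standard_normal((n, 2))
        a = logistic_eval(y, prs, cov)
        b = logistic_eval(y, 3.5 * prs - 11.0, cov)
        assert a.delta_r2 == pytest.approx(b.delta_r2, abs=1e-8)
        assert a.p_prs == pytest.approx(b.p_prs, rel=1e-6)

    def test_permutation_null_vs_signal(self):
        rng = np.random.default_rng(8)
        n = 400
        signal = rng.standard_normal(n)
        y = (0.8 * signal + rng.standard_normal(n) > 0).astype(float)
        true_delta = logistic_eval(y, signal, None).delta_r2
        null_deltas = [
            logistic_eval(y, rng.permutation(signal), None).delta_r2
            for _ in range(200)
        ]
        assert np.percentile(null_deltas, 95) < true_delta
        assert np.median(null_deltas) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(AnalysisError):
            logistic_eval(np.ones(50), np.random.default_rng(9).random(50), None)


class TestAuc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        assert auc(np.array([1.0, 2.0, 3.0, 4.0]), y) == 1.0

    def test_all_ties(self):
        y = np.array([0, 1, 0, 1])
        assert auc(np.ones(4), y) == 0.5

    def test_pair_enumeration_oracle(self):
        # cases (2, 3), controls (1, 2.5): pairs win, lose, win, win -> 0.75
        y = np.array([1, 1, 0, 0])
        s = np.array([2.0, 3.0, 1.0, 2.5])
        assert auc(s, y) == 0.75

    def test_complement_identity(self):
        rng = np.random.default_rng(10)
        s = rng.standard_normal(100)  # tie-free w.p. 1
        y = rng.integers(0, 2, size=100)
        y[0], y[1] = 0, 1
        assert auc(s, y) + auc(-s, y) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(AnalysisError):
            auc(np.arange(4.0), np.zeros(4))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_complement_identity_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        s = rng.standard_normal(n)
        y = np.zeros(n, dtype=int)
        y[: max(1, n // 3)] = 1
        a = auc(s, y)
        assert 0.0 <= a <= 1.0
        assert a + auc(-s, y) == pytest.approx(1.0)


class TestBinMatrix:
    def test_hand_binning(self):
        S, bins = build_bin_matrix(np.array([1.0, 2.0, 3.0, 4.0]), 2)
        expected = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float
        )
        np.testing.assert_array_equal(S, expected)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        prs = rng.standard_normal(20)
        S, _ = build_bin_matrix(prs, 4)
        perm = rng.permutation(20)
        S2, _ = build_bin_matrix(prs[perm], 4)
        np.testing.assert_array_equal(S2, S[np.ix_(perm, perm)])

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(12)
        S, _ = build_bin_matrix(rng.standard_normal(30), 5)
        evals = np.linalg.eigvalsh(S)
        assert evals.min() > -1e-10

    def test_guards(self):
        prs = np.arange(10.0)
        with pytest.raises(ParameterError):
            build_bin_matrix(prs, 1)
        with pytest.raises(ParameterError):
            build_bin_matrix(prs, 6)  # B > n/2
        with pytest.raises(ParameterError):
            build_bin_matrix(prs, 10)  # B = n

    def test_diagonal_ones(self):
        S, _ = build_bin_matrix(np.random.default_rng(13).random(24), 6)
        np.testing.assert_array_equal(np.diag(S), 1.0)


def _bin_phenotype(n, B, var_bin, seed):
    rng = np.random.default_rng(seed)
    prs = rng.standard_normal(n)
    S, bins = build_bin_matrix(prs, B)
    effects = rng.standard_normal(B) * np.sqrt(var_bin)
    y = effects[bins] + rng.standard_normal(n) * np.sqrt(1 - var_bin)
    return prs, S, bins, y


class TestPrsBinLmm:
    def test_null_proportion_near_zero(self):
        rng = np.random.default_rng(14)
        props, ps = [], []
        for seed in range(8):
            prs, S, _, _ = _bin_phenotype(300, 10, 0.0, seed)
            y = rng.standard_normal(300)
            res = prs_bin_lmm(y, None, {"bin": S})
            props.append(res[0].proportion)
            ps.append(res[0].p_lrt)
        assert np.median(props) < 0.05
        assert 0.2 <= np.median(ps) <= 0.8

    def test_recovery_of_bin_variance(self):
        hits = 0
        reps = 10
        for seed in range(reps):
            _, S, _, y = _bin_phenotype(800, 20, 0.05, 100 + seed)
            res = prs_bin_lmm(y, None, {"bin": S})
            hits += abs(res[0].proportion - 0.05) < 2 * res[0].se
        assert hits >= 8

    def test_joint_with_grm_additive_construction(self):
        rng = np.random.default_rng(15)
        n = 600
        Zg = rng.standard_normal((n, 500))
        A = Zg @ Zg.T / 500
        grm = GRM(values=A, ids=[str(i) for i in range(n)], n_snps=500)
        prs = rng.standard_normal(n)
        S, bins = build_bin_matrix(prs, 20)
        g = Zg @ rng.standard_normal(500) * np.sqrt(0.25 / 500)
        b = rng.standard_normal(20)[bins] * np.sqrt(0.10)
        y = g + b + rng.standard_normal(n) * np.sqrt(0.65)
        res = prs_bin_lmm(y, None, {"bin": S}, grm=grm)
        by_name = {r.name: r for r in res}
        assert abs(by_name["bin"].proportion - 0.10) < 2.5 * by_name["bin"].se
        assert abs(by_name["grm"].proportion - 0.25) < 2.5 * by_name["grm"].se
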