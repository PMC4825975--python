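"""Exact-test and Monte-Carlo machinery against independent oracles."""

import math

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from oligoheart.stats import (
    PermutationResult,
    ValidationError,
    carrier_table,
    fisher_exact,
    hypergeom_upper,
    montecarlo_geneset_p,
    negative_control_contrast,
)


def tail_oracle(k, K, n, N):
    """Exhaustive upper tail by direct binomial-coefficient enumeration."""
    denom = math.comb(N, n)
    lo = max(0, n - (N - K))
    return sum(math.comb(K, x) * math.comb(N - K, n - x) for x in range(max(k, lo), min(K, n) + 1)) / denom


def twotail_oracle(a, b, c, d):
    """Probability-ordering two-tailed Fisher by enumeration."""
    N, K, n = a + b + c + d, a + c, a + b
    denom = math.comb(N, n)
    lo = max(0, n - (N - K))
    pmf = {x: math.comb(K, x) * math.comb(N - K, n - x) / denom for x in range(lo, min(K, n) + 1)}
    obs = pmf[a]
    return sum(p for p in pmf.values() if p <= obs * (1 + 1e-9))


class TestHypergeomUpper:
    def test_zero_successes_is_certain(self):
        assert hypergeom_upper(0, 3, 3, 10) == pytest.approx(1.0)

    def test_small_enumeration_example(self):
        # (C(3,2)C(7,1)+C(3,3)) / C(10,3) = 22/120
        assert hypergeom_upper(2, 3, 3, 10) == pytest.approx(22 / 120, rel=1e-12)

    def test_full_draw_forces_all_marked(self):
        # drawing the whole population always captures the K marked items
        assert hypergeom_upper(3, 3, 10, 10) == pytest.approx(1.0)

    def test_impossible_configuration_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_upper(5, 3, 3, 10)
        with pytest.raises(ValidationError):
            hypergeom_upper(1, 11, 3, 10)

    def test_tail_complement_identity(self):
        # P(X>=k) + P(X<=k) = 1 + P(X=k), enumerated for a grid of designs
        rng = np.random.default_rng(1)
        for _ in range(200):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            lo = max(0, n - (N - K))
            k = int(rng.integers(lo, min(K, n) + 1))
            upper = hypergeom_upper(k, K, n, N)
            lower = tail_oracle(lo, K, n, N) - tail_oracle(k + 1, K, n, N) if k < min(K, n) else 1.0
            point = tail_oracle(k, K, n, N) - tail_oracle(k + 1, K, n, N)
            assert upper + lower == pytest.approx(1.0 + point, abs=1e-10)


class TestFisherExact:
    def test_known_gene_carrier_contrast(self):
        # 18 carriers of 59 cases vs 1 of 59 controls
        assert fisher_exact([[18, 41], [1, 58]], "one_tailed") == pytest.approx(9.60e-06, rel=1e-3)

    def test_degenerate_margins_warn_and_return_one(self):
        with pytest.warns(UserWarning):
            assert fisher_exact([[0, 59], [0, 59]]) == 1.0

    def test_single_carrier_two_tailed_is_one(self):
        # 1 vs 0 carriers in 59 vs 59: the observed table is the most probable
        assert fisher_exact([[1, 58], [0, 59]], "two_tailed") == pytest.approx(1.0)
        assert twotail_oracle(1, 58, 0, 59) == pytest.approx(1.0)

    def test_matches_enumeration_exhaustive_small(self):
        for N in range(2, 26):
            for K in range(1, N):
                for n in range(1, N):
                    lo = max(0, n - (N - K))
                    for a in range(lo, min(K, n) + 1):
                        table = [[a, n - a], [K - a, N - K - n + a]]
                        assert fisher_exact(table, "one_tailed") == pytest.approx(
                            tail_oracle(a, K, n, N), rel=1e-9, abs=1e-300
                        )

    def test_matches_enumeration_random_to_sixty(self):
        rng = np.random.default_rng(2)
        for _ in range(400):
            N = int(rng.integers(4, 61))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            lo = max(0, n - (N - K))
            a = int(rng.integers(lo, min(K, n) + 1))
            table = [[a, n - a], [K - a, N - K - n + a]]
            assert fisher_exact(table, "one_tailed") == pytest.approx(tail_oracle(a, K, n, N), rel=1e-9)
            assert fisher_exact(table, "two_tailed") == pytest.approx(
                twotail_oracle(*table[0], *table[1]), rel=1e-6
            )

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            t = rng.integers(0, 25, size=4)
            if t[0] + t[2] in (0, t.sum()) or t[0] + t[1] in (0, t.sum()):
                continue
            table = [[int(t[0]), int(t[1])], [int(t[2]), int(t[3])]]
            assert fisher_exact(table, "one_tailed") == pytest.approx(
                scipy_fisher(table, alternative="greater").pvalue, rel=1e-8
            )
            assert fisher_exact(table, "two_tailed") == pytest.approx(
                scipy_fisher(table).pvalue, rel=1e-6
            )

    def test_margin_symmetry(self):
        # equal group sizes: p(k carriers in A) mirrors p(M-k) by enumeration
        M, n = 10, 30
        for k in range(M + 1):
            p1 = tail_oracle(k, M, n, 2 * n)
            p2 = tail_oracle(M - k, M, n, 2 * n)
            t1 = fisher_exact([[k, n - k], [M - k, n - M + k]], "one_tailed")
            assert t1 == pytest.approx(p1, rel=1e-9)
            assert p1 + p2 >= 1.0  # tails overlap at the shared point mass


class TestMonteCarloGenesetP:
    @staticmethod
    def _incidence(seed=0, n_genes=300, rate_case=0.01, rate_ctrl=0.01, n=40):
        rng = np.random.default_rng(seed)
        return rng.random((n, n_genes)) < rate_case, rng.random((n, n_genes)) < rate_ctrl

    def test_empirical_p_formula_and_floor(self):
        # target with all case signal in a large universe: replicates almost
        # never redraw the signal genes, so the observed p is unbeaten
        case = np.zeros((30, 100_000), bool)
        case[:, :3] = True
        ctrl = np.zeros((30, 100_000), bool)
        res = montecarlo_geneset_p(case, ctrl, np.arange(3), n_perm=999, seed=0)
        assert res.r == 0
        assert res.empirical_p == pytest.approx(1 / 1000)
        assert res.empirical_p == (res.r + 1) / (res.n + 1)

    def test_all_replicates_as_extreme_gives_one(self):
        case, ctrl = self._incidence()
        # an empty target is never beaten: its p is 1, every replicate ties
        res = montecarlo_geneset_p(case, ctrl, np.arange(3), n_perm=99, seed=1)
        assert res.empirical_p <= 1.0
        assert res.empirical_p >= 1 / 100
        assert res.empirical_p == (res.r + 1) / (res.n + 1)

    def test_deterministic_per_seed_and_universe_order_invariant(self):
        case, ctrl = self._incidence(seed=5)
        a = montecarlo_geneset_p(case, ctrl, np.arange(10), n_perm=99, seed=11)
        b = montecarlo_geneset_p(case, ctrl, np.arange(10), n_perm=99, seed=11)
        assert a.empirical_p == b.empirical_p and a.r == b.r
        perm = np.random.default_rng(0).permutation(case.shape[1])
        inv = np.argsort(perm)
        c = montecarlo_geneset_p(case[:, perm], ctrl[:, perm], inv[np.arange(10)], n_perm=99, seed=11)
        assert c.observed == pytest.approx(a.observed)

    def test_validation(self):
        case, ctrl = self._incidence()
        with pytest.raises(ValidationError):
            montecarlo_geneset_p(case, ctrl, np.arange(case.shape[1] + 1), n_perm=9, seed=0)
        with pytest.raises(ValidationError):
            montecarlo_geneset_p(case, ctrl, np.arange(3), n_perm=0, seed=0)

    def test_result_invariant_checked(self):
        with pytest.raises(AssertionError):
            PermutationResult(observed=0.5, null=np.array([0.5]), r=1, n=1, empirical_p=0.123)


class TestNegativeControl:
    def test_empty_list_warns_p_one(self):
        case = np.zeros((10, 50), bool)
        with pytest.warns(UserWarning):
            _, p = negative_control_contrast(case, case, [])
        assert p == 1.0

    def test_overlap_with_signal_warns(self):
        case = np.zeros((10, 50), bool)
        with pytest.warns(UserWarning, match="shares"):
            negative_control_contrast(case, case, [1, 2], signal_idx=[2, 3])

    def test_balanced_single_carrier(self):
        case = np.zeros((59, 50), bool)
        ctrl = np.zeros((59, 50), bool)
        case[0, 4] = True
        table, p = negative_control_contrast(case, ctrl, [4, 5, 6])
        assert table == ((1, 58), (0, 59))
        assert p == pytest.approx(1.0)


def test_carrier_table_counts_individuals_once():
    inc = np.zeros((5, 4), bool)
    inc[0, 0] = inc[0, 1] = True  # same individual, two genes of the set
    inc[1, 1] = True
    table = carrier_table(inc, np.zeros((3, 4), bool), [0, 1])
    assert table == ((2, 3), (0, 3))
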