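import math

import numpy as np
import pytest
from sklearn.isotonic import IsotonicRegression

from sapling.likelihood import (
    SolverConfig,
    fit_frequencies,
    loglik_at,
    naive_frequencies,
)
from sapling.trees import ReadCountData, make_tree

from conftest import random_parent_vector, tree_from_parent_vector


def _data(a, d, mutations=None):
    a = np.atleast_2d(a)
    d = np.atleast_2d(d)
    muts = mutations or list(range(1, a.shape[1] + 1))
    return ReadCountData([f"s{p}" for p in range(a.shape[0])], muts, a, d)


class TestNaiveFrequencies:
    def test_entrywise_ratio(self):
        F = naive_frequencies(_data([[5, 0]], [[10, 100]]))
        assert np.allclose(F.values, [[0.5, 0.0]])

    def test_zero_depth_maps_to_zero(self):
        F = naive_frequencies(_data([[0]], [[0]]))
        assert F.values[0, 0] == 0.0

    def test_variant_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            _data([[3]], [[0]])


class TestLoglikAt:
    def test_closed_form(self):
        d = _data([[5]], [[10]])
        F = naive_frequencies(d)
        assert math.isclose(loglik_at(d, F), 10 * math.log(0.5), rel_tol=1e-12)

    def test_zero_log_zero_convention(self):
        d = _data([[0]], [[10]])
        assert loglik_at(d, naive_frequencies(d)) == 0.0

    def test_sum_of_terms(self):
        d = _data([[10, 90]], [[100, 100]])
        from sapling.likelihood import FrequencyMatrix

        F = FrequencyMatrix(["s0"], [1, 2], np.array([[0.5, 0.5]]))
        assert math.isclose(loglik_at(d, F), 200 * math.log(0.5), rel_tol=1e-12)

    def test_impossible_observation_is_neg_inf(self):
        d = _data([[5]], [[10]])
        from sapling.likelihood import FrequencyMatrix

        F = FrequencyMatrix(["s0"], [1], np.array([[0.0]]))
        assert loglik_at(d, F) == -math.inf


class TestFitFrequencies:
    def test_single_node_unconstrained(self):
        d = _data([[5]], [[10]])
        fit = fit_frequencies(d, make_tree({}, nodes={1}))
        assert math.isclose(fit.loglik, 10 * math.log(0.5), rel_tol=1e-9)
        assert np.allclose(fit.F_star.values, 0.5, atol=1e-6)

    def test_nonbinding_constraint_keeps_naive(self):
        d = _data([[90, 40]], [[100, 100]])
        fit = fit_frequencies(d, make_tree({2: 1}))
        assert math.isclose(fit.loglik, loglik_at(d, naive_frequencies(d)), rel_tol=1e-12)

    def test_binding_chain_pools(self):
        # (a1+a2)/(d1+d2) = 0.5 for both mutations when the order is violated
        d = _data([[10, 90]], [[100, 100]])
        fit = fit_frequencies(d, make_tree({2: 1}))
        assert math.isclose(fit.loglik, 200 * math.log(0.5), abs_tol=1e-6)
        assert np.allclose(fit.F_star.values, 0.5, atol=1e-4)

    def test_scores_only_tree_columns(self):
        d = _data([[90, 40, 7]], [[100, 100, 100]])
        fit = fit_frequencies(d, make_tree({2: 1}))
        d2 = _data([[90, 40]], [[100, 100]])
        ref = fit_frequencies(d2, make_tree({2: 1}))
        assert math.isclose(fit.loglik, ref.loglik, rel_tol=1e-12)

    def test_missing_tree_node_rejected(self):
        d = _data([[5]], [[10]])
        with pytest.raises(KeyError):
            fit_frequencies(d, make_tree({2: 1}))

    @pytest.mark.parametrize("seed", range(6))
    def test_feasibility_and_upper_bound(self, seed):
        """F* satisfies the sum condition and [0,1]; the fit never exceeds the
        unconstrained optimum, with equality iff naive F is feasible."""
        rng = np.random.default_rng(seed)
        n, m = 6, 3
        par = random_parent_vector(rng, n)
        tree = tree_from_parent_vector(par)
        D = rng.poisson(100, (m, n))
        A = rng.binomial(D, rng.uniform(0, 1, (m, n)))
        d = ReadCountData([f"s{p}" for p in range(m)], list(range(n)), A, D)
        fit = fit_frequencies(d, tree)
        F = fit.F_star.values
        assert (F >= -1e-9).all() and (F <= 1 + 1e-9).all()
        cols = fit.F_star.mutations
        for i, mut in enumerate(cols):
            kids = [cols.index(c) for c in tree.children(mut)]
            if kids:
                assert (F[:, i] + 1e-6 >= F[:, kids].sum(axis=1)).all()
        unconstrained = loglik_at(d, naive_frequencies(d))
        assert fit.loglik <= unconstrained + 1e-6

    @pytest.mark.parametrize("seed", range(8))
    def test_chain_fit_matches_isotonic_pooling(self, seed):
        """On a single-sample chain the constrained binomial MLE equals
        weighted isotonic regression of the naive proportions (PAVA)."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(3, 8))
        D = rng.poisson(120, n) + 1
        A = rng.binomial(D, rng.uniform(0, 1, n))
        d = _data(A[None, :], D[None, :], mutations=list(range(n)))
        chain = make_tree({i: i - 1 for i in range(1, n)}, nodes=list(range(n)))
        fit = fit_frequencies(d, chain, SolverConfig(tol=1e-10))
        iso = IsotonicRegression(increasing=False)
        f_pava = iso.fit_transform(np.arange(n), A / D, sample_weight=D)
        ll_pava = float(
            np.where(A > 0, A * np.log(np.clip(f_pava, 1e-300, 1)), 0.0).sum()
            + np.where(D - A > 0, (D - A) * np.log(np.clip(1 - f_pava, 1e-300, 1)), 0.0).sum()
        )
        assert math.isclose(fit.loglik, ll_pava, abs_tol=1e-5)

    def test_invariance_under_sample_relabeling_and_sibling_order(self):
        rng = np.random.default_rng(0)
        D = rng.poisson(100, (2, 3))
        A = rng.binomial(D, [[0.9, 0.3, 0.4], [0.8, 0.5, 0.2]])
        d1 = ReadCountData(["s1", "s2"], [1, 2, 3], A, D)
        d2 = ReadCountData(["s2", "s1"], [1, 2, 3], A[::-1], D[::-1])
        star = make_tree({2: 1, 3: 1})
        f1 = fit_frequencies(d1, star).loglik
        f2 = fit_frequencies(d2, star).loglik
        assert math.isclose(f1, f2, rel_tol=1e-10)
        # swapping the two sibling columns relabels the same star tree
        d3 = ReadCountData(["s1", "s2"], [1, 3, 2], A[:, [0, 2, 1]], D[:, [0, 2, 1]])
        f3 = fit_frequencies(d3, star).loglik
        assert math.isclose(f1, f3, rel_tol=1e-10)
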