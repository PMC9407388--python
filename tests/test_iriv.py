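from itertools import combinations

import numpy as np
import pytest

from conftest import planted_problem
from specfuse.iriv import (INTERFERING, STRONG, UNINFORMATIVE, WEAK,
                           backward_eliminate, bms_matrix, classify,
                           iriv_select, mpa_diagnostics, _mann_whitney_p)
from specfuse.pls import rmsecv


class TestBMSMatrix:
    def test_column_sums_are_half_rows(self):
        m = bms_matrix(12, 50, seed=0)
        np.testing.assert_array_equal(m.sum(axis=0), np.full(12, 25))

    def test_same_seed_same_matrix(self):
        np.testing.assert_array_equal(
            bms_matrix(8, 20, seed=42), bms_matrix(8, 20, seed=42)
        )

    def test_no_empty_rows(self):
        for seed in range(20):
            assert bms_matrix(3, 10, seed=seed).sum(axis=1).min() > 0

    def test_row_sums_near_binomial_mean(self):
        """Row sums are Binomial(n_vars, 1/2) marginally; the empirical
        mean over many rows must sit inside a 5-sigma band."""
        n_vars, n_rows = 40, 400
        m = bms_matrix(n_vars, n_rows, seed=7)
        mean = m.sum(axis=1).mean()
        se = np.sqrt(n_vars * 0.25 / n_rows)
        assert abs(mean - n_vars / 2) < 5 * se

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bms_matrix(0, 10, seed=0)
        with pytest.raises(ValueError):
            bms_matrix(5, 7, seed=0)  # odd rows
        with pytest.raises(ValueError):
            bms_matrix(5, 2, seed=0)  # too few rows


class TestClassify:
    @pytest.mark.parametrize(
        "dmean,p,expected",
        [
            (-0.3, 0.01, STRONG),
            (-0.3, 0.50, WEAK),
            (0.3, 0.01, INTERFERING),
            (0.3, 0.50, UNINFORMATIVE),
            (0.0, 0.50, WEAK),  # boundary convention
        ],
    )
    def test_table_rules(self, dmean, p, expected):
        assert classify(dmean, p) == expected

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            classify(0.1, 1.5)


def mann_whitney_exact_oracle(a, b):
    """Exact two-sided p by enumerating all rank assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = pooled.argsort().argsort() + 1.0
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    u_obs = min(u_obs, n_a * len(b) - u_obs)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n_a):
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
        u = min(u, n_a * len(b) - u)
        total += 1
        if u <= u_obs:
            count += 1
    return count / total


@pytest.mark.parametrize("seed", range(5))
def test_mann_whitney_matches_exact_enumeration(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=5)
    b = rng.normal(0.6, 1.0, size=6)
    assert abs(_mann_whitney_p(a, b) - mann_whitney_exact_oracle(a, b)) < 1e-12


class TestMPADiagnostics:
    def test_identical_rmsecv_samples_give_null_contrast(self):
        """Identical inclusion/exclusion RMSECV vectors mean DMEAN = 0 and
        a p-value of (essentially) 1."""
        rng = np.random.default_rng(0)
        v = rng.normal(1.0, 0.1, size=12)
        assert v.mean() - v.copy().mean() == 0.0
        assert _mann_whitney_p(v, v.copy()) >= 0.99
        assert _mann_whitney_p(np.full(6, 1.3), np.full(6, 1.3)) == 1.0

    def test_planted_signal_has_negative_dmean(self):
        X, y, true_vars = planted_problem(n=60, p=20, true_vars=(2, 9),
                                          coefs=(1.0, 0.8), seed=1)
        matrix = bms_matrix(20, 80, seed=1)
        diag = mpa_diagnostics(X, y, matrix, folds=5, max_components=10)
        assert np.all(diag.dmean[list(true_vars)] < 0)
        assert all(diag.classes[v] == STRONG for v in true_vars)

    def test_matrix_width_must_match(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            mpa_diagnostics(rng.normal(size=(10, 4)), rng.normal(size=10),
                            bms_matrix(5, 10, seed=0), folds=5)


class TestIRIVSelect:
    def test_retained_counts_non_increasing_and_nested(self):
        X, y, _ = planted_problem(seed=3)
        res = iriv_select(X, y, n_rows=60, max_iter=5, folds=5,
                          max_components=8, seed=3)
        counts = [len(r) for r in res.retained]
        assert counts == sorted(counts, reverse=True)
        for earlier, later in zip(res.retained, res.retained[1:]):
            assert set(later) <= set(earlier)
        assert set(res.final) <= set(res.retained[-1])

    def test_classification_partitions_variables(self):
        X, y, _ = planted_problem(seed=4)
        res = iriv_select(X, y, n_rows=60, max_iter=2, folds=5,
                          max_components=8, seed=4)
        diag = res.diagnostics
        assert all(
            c in (STRONG, WEAK, UNINFORMATIVE, INTERFERING)
            for c in diag.classes
        )
        assert len(diag.classes) == len(diag.variables)

    def test_deterministic_given_seed(self):
        X, y, _ = planted_problem(seed=5)
        a = iriv_select(X, y, n_rows=40, max_iter=3, folds=5,
                        max_components=6, seed=9)
        b = iriv_select(X, y, n_rows=40, max_iter=3, folds=5,
                        max_components=6, seed=9)
        np.testing.assert_array_equal(a.final, b.final)
        np.testing.assert_array_equal(a.diagnostics.dmean, b.diagnostics.dmean)

    def test_needs_two_variables(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            iriv_select(rng.normal(size=(10, 1)), rng.normal(size=10))


class TestBackwardElimination:
    def test_matches_exhaustive_subset_search_on_toy(self):
        """On a 3-variable toy (one informative, one noise copy, one pure
        noise) greedy elimination lands on the RMSECV-optimal subset."""
        rng = np.random.default_rng(2)
        x_signal = rng.normal(size=40)
        X = np.column_stack([
            x_signal,
            rng.normal(size=40),
            rng.normal(size=40),
        ])
        y = 2.0 * x_signal + rng.normal(0, 0.05, 40)

        def score(cols):
            return rmsecv(X[:, list(cols)], y, folds=5,
                          max_components=len(cols)).best_rmsecv

        subsets = [c for r in (1, 2, 3) for c in combinations(range(3), r)]
        best_subset = min(subsets, key=score)
        final, _ = backward_eliminate(X, y, [0, 1, 2], folds=5,
                                      max_components=3)
        assert tuple(final) == best_subset

    def test_removal_trace_improves_monotonically(self):
        X, y, _ = planted_problem(n=50, p=10, true_vars=(1,), coefs=(1.0,),
                                  seed=6)
        final, trace = backward_eliminate(X, y, list(range(10)), folds=5,
                                          max_components=8)
        scores = [s for _, s in trace]
        assert scores == sorted(scores, reverse=True)
        assert 1 in final
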