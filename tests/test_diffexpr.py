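"""Differential expression: logistic screen, BH-FDR, AUC, Venn partition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirdiag.diffexpr import (
    DEAConfig,
    adjust_fdr,
    differential_expression,
    logistic_screen,
    marker_auc,
    roc_auc,
    select_demirnas,
    univariate_logistic,
    venn_partition,
)


def naive_bh(p):
    """Independent step-up oracle: q_i = min over tail of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def brute_force_auc(values, labels):
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    cases, ctrls = v[y == 1], v[y == 0]
    total = 0.0
    for a in cases:
        for b in ctrls:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(cases) * len(ctrls))


class TestUnivariateLogistic:
    def test_constant_feature_is_uninformative(self):
        y = np.array([0, 1] * 10)
        slope, p = univariate_logistic(np.ones(20), y)
        assert slope == 0.0 and p == 1.0

    def test_matches_statsmodels_on_random_instances(self, rng):
        """Slope and both test statistics agree with the statsmodels fit."""
        import statsmodels.api as sm
        from scipy import stats

        for _ in range(25):
            n = int(rng.integers(30, 80))
            x = rng.standard_normal(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-0.8 * x))).astype(int)
            if min(y.sum(), n - y.sum()) < 2:
                continue
            slope, p_lrt = univariate_logistic(x, y)
            _, p_wald = univariate_logistic(x, y, statistic="wald")
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            null = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
            assert slope == pytest.approx(fit.params[1], abs=1e-4)
            assert p_wald == pytest.approx(fit.pvalues[1], rel=1e-3, abs=1e-8)
            ref_lrt = stats.chi2.sf(2 * (fit.llf - null.llf), 1)
            assert p_lrt == pytest.approx(ref_lrt, rel=1e-3, abs=1e-8)

    def test_null_pvalues_uniform(self, rng):
        """Permuted labels: fraction below 0.05 within binomial tolerance."""
        n, m = 80, 1000
        X = rng.standard_normal((m, n))
        y = rng.permutation(np.array([1] * 40 + [0] * 40))
        _, pvals = logistic_screen(X, y)
        rate = (pvals < 0.05).mean()
        assert abs(rate - 0.05) < 4 * np.sqrt(0.05 * 0.95 / m)

    def test_strong_effect_has_tiny_pvalue_vs_lrt_oracle(self, rng):
        """3-sd shift at n=60/60: p < 1e-6, consistent with an LRT."""
        from scipy import stats

        x = np.concatenate([rng.standard_normal(60) + 3.0, rng.standard_normal(60)])
        y = np.array([1] * 60 + [0] * 60)
        slope, p = univariate_logistic(x, y)
        assert p < 1e-6
        assert slope > 0
        # independent likelihood-ratio computation agrees it is overwhelming
        import statsmodels.api as sm

        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0, method="bfgs", maxiter=200)
        lrt = 2 * (fit.llf - sm.Logit(y, np.ones((120, 1))).fit(disp=0).llf)
        assert stats.chi2.sf(lrt, 1) < 1e-6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            univariate_logistic(np.arange(10.0), np.ones(10))

    def test_quasi_separated_feature_survives_with_rank_fallback(self):
        x = np.concatenate([np.arange(10) + 100.0, np.arange(10)])
        y = np.array([1] * 10 + [0] * 10)
        _, p = univariate_logistic(x, y)
        assert 0 < p < 1e-3  # Mann-Whitney scale, not a Wald artifact


class TestAdjustFdr:
    def test_identical_pvalues_are_a_fixed_point(self):
        q = adjust_fdr(np.full(7, 0.01))
        assert np.allclose(q, 0.01)

    def test_hand_computed_example(self):
        q = adjust_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_naive_step_up_oracle(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 21))
            p = rng.random(m)
            assert np.allclose(adjust_fdr(p), naive_bh(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_fdr(np.array([0.5, 1.5]))

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=15))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, pvals):
        p = np.asarray(pvals)
        perm = np.random.default_rng(0).permutation(len(p))
        q = adjust_fdr(p)
        q_perm = adjust_fdr(p[perm])
        assert np.allclose(q[perm], q_perm)


class TestMarkerAuc:
    def test_perfect_separation(self):
        auc, orient = marker_auc(np.array([5.0, 6, 7, 1, 2, 3]), np.array([1, 1, 1, 0, 0, 0]))
        assert auc == 1.0 and orient == 1

    def test_all_ties(self):
        auc, _ = marker_auc(np.ones(8), np.array([1, 1, 1, 1, 0, 0, 0, 0]))
        assert auc == 0.5

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 13))
            y = np.zeros(n, dtype=int)
            y[: int(rng.integers(1, n))] = 1
            if y.sum() in (0, n):
                continue
            v = rng.integers(0, 5, n).astype(float)  # ties likely
            assert roc_auc(v, y) == pytest.approx(brute_force_auc(v, y), abs=1e-12)

    def test_orientation_complement(self, rng):
        x = rng.standard_normal(30)
        y = np.array([1] * 15 + [0] * 15)
        assert roc_auc(x, y) + roc_auc(-x, y) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(5.0), np.ones(5))


class TestSelection:
    def test_all_null_pvalues_select_nothing(self):
        res = pd.DataFrame(
            {"p_value": [1.0, 1.0], "q_value": [1.0, 1.0]},
            index=["a", "b"],
        )
        assert select_demirnas(res) == []

    def test_truth_recovered_with_fdr_control(self, rng):
        """Strong signals selected; false discovery proportion near level."""
        n, p, s = 120, 300, 8
        reps, fdp = 30, []
        hits = 0
        for r in range(reps):
            rr = np.random.default_rng(900 + r)
            X = rr.standard_normal((p, n))
            y = np.array([1] * 60 + [0] * 60)
            X[:s, y == 1] += 1.5
            expr = pd.DataFrame(X, index=[f"f{j}" for j in range(p)])
            table = differential_expression(expr, y)
            selected = set(select_demirnas(table))
            truth = {f"f{j}" for j in range(s)}
            hits += len(selected & truth) / s
            fdp.append(len(selected - truth) / max(len(selected), 1))
        assert hits / reps > 0.95
        assert np.mean(fdp) < 0.08  # Monte-Carlo slack around the 0.05 level

    def test_table_contract(self, small_cohort):
        from conftest import split_training

        _, expression, metadata, truth = small_cohort
        X, y = split_training(expression, metadata)
        table = differential_expression(X, y)
        assert (table["q_value"] >= table["p_value"] - 1e-15).all()
        assert ((table["q_value"] < 0.05) == table["significant"]).all()
        assert table["auc"].between(0.5, 1.0).all()
        assert truth <= set(select_demirnas(table))


class TestVennPartition:
    def test_disjoint_panel(self):
        both, only_b, flags = venn_partition({"x"}, {"a", "b"}, ["a", "b"])
        assert (both, only_b) == (0, 2)
        assert not flags["in_both"].any()

    def test_contained_panel(self):
        both, only_b, _ = venn_partition({"a", "b"}, {"a", "b"}, ["a", "b"])
        assert (both, only_b) == (2, 0)

    def test_panel_outside_set_b_warns_but_counts(self):
        with pytest.warns(UserWarning, match="subset"):
            both, only_b, _ = venn_partition({"a"}, {"b"}, ["a", "c"])
        assert both + only_b == 2
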