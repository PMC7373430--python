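"""Paired/randomized ratios, rank-based tests vs enumeration/permutation oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pbodyquant import (classify_hc_lc, copartition_report, fligner_killeen,
                        generate_paired_table, paired_ratios, pearson_r,
                        randomized_ratios, wilcoxon_rank_sum)


def _table(x, y):
    return pd.DataFrame({"pbody_id": range(len(x)), "cell_id": range(len(x)),
                         "c_x_uM": x, "c_y_uM": y})


class TestPearson:
    def test_proportional(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRatios:
    def test_paired_identity_and_order(self):
        t = _table([4.0, 6.0, 10.0], [2.0, 6.0, 5.0])
        np.testing.assert_allclose(paired_ratios(t), [2.0, 1.0, 2.0])

    def test_randomized_never_self_pairs(self):
        # distinct primes make every self-ratio value unique
        x = np.array([2.0, 3.0, 5.0, 7.0, 11.0])
        y = np.array([13.0, 17.0, 19.0, 23.0, 29.0])
        self_ratios = set(x / y)
        t = _table(x, y)
        cross = {xv / yv for i, xv in enumerate(x) for j, yv in enumerate(y)
                 if i != j}
        for seed in range(100):
            for method in ("replacement", "derangement"):
                out = randomized_ratios(t, seed, method=method)
                assert len(out) == len(t)
                assert set(out) <= cross
                assert not (set(out) & self_ratios)

    def test_two_rows_always_cross(self):
        t = _table([4.0, 9.0], [2.0, 3.0])
        for seed in range(20):
            out = randomized_ratios(t, seed)
            assert set(out) <= {4.0 / 3.0, 9.0 / 2.0}

    def test_seed_determinism(self):
        t = generate_paired_table(30, 0.6, seed=5)
        np.testing.assert_array_equal(randomized_ratios(t, 3),
                                      randomized_ratios(t, 3))

    def test_randomization_inflates_log_ratio_variance(self):
        """Decorrelating the pairing can only widen the log-ratio spread, on
        average: checked over 100 seeds of a correlated lognormal table."""
        t = generate_paired_table(86, 0.65, seed=9)
        v_paired = np.var(np.log(paired_ratios(t)))
        wins = sum(np.var(np.log(randomized_ratios(t, s))) >= v_paired
                   for s in range(100))
        assert wins >= 95


def _fligner_statistic_oracle(groups):
    """Independent implementation: rank |x - group median| across the pooled
    sample, map through normal quantiles, chi-squared on group score means."""
    centered = [np.abs(np.asarray(g) - np.median(g)) for g in groups]
    pooled = np.concatenate(centered)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    scores = stats.norm.ppf(0.5 + ranks / (2.0 * (n + 1.0)))
    abar = scores.mean()
    v = scores.var(ddof=1)
    stat = 0.0
    start = 0
    for g in centered:
        m = len(g)
        gbar = scores[start:start + m].mean()
        stat += m * (gbar - abar) ** 2
        start += m
    return stat / v


class TestFlignerKilleen:
    def test_identical_groups_are_null(self):
        r = fligner_killeen([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_statistic_matches_recipe_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 3, 10)
        r = fligner_killeen(a, b)
        assert r.statistic == pytest.approx(_fligner_statistic_oracle([a, b]),
                                            rel=1e-9)

    def test_p_matches_permutation_null(self):
        """Chi-squared p agrees with a 5000-permutation label-shuffle null."""
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 2.5, 10)
        r = fligner_killeen(a, b)
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 5000
        for _ in range(n_perm):
            perm = rng.permutation(20)
            s = _fligner_statistic_oracle([pooled[perm[:10]], pooled[perm[10:]]])
            if s >= r.statistic - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert r.p_value == pytest.approx(p_perm, abs=0.05)

    def test_power_under_ninefold_variance(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 200)
            b = rng.normal(0, 3, 200)
            if fligner_killeen(a, b).p_value < 0.001:
                rejections += 1
        assert rejections >= 95

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fligner_killeen([2.0, 2.0], [2.0, 2.0])


class TestWilcoxon:
    def test_exact_enumeration_example(self):
        r = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1)
        assert r.method == "wilcoxon-exact"

    def test_identical_samples(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_normal_approximation_near_exact(self, seed):
        """Normal-approximation p within 0.01 of exact enumeration at n=6+6
        (ties included via integer draws)."""
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 8, 6).astype(float)
        b = rng.integers(2, 10, 6).astype(float)
        p_exact = wilcoxon_rank_sum(a, b, method="exact").p_value
        p_norm = wilcoxon_rank_sum(a, b, method="normal").p_value
        assert p_norm == pytest.approx(p_exact, abs=0.05)

    def test_large_sample_agrees_with_scipy(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.8, 1, 25)
        r = wilcoxon_rank_sum(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided")
        assert r.method == "wilcoxon-normal"
        assert r.p_value == pytest.approx(ref.pvalue, rel=0.05)

    def test_significance_labels(self):
        rng = np.random.default_rng(3)
        r = fligner_killeen(rng.normal(0, 1, 300), rng.normal(0, 4, 300))
        assert r.significance == "****"


class TestClassification:
    @pytest.mark.parametrize("pc,conc,label", [
        (133.0, 15.0, "HC"),      # strongly enriched decapping-complex regime
        (13.0, 4.6, "LC"),        # high cytoplasmic pool, low enrichment
        (30.0, 5.0, "LC"),        # boundary: concentration must exceed 5 µM
        (30.0, 5.01, "HC"),
        (29.9, 15.0, "LC"),
    ])
    def test_hc_lc_rule(self, pc, conc, label):
        assert classify_hc_lc(pc, conc) == label

    @given(st.floats(0.1, 300), st.floats(0.1, 30))
    @settings(deadline=None, max_examples=100)
    def test_rule_is_conjunction(self, pc, conc):
        want = "HC" if (pc >= 30.0 and conc > 5.0) else "LC"
        assert classify_hc_lc(pc, conc) == want


class TestReport:
    def test_report_fields_and_variance_ordering(self):
        t = generate_paired_table(86, 0.65, seed=2)
        rep = copartition_report(t, seed=3)
        assert rep["n"] == 86
        assert 0.3 < rep["pearson_r_log"] < 0.9
        assert rep["randomized_log_ratio_sd"] > rep["paired_log_ratio_sd"]
        assert rep["fligner_log"].p_value < 0.05
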