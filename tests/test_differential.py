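"""NB differential machinery: hand examples, enumeration oracles, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bindexpr.differential import (
    bh_adjust,
    estimate_dispersions,
    estimate_size_factors,
    fold_change,
    nb_exact_test,
    run_differential,
)
from bindexpr.io import CountMatrix


GROUPS_4V4 = ["A"] * 4 + ["B"] * 4


class TestSizeFactors:
    def test_identical_libraries_unity(self):
        df = pd.DataFrame({"a": [10, 100, 1], "b": [10, 100, 1]})
        s = estimate_size_factors(df)
        assert np.allclose(s, [1.0, 1.0])

    def test_hand_example_two_libraries(self):
        # features (10,20),(100,200),(1,2): every ratio to the geometric
        # mean is 1/sqrt(2) or sqrt(2)
        df = pd.DataFrame({"a": [10, 100, 1], "b": [20, 200, 2]})
        s = estimate_size_factors(df)
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_scaling_one_library(self, rng):
        base = rng.integers(1, 1000, size=(200, 2))
        df = pd.DataFrame(base, columns=["a", "b"])
        s0 = estimate_size_factors(df)
        df2 = df.copy()
        df2["b"] *= 3
        s1 = estimate_size_factors(df2)
        # under 2 libraries the geometric mean absorbs sqrt(c)
        assert np.allclose(s1["b"] / s0["b"], 3 / np.sqrt(3))
        assert np.allclose(s1["a"] / s0["a"], 1 / np.sqrt(3))

    def test_zero_in_every_feature_rejected(self):
        df = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="all-positive"):
            estimate_size_factors(df)


class TestDispersions:
    def test_constant_counts_raw_zero(self):
        libs = [f"L{j}" for j in range(4)]
        cm = CountMatrix(
            pd.DataFrame([[50] * 4, [7] * 4], index=["f1", "f2"], columns=libs),
            pd.Series(["A"] * 4, index=libs),
        )
        s = pd.Series(1.0, index=libs)
        d = estimate_dispersions(cm, s)
        assert np.allclose(d.raw, 0.0)

    def test_poisson_data_near_zero_dispersion(self, rng, make_nb_counts):
        cm = make_nb_counts(rng, 2000, [1.0] * 4, ["A"] * 4,
                            baseline=rng.lognormal(5, 1, 2000), alpha=0.0)
        d = estimate_dispersions(cm, pd.Series(1.0, index=cm.libraries))
        assert np.median(d.final) < 0.05

    def test_planted_dispersion_recovered(self, rng, make_nb_counts):
        # alpha=0.2 at high means: median of raw estimates within 25%
        cm = make_nb_counts(rng, 3000, [1.0] * 8, ["A"] * 8,
                            baseline=2000.0, alpha=0.2)
        d = estimate_dispersions(cm, pd.Series(1.0, index=cm.libraries))
        assert abs(np.median(d.raw) - 0.2) < 0.05

    def test_single_replicate_rejected(self, rng, make_nb_counts):
        cm = make_nb_counts(rng, 10, [1.0], ["A"], baseline=100.0, alpha=0.1)
        with pytest.raises(ValueError, match=">= 2"):
            estimate_dispersions(cm, pd.Series(1.0, index=cm.libraries))


def binomial_two_sided_oracle(k_a, total, prob):
    """Enumeration oracle: two-sided tail of Binomial(total, prob) by
    summing all outcomes no more probable than the observed one."""
    pmf = np.array([stats.binom.pmf(a, total, prob) for a in range(total + 1)])
    return pmf[pmf <= pmf[k_a] * (1 + 1e-12)].sum()


class TestExactTest:
    def test_modal_split_p_one(self):
        assert nb_exact_test(50, 50, 50, 60, 50, 60) == pytest.approx(1.0)

    def test_zero_total(self):
        assert nb_exact_test(0, 0, 5, 6, 5, 6) == 1.0

    @pytest.mark.parametrize("k_a", [0, 1, 2, 5])
    def test_poisson_limit_matches_binomial_enumeration(self, k_a):
        # equal size factors, variance == mean: conditioning on the total
        # gives Binomial(5, 1/2)
        total = 5
        p = nb_exact_test(k_a, total - k_a, 10.0, 10.0, 10.0, 10.0)
        assert p == pytest.approx(binomial_two_sided_oracle(k_a, total, 0.5),
                                  rel=1e-10)

    def test_unequal_means_poisson_limit(self):
        # means 20 vs 10: conditional is Binomial(n, 2/3)
        total, k_a = 9, 8
        p = nb_exact_test(k_a, total - k_a, 20.0, 20.0, 10.0, 10.0)
        assert p == pytest.approx(
            binomial_two_sided_oracle(k_a, total, 2 / 3), rel=1e-10
        )

    @pytest.mark.parametrize("ka,kb", [(3, 20), (100, 80), (0, 12)])
    def test_group_swap_symmetry(self, ka, kb):
        p1 = nb_exact_test(ka, kb, 30.0, 90.0, 40.0, 100.0)
        p2 = nb_exact_test(kb, ka, 40.0, 100.0, 30.0, 90.0)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_underdispersion_clamped(self):
        p = nb_exact_test(5, 5, 10.0, 5.0, 10.0, 5.0)
        assert 0 < p <= 1

    def test_large_total_normal_branch(self):
        p = nb_exact_test(8000, 8000, 8000.0, 9000.0, 8000.0, 9000.0)
        assert p == pytest.approx(1.0, abs=0.05)
        p_far = nb_exact_test(12000, 4000, 8000.0, 9000.0, 8000.0, 9000.0)
        assert p_far < 1e-10


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        # ranks 1..4: adjusted = min over j>=i of p_j * m / j, here all 0.04
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_order_restored_and_clipped(self):
        adj = bh_adjust([0.9, 0.001, 0.5])
        assert adj[1] == min(adj) and (adj <= 1).all()

    def test_min_adjusted_at_least_min_raw(self, rng):
        p = rng.random(100)
        assert bh_adjust(p).min() >= p.min() - 1e-15

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_rejection_set_matches_step_up_rule(self, rng):
        p = np.sort(rng.random(50) ** 2)
        q = 0.1
        adj = bh_adjust(p)
        m = len(p)
        below = np.nonzero(p <= (np.arange(1, m + 1) / m) * q)[0]
        k = below.max() + 1 if len(below) else 0
        assert set(np.nonzero(adj < q)[0]) <= set(range(k))
        assert (adj[:k] <= q).all() if k else True


class TestRunDifferential:
    def test_fold_change_is_ratio_of_normalized_means(self):
        assert fold_change(22162.49, 4599.52) == pytest.approx(4.82, abs=5e-3)
        assert np.isnan(fold_change(386.14, 0.0))

    def test_null_data_few_rejections(self, rng, make_nb_counts):
        cm = make_nb_counts(
            rng, 2000, rng.uniform(0.5, 2, 8), GROUPS_4V4,
            baseline=rng.lognormal(5, 1.2, 2000), alpha=0.08,
        )
        tab = run_differential(cm)
        assert (tab["fdr"] < 0.05).mean() < 0.01

    def test_planted_effects_recovered(self, rng, make_nb_counts):
        n = 400
        lfc = np.zeros(n)
        lfc[:100] = rng.choice([-2.5, 2.5], size=100)
        cm = make_nb_counts(
            rng, n, rng.uniform(0.5, 2, 8), GROUPS_4V4,
            baseline=rng.lognormal(5, 1, n), alpha=0.1, log2fc=lfc,
        )
        tab = run_differential(cm)
        called = tab["fdr"] < 0.05
        assert called[:100].mean() >= 0.9
        # directions follow the planted sign
        sig_dir = tab.loc[called[:100][called[:100]].index, "direction"]
        expect = np.where(lfc[:100] > 0, "A-up", "B-up")[called[:100]]
        assert (sig_dir.to_numpy() == expect).mean() > 0.99

    def test_zero_denominator_direction_and_na(self, rng, make_nb_counts):
        n = 50
        cm = make_nb_counts(rng, n, [1.0] * 8, GROUPS_4V4, baseline=200.0,
                            alpha=0.05)
        k = cm.counts.copy()
        k.iloc[0, 4:] = 0  # group B silent
        cm2 = CountMatrix(k, cm.groups)
        tab = run_differential(cm2)
        row = tab.iloc[0]
        assert np.isnan(row["fold_change"])
        assert row["direction"] == "A-up"

    def test_requires_two_libraries_per_group(self, rng, make_nb_counts):
        cm = make_nb_counts(rng, 10, [1.0, 1.0, 1.0], ["A", "B", "B"],
                            baseline=100.0, alpha=0.1)
        with pytest.raises(ValueError, match=">= 2"):
            run_differential(cm)

    def test_scale_invariance_on_null(self, rng, make_nb_counts):
        cm = make_nb_counts(rng, 800, [1.0] * 8, GROUPS_4V4,
                            baseline=rng.lognormal(5, 1, 800), alpha=0.08)
        tab1 = run_differential(cm)
        scaled = cm.counts.copy()
        scaled.iloc[:, 0] *= 4
        tab2 = run_differential(CountMatrix(scaled, cm.groups))
        n1, n2 = (tab1["fdr"] < 0.05).sum(), (tab2["fdr"] < 0.05).sum()
        assert abs(int(n1) - int(n2)) <= 8
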