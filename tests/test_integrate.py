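"""Pair classification, concordance chi-square, on/off rule, clustering prep."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bindexpr.integrate import (
    QUADRANTS,
    cluster_prep,
    concordance_chi2,
    direction_marginal,
    join_pairs,
    onoff_classify,
    quadrant_counts,
    report,
)
from bindexpr.io import CountMatrix


def diff_table(rows):
    return pd.DataFrame(
        rows, columns=["feature", "mean_A", "mean_B", "fold_change", "p",
                       "fdr", "direction"]
    )


@pytest.fixture
def toy_tables():
    binding = diff_table([
        ("BR1", 100, 10, 10.0, 1e-4, 0.04, "A-up"),
        ("BR2", 10, 100, 0.1, 1e-3, 0.04, "B-up"),
        ("BR3", 50, 50, 1.0, 0.5, 0.8, "none"),
        ("BR4", 80, 20, 4.0, 2e-3, 0.05, "none"),  # FDR exactly at threshold
    ])
    expression = diff_table([
        ("g1", 200, 5, 40.0, 1e-5, 0.01, "A-up"),
        ("g2", 5, 200, 0.025, 1e-5, 0.01, "B-up"),
        ("g3", 30, 30, 1.0, 0.9, 0.95, "none"),
    ])
    pairs = pd.DataFrame({
        "gene_id": ["g1", "g1", "g2", "g3", "g1"],
        "br_id": ["BR1", "BR2", "BR1", "BR1", "BR4"],
    })
    return pairs, binding, expression


class TestJoinPairs:
    def test_classes_and_quadrants(self, toy_tables):
        pairs, binding, expression = toy_tables
        out = join_pairs(pairs, binding, expression, q=0.05)
        rec = out.set_index(["gene_id", "br_id"])
        assert rec.loc[("g1", "BR1"), "pair_class"] == "both-significant"
        assert rec.loc[("g1", "BR1"), "quadrant"] == "A+/A+"
        assert rec.loc[("g1", "BR2"), "quadrant"] == "B+/A+"
        assert rec.loc[("g2", "BR1"), "quadrant"] == "A+/B+"
        assert rec.loc[("g3", "BR1"), "pair_class"] == "binding-only"

    def test_fdr_exactly_at_threshold_not_significant(self, toy_tables):
        pairs, binding, expression = toy_tables
        out = join_pairs(pairs, binding, expression, q=0.05)
        rec = out.set_index(["gene_id", "br_id"])
        # BR4 has FDR = 0.05: strict inequality keeps it non-significant
        assert rec.loc[("g1", "BR4"), "pair_class"] == "expression-only"

    def test_class_counts_conserve_pairs(self, toy_tables):
        pairs, binding, expression = toy_tables
        out = join_pairs(pairs, binding, expression)
        assert out["pair_class"].value_counts().sum() == len(pairs)
        quad = quadrant_counts(out)
        assert sum(quad.values()) == (out["pair_class"] == "both-significant").sum()

    def test_unknown_feature_rejected(self, toy_tables):
        pairs, binding, expression = toy_tables
        bad = pd.concat(
            [pairs, pd.DataFrame({"gene_id": ["gX"], "br_id": ["BR1"]})]
        )
        with pytest.raises(ValueError, match="unknown genes"):
            join_pairs(bad, binding, expression)


class TestConcordanceChi2:
    def test_quadrant_table_arithmetic(self):
        # marginals embodied by the published-style 2x2: binding 56% up in
        # group A, expression 83%; n = 823 pairs
        res = concordance_chi2(
            {"A+/A+": 531, "A+/B+": 64, "B+/A+": 155, "B+/B+": 73},
            p_bind=1974 / 3524, p_expr=0.83,
        )
        t = res.table().set_index("quadrant")
        assert list(t["expected_count_display"]) == [382, 78, 300, 61]
        assert t.loc["A+/B+", "contribution_display"] == pytest.approx(2.51, abs=5e-3)
        assert t.loc["B+/A+", "contribution_display"] == pytest.approx(70.08, abs=5e-3)
        assert res.df == 3
        # statistic recomputed from unrounded expected counts
        assert res.chi2 == pytest.approx(sum(res.contributions.values()))
        assert res.p_value < 1e-25

    def test_exact_match_gives_zero(self):
        res = concordance_chi2(
            {"A+/A+": 25, "A+/B+": 25, "B+/A+": 25, "B+/B+": 25},
            p_bind=0.5, p_expr=0.5,
        )
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_expected_frequencies_sum_to_one(self):
        res = concordance_chi2({"A+/A+": 10, "A+/B+": 5, "B+/A+": 3,
                                "B+/B+": 2}, 0.3, 0.7)
        assert sum(res.expected_freq.values()) == pytest.approx(1.0)
        assert sum(res.expected_counts.values()) == pytest.approx(res.n)

    def test_degenerate_marginal_rejected(self):
        with pytest.raises(ValueError):
            concordance_chi2({"A+/A+": 5}, 1.0, 0.5)
        with pytest.raises(ValueError):
            concordance_chi2({}, 0.5, 0.5)

    def test_multinomial_null_mean_matches_df(self, rng):
        # observed drawn from the product marginals: E[chi2] = df = 3
        res = concordance_chi2(
            {"A+/A+": 1, "A+/B+": 1, "B+/A+": 1, "B+/B+": 1}, 0.56, 0.83
        )
        freqs = np.array([res.expected_freq[qd] for qd in QUADRANTS])
        draws = rng.multinomial(823, freqs, size=10_000)
        e = 823 * freqs
        chi2 = ((draws - e) ** 2 / e).sum(axis=1)
        assert chi2.mean() == pytest.approx(3.0, rel=0.05)


class TestOnOff:
    def test_rule_with_strict_threshold(self):
        table = diff_table([
            ("g1", 386.14, 0.0, np.nan, 1e-9, 2.25e-8, "A-up"),   # on/off
            ("g2", 500.0, 4.99, 100.0, 1e-9, 1e-8, "A-up"),       # on/off
            ("g3", 500.0, 5.0, 100.0, 1e-9, 1e-8, "A-up"),        # boundary
            ("g4", 3.0, 400.0, 0.0075, 1e-9, 1e-8, "B-up"),       # on/off B
            ("g5", 2.0, 300.0, 0.007, 0.5, 0.9, "none"),          # not sig
        ])
        flags = onoff_classify(table, threshold=5)
        assert flags["g1"] == "A" and flags["g2"] == "A"
        assert flags["g3"] == ""
        assert flags["g4"] == "B"
        assert flags["g5"] == ""


class TestClusterPrep:
    def test_rows_unit_sum_of_squares(self, rng):
        df = pd.DataFrame(rng.integers(0, 1000, size=(50, 8)).astype(float))
        out = cluster_prep(df)
        ss = (out.to_numpy() ** 2).sum(axis=1)
        nonzero = ss > 0
        assert np.allclose(ss[nonzero], 1.0, atol=1e-12)

    def test_column_standardization_independent_recompute(self, rng):
        df = pd.DataFrame(rng.integers(0, 1000, size=(50, 8)).astype(float))
        x = np.log1p(df.to_numpy())
        z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)
        row_norm = np.sqrt((z**2).sum(axis=1))
        expected = z / row_norm[:, None]
        assert np.allclose(cluster_prep(df).to_numpy(), expected)

    def test_constant_column_zero_filled(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0],
                           "c": [2.0, 9.0, 4.0]})
        out = cluster_prep(df)
        assert (out["b"] == 0).all()

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            cluster_prep(pd.DataFrame({"a": [1.0, 2.0]}))

    def test_all_degenerate_matrix_left_zero(self):
        # every column constant: zero after standardization, and the
        # zero-sum-of-squares rows stay zero rather than dividing by 0
        df = pd.DataFrame(np.tile([[3.0, 8.0, 1.0]], (4, 1)))
        out = cluster_prep(df)
        assert (out.to_numpy() == 0).all()


class TestReport:
    def test_bundle_deterministic_and_conserving(self, tmp_path, toy_tables):
        pairs, binding, expression = toy_tables
        pair_table = join_pairs(pairs, binding, expression)
        quad = quadrant_counts(pair_table)
        conc = concordance_chi2(quad, direction_marginal(binding),
                                direction_marginal(expression))
        onoff = onoff_classify(expression)
        kwargs = dict(
            diff_binding=binding, diff_expression=expression,
            pair_table=pair_table, concordance=conc, onoff=onoff,
            cluster_matrix=None, manifest={"seed": 1},
        )
        s1 = report(tmp_path / "r1", **kwargs)
        s2 = report(tmp_path / "r2", **kwargs)
        for f in (tmp_path / "r1").iterdir():
            assert f.read_bytes() == (tmp_path / "r2" / f.name).read_bytes()
        assert sum(s1["quadrant_counts"].values()) == \
            s1["class_counts"]["both-significant"]
        assert s1 == s2

    def test_empty_significant_set_skips_chi2(self, tmp_path):
        binding = diff_table([("BR1", 1, 1, 1.0, 0.9, 0.95, "none")])
        expression = diff_table([("g1", 1, 1, 1.0, 0.9, 0.95, "none")])
        pair_table = join_pairs(
            pd.DataFrame({"gene_id": ["g1"], "br_id": ["BR1"]}),
            binding, expression,
        )
        summary = report(
            tmp_path, diff_binding=binding, diff_expression=expression,
            pair_table=pair_table, concordance=None,
            onoff=onoff_classify(expression), cluster_matrix=None,
            manifest={},
        )
        assert "chi2" not in summary
        assert "skipped" in (tmp_path / "concordance.txt").read_text()
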