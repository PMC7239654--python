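"""Per-gene enrichment statistics: counts, exact test, FDR, bias score."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trapscreen import (
    Insertion,
    InsertionDataset,
    bh_fdr,
    circle_plot_table,
    enrichment_test,
    igtiob,
    screen_results,
    tabulate,
)


def hypergeom_upper_tail(a, t_s, g, t_c):
    """Exact-fraction oracle: P(X >= a) by enumerating the full support."""
    n_pop, n_marked, n_draw = t_s + t_c, a + g, t_s
    total = Fraction(comb(n_pop, n_draw))
    tail = sum(
        Fraction(comb(n_marked, k) * comb(n_pop - n_marked, n_draw - k))
        for k in range(a, min(n_marked, n_draw) + 1)
    )
    return tail / total


def make_dataset(population, sites):
    return InsertionDataset.from_insertions(
        "s1", population, [Insertion("chr1", p, s) for p, s in sites]
    )


class TestTabulate:
    def test_hand_tally_on_toy_annotation(self, toy_annotation):
        # gA: +, exons [100,200),[300,400); gB: -, exon [600,800)
        sorted_ds = make_dataset(
            "sorted",
            [
                (150, "-"),  # gA exon, antisense -> inactivating
                (250, "+"),  # gA intron sense -> inactivating
                (250, "-"),  # gA intron antisense -> not inactivating
                (650, "-"),  # gB exon sense -> inactivating
                (50, "+"),  # intergenic
            ],
        )
        control_ds = make_dataset("control", [(120, "+"), (900, "-")])
        counts = tabulate(sorted_ds, control_ds, toy_annotation).set_index("gene_id")
        assert counts.loc["gA", "inactivating_sorted"] == 2
        assert counts.loc["gA", "sense_intronic_sorted"] == 1
        assert counts.loc["gA", "antisense_intronic_sorted"] == 1
        assert counts.loc["gA", "control_insertions"] == 1
        assert counts.loc["gB", "inactivating_sorted"] == 1
        assert counts.loc["gB", "control_insertions"] == 0
        assert (counts["total_sorted"] == 5).all()
        assert (counts["total_control"] == 2).all()

    def test_empty_datasets_give_zero_counts_for_every_gene(self, toy_annotation):
        counts = tabulate(
            make_dataset("sorted", []), make_dataset("control", []), toy_annotation
        )
        assert list(counts["gene_id"]) == ["gA", "gB"]
        assert (counts[counts.columns[1:]] == 0).all().all()

    def test_population_roles_enforced(self, toy_annotation):
        ctrl = make_dataset("control", [])
        with pytest.raises(ValueError, match="sorted"):
            tabulate(ctrl, ctrl, toy_annotation)


class TestEnrichmentTest:
    def test_zero_inactivating_gives_p_one(self):
        assert enrichment_test(0, 10, 3, 20) == 1.0

    def test_hand_enumerated_half(self):
        # N=2 insertions, 1 in the gene, draw 1: P(X>=1) = 1/2
        assert enrichment_test(1, 1, 0, 1) == pytest.approx(0.5)

    def test_hand_enumerated_binomial_ratio(self):
        # a=3 of T_s=10 vs 0 of T_c=10: P = C(17,7)/C(20,10)
        expected = comb(17, 7) / comb(20, 10)
        assert enrichment_test(3, 10, 0, 10) == pytest.approx(expected, rel=1e-12)

    def test_margin_violations_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(11, 10, 0, 10)
        with pytest.raises(ValueError):
            enrichment_test(0, 10, 11, 10)
        with pytest.raises(ValueError):
            enrichment_test(0, 0, 0, 10)

    def test_matches_enumeration_oracle_small_margins(self):
        for t_s in range(1, 9):
            for t_c in range(1, 9):
                for a in range(t_s + 1):
                    for g in range(t_c + 1):
                        p = enrichment_test(a, t_s, g, t_c)
                        assert p == pytest.approx(
                            float(hypergeom_upper_tail(a, t_s, g, t_c)), abs=1e-12
                        )


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_step_up_hand_example(self):
        # p=(0.01,0.02,0.03,0.04): q_i = min_j>=i p_(j)*4/j = 0.04 everywhere
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones_stay_one(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_step_up_formula_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = rng.random(rng.integers(1, 60))
            order = np.argsort(p)
            m = len(p)
            q_sorted = p[order] * m / np.arange(1, m + 1)
            q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            assert bh_fdr(p) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(0, 1), min_size=2, max_size=20),
        st.data(),
    )
    def test_monotone_in_any_single_p(self, pvals, data):
        """Decreasing one p never increases any adjusted value."""
        i = data.draw(st.integers(0, len(pvals) - 1))
        smaller = list(pvals)
        smaller[i] = data.draw(st.floats(0, pvals[i]))
        assert np.all(bh_fdr(smaller) <= bh_fdr(pvals) + 1e-12)


class TestIgtiob:
    @pytest.mark.parametrize(
        "s,a,score", [(5, 5, 0.0), (3, 0, 1.0), (0, 3, -1.0), (7, 3, 0.4)]
    )
    def test_signed_bias_fraction(self, s, a, score):
        assert igtiob(s, a) == pytest.approx(score)

    def test_undefined_without_intronic_insertions(self):
        assert np.isnan(igtiob(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            igtiob(-1, 2)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500))
    def test_antisymmetric_and_bounded(self, s, a):
        if s + a == 0:
            return
        assert igtiob(s, a) == pytest.approx(-igtiob(a, s))
        assert abs(igtiob(s, a)) <= 1.0


class TestCirclePlotTable:
    @pytest.fixture
    def results(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "inactivating_sorted": [10, 0, 3],
                "q_value": [0.01, 1.0, 0.5],
            }
        )

    def test_y_is_neg_log10_q(self, results):
        table = circle_plot_table(results, seed=0).set_index("gene_id")
        assert table.loc["g1", "y_neg_log10_q"] == pytest.approx(2.0)
        assert table.loc["g2", "y_neg_log10_q"] == pytest.approx(0.0)

    def test_diameter_proportional_to_inactivating_count(self, results):
        table = circle_plot_table(results, seed=0, diameter_per_insertion=3.0)
        by_gene = table.set_index("gene_id")["diameter"]
        assert by_gene["g1"] == pytest.approx(30.0)
        assert by_gene["g2"] == pytest.approx(0.0)

    def test_same_seed_same_order(self, results):
        t1 = circle_plot_table(results, seed=9)
        t2 = circle_plot_table(results, seed=9)
        assert list(t1["x_rank"]) == list(t2["x_rank"])


def test_screen_results_q_ordering_and_flags(toy_annotation):
    sorted_ds = make_dataset("sorted", [(150, "+"), (160, "+"), (310, "-")])
    control_ds = make_dataset("control", [(650, "+"), (900, "-"), (20, "+")])
    results = screen_results(sorted_ds, control_ds, toy_annotation)
    assert set(results["gene_id"]) == {"gA", "gB"}
    assert (results["q_value"] >= results["p_value"] - 1e-15).all()
    assert (results["hit_q_lt_0_01"] == (results["q_value"] < 0.01)).all()
    assert (results["hit_q_lt_1e_4"] == (results["q_value"] < 1e-4)).all()
    # sorted by q then p then gene_id
    assert results["q_value"].is_monotonic_increasing
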