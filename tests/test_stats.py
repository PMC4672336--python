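"""Tests for presence summaries, the exact test, and background presence
probability calculators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from dupggaa import (
    CompositionModel,
    MotifPattern,
    SequenceRecord,
    analytic_presence_probability,
    build_table1_report,
    exact_presence_probability,
    expected_match_count,
    fisher_exact,
    generate_random_set,
    has_duplicated_motif,
    summarize_presence,
)
from dupggaa.stats import (
    _fisher_two_sided_p,
    odds_ratio_estimate,
    percent_round,
    render_percent,
)


class TestPresenceSummary:
    @pytest.mark.parametrize(
        "present, total, pct",
        [(47, 58, 81.0), (30, 58, 51.7), (15, 60, 25.0), (0, 60, 0.0), (11, 58, 19.0), (28, 58, 48.3)],
    )
    def test_percent_rounding_half_up(self, present, total, pct):
        assert percent_round(present, total) == pct

    def test_render_suppresses_trailing_zero(self):
        assert render_percent(81.0) == "81"
        assert render_percent(51.7) == "51.7"
        assert render_percent(25.0) == "25"

    def test_summary_fields(self):
        s = summarize_presence([True] * 47 + [False] * 11, "ISG")
        assert (s.n_total, s.n_present, s.percent_present) == (58, 47, 81.0)
        assert s.render_cell() == "81 (47)"

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_presence([])

    @given(st.integers(0, 200), st.integers(1, 200))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_wilson_interval_contains_point_estimate(self, k, n):
        k = min(k, n)
        s = summarize_presence([True] * k + [False] * (n - k))
        assert s.ci_low <= k / n <= s.ci_high
        assert 0.0 <= s.ci_low and s.ci_high <= 1.0

    def test_wilson_degenerate_bounds(self):
        z = summarize_presence([False] * 60)
        assert z.ci_low == 0.0 and z.ci_high > 0.0
        full = summarize_presence([True] * 60)
        assert full.ci_high == 1.0 and full.ci_low < 1.0


class TestFisherExact:
    def test_symmetric_table(self):
        c = fisher_exact(5, 5, 5, 5)
        assert c.p_two_sided == 1.0
        assert c.odds_ratio == 1.0

    def test_diagonal_table_enumeration(self):
        # margins (3,3)/(3,3): the two extreme tables each have mass
        # C(3,3)C(3,0)/C(6,3) = 1/20, so the two-sided p is 2/20 = 0.1
        assert _fisher_two_sided_p(3, 0, 0, 3) == pytest.approx(0.1, abs=1e-15)

    def test_zero_row_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            _fisher_two_sided_p(0, 0, 3, 3)

    def test_zero_column_margin_is_degenerate_certainty(self):
        assert _fisher_two_sided_p(0, 5, 0, 5) == 1.0

    def test_haldane_correction_on_zero_cell(self):
        assert odds_ratio_estimate(3, 0, 0, 3) == pytest.approx((3.5 * 3.5) / (0.5 * 0.5))
        assert odds_ratio_estimate(2, 4, 1, 8) == pytest.approx(16 / 4)

    @given(st.integers(1, 30), st.integers(1, 30), st.data())
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_agrees_with_scipy_oracle(self, r1, r2, data):
        a = data.draw(st.integers(0, r1))
        c = data.draw(st.integers(0, r2))
        ours = _fisher_two_sided_p(a, r1 - a, c, r2 - c)
        ref = scipy_fisher([[a, r1 - a], [c, r2 - c]])[1]
        assert ours == pytest.approx(ref, abs=1e-12)

    @given(st.integers(1, 40), st.integers(1, 40), st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_swap_inverts_odds_and_preserves_p(self, r1, r2, data):
        a = data.draw(st.integers(0, r1))
        c = data.draw(st.integers(0, r2))
        fwd = fisher_exact(a, r1 - a, c, r2 - c)
        rev = fisher_exact(c, r2 - c, a, r1 - a)
        assert fwd.p_two_sided == pytest.approx(rev.p_two_sided, rel=1e-12)
        assert fwd.odds_ratio * rev.odds_ratio == pytest.approx(1.0, rel=1e-9)


class TestPresenceProbability:
    def test_uniform_model_closed_form_lambda(self):
        """3 pair types x sum over 11 spacers of (600-8-s+1) positions,
        each pair hitting with (1/256)^2."""
        lam = expected_match_count(CompositionModel.uniform(), 600)
        expected = 3 * sum(600 - 8 - s + 1 for s in range(11)) / 256**2
        assert lam == pytest.approx(expected)  # = 19404/65536 ~= 0.2961
        assert analytic_presence_probability(CompositionModel.uniform(), 600) == pytest.approx(
            1 - math.exp(-expected)
        )

    def test_too_short_sequence_has_zero_probability(self):
        assert analytic_presence_probability(CompositionModel.uniform(), 7) == 0.0
        assert exact_presence_probability(CompositionModel.uniform(), 7) == 0.0

    def test_impossible_core_has_zero_probability(self):
        m = CompositionModel(0, (0.5, 0.5, 0.0, 0.0))  # p(G) = 0
        assert analytic_presence_probability(m, 600) == 0.0
        assert exact_presence_probability(m, 600) == pytest.approx(0.0, abs=1e-12)

    def test_order1_directed_to_monte_carlo(self):
        m = fit_composition_stub()
        with pytest.raises(ValueError, match="Monte Carlo"):
            analytic_presence_probability(m, 600)
        with pytest.raises(ValueError, match="Monte Carlo"):
            exact_presence_probability(m, 600)

    @pytest.mark.parametrize("gc", [0.3, 0.41, 0.5, 0.6])
    def test_exact_matches_monte_carlo(self, gc):
        """Automaton probability vs simulation, 3 binomial SE (n = 20,000)."""
        at = (1 - gc) / 2
        model = CompositionModel(0, (at, gc / 2, gc / 2, at))
        n = 20_000
        recs = generate_random_set(model, n, 600, seed=int(gc * 100))
        hit = sum(has_duplicated_motif(r) for r in recs) / n
        p = exact_presence_probability(model, 600)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hit - p) <= 3 * se

    @pytest.mark.parametrize("gc", [0.3, 0.41, 0.5, 0.6])
    def test_poisson_approximation_close_to_exact(self, gc):
        """The Poisson closed form overestimates presence by the clumping
        of matches sharing a core; the error stays below 2 pp at these
        compositions (lambda <= 0.5)."""
        at = (1 - gc) / 2
        model = CompositionModel(0, (at, gc / 2, gc / 2, at))
        approx = analytic_presence_probability(model, 600)
        exact = exact_presence_probability(model, 600)
        assert exact <= approx  # clumping only lowers presence
        assert approx - exact < 0.02

    def test_exact_brute_force_tiny_case(self):
        """Length-9 sequences, spacer fixed at 1: enumeration over all 4^9
        sequences equals the automaton probability."""
        pattern = MotifPattern(spacer_min=1, spacer_max=1)
        model = CompositionModel(0, (0.4, 0.1, 0.2, 0.3))
        from itertools import product

        total = 0.0
        for tup in product("ACGT", repeat=9):
            s = "".join(tup)
            if has_duplicated_motif(SequenceRecord("t", s), pattern):
                total += math.prod(model.word_probability(ch) for ch in s)
        assert exact_presence_probability(model, 9, pattern) == pytest.approx(total, abs=1e-12)


def fit_composition_stub():
    from dupggaa import fit_composition

    return fit_composition([SequenceRecord("x", "ACGTAACCGGTT" * 60)], order=1)


class TestTable1Report:
    def test_cells_match_expected_formatting(self):
        sets = {
            "ISG": [True] * 47 + [False] * 11,
            "random_gene": [True] * 30 + [False] * 28,
            "random_seq": [True] * 15 + [False] * 45,
        }
        report = build_table1_report(sets)
        cells = [s.render_cell() for s in report.summaries]
        assert cells == ["81 (47)", "51.7 (30)", "25 (15)"]
        text = report.render()
        assert "81 (47)" in text and "51.7 (30)" in text and "25 (15)" in text
        assert "100 (58)" in text and "100 (60)" in text
        assert "19 (11)" in text  # absence row from counts, not complement of percent

    def test_json_keeps_numeric_percent(self):
        report = build_table1_report(
            {"a": [True] * 47 + [False] * 11, "b": [False] * 60}
        )
        assert '"percent_present": 81.0' in report.to_json()

    def test_identical_sets_not_distinguishable(self):
        tbl = [True] * 10 + [False] * 10
        report = build_table1_report({"a": list(tbl), "b": list(tbl)})
        assert all(c.p_two_sided == 1.0 for c in report.comparisons)

    def test_pairwise_comparisons_cover_all_pairs(self):
        report = build_table1_report(
            {"a": [True, False], "b": [True, True], "c": [False, False]}
        )
        pairs = {(c.summary_a.set_label, c.summary_b.set_label) for c in report.comparisons}
        assert pairs == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            build_table1_report({"a": [True]})

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            build_table1_report({"a": [True], "b": []})
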