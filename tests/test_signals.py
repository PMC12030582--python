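"""Disproportionality statistics: formulas, criteria, inversion."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy.stats import chi2_contingency

from gbsig.errors import InversionError, UndefinedStatisticError, UsageError
from gbsig.signals import (
    BcpnnPriors,
    ContingencyTable,
    CriteriaThresholds,
    SignalResult,
    apply_criteria,
    build_contingency,
    compute_bcpnn,
    compute_ebgm,
    compute_prr_chi2,
    compute_ror,
    evaluate_signal,
    invert_contingency,
    pearson_chi2,
    rank_signals,
)

positive_cells = st.integers(min_value=1, max_value=5000)


def table(a, b, c, d):
    return ContingencyTable(a, b, c, d)


class TestForwardStatistics:
    def test_balanced_table_is_null_on_all_algorithms(self):
        res = evaluate_signal(table(10, 10, 10, 10))
        assert res.ror == pytest.approx(1.0)
        assert res.prr == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0)
        assert res.ic == pytest.approx(0.0)
        assert res.ebgm == pytest.approx(1.0)
        assert not res.flags.overall

    def test_ror_point_and_interval(self):
        # 1.96 * sqrt(4/25) = 0.784 -> CI (exp(-0.784), exp(0.784))
        ror, lo, hi = compute_ror(table(25, 25, 25, 25))
        assert ror == pytest.approx(1.0)
        assert round(lo, 2) == 0.46
        assert round(hi, 2) == 2.19

    def test_ror_reciprocal_symmetry(self):
        t = table(7, 13, 29, 57)
        swapped = table(13, 7, 57, 29)
        assert compute_ror(t)[0] * compute_ror(swapped)[0] == pytest.approx(1.0)

    @given(a=positive_cells, b=positive_cells, c=positive_cells, d=positive_cells)
    @settings(max_examples=100, deadline=None)
    def test_chi2_matches_scipy_pearson(self, a, b, c, d):
        t = table(a, b, c, d)
        expected = chi2_contingency([[a, b], [c, d]], correction=False)[0]
        assert pearson_chi2(t) == pytest.approx(expected, rel=1e-12)

    @given(a=positive_cells, b=positive_cells, c=positive_cells, d=positive_cells)
    @settings(max_examples=100, deadline=None)
    def test_ic_is_log2_ebgm(self, a, b, c, d):
        t = table(a, b, c, d)
        bc = compute_bcpnn(t)
        ebgm, _ = compute_ebgm(t)
        assert bc.ic == pytest.approx(math.log2(ebgm), abs=1e-9)

    @given(a=positive_cells, b=positive_cells, c=positive_cells, d=positive_cells)
    @settings(max_examples=50, deadline=None)
    def test_chi2_invariant_under_transpose(self, a, b, c, d):
        assert pearson_chi2(table(a, b, c, d)) == pytest.approx(
            pearson_chi2(table(a, c, b, d)), rel=1e-12
        )

    def test_monotone_in_a_with_margins_fixed(self):
        # move one report from cell d to cell a keeping row/col totals free
        lo = evaluate_signal(table(5, 20, 40, 1000))
        hi = evaluate_signal(table(6, 19, 39, 1001))
        assert hi.ror > lo.ror
        assert hi.prr > lo.prr
        assert hi.ic > lo.ic
        assert hi.ebgm > lo.ebgm

    def test_ebgm05_below_ebgm(self):
        ebgm, ebgm05 = compute_ebgm(table(12, 40, 30, 900))
        assert 0 < ebgm05 < ebgm

    def test_zero_cell_raises_without_continuity(self):
        with pytest.raises(UndefinedStatisticError):
            compute_ror(table(0, 5, 5, 5))
        with pytest.raises(UndefinedStatisticError):
            compute_ebgm(table(5, 0, 5, 5))

    def test_continuity_correction_recovers_zero_cell(self):
        ror, lo, hi = compute_ror(table(0, 5, 5, 5), continuity=True)
        manual, _, _ = compute_ror(table(0.5, 5.5, 5.5, 5.5))
        assert ror == pytest.approx(manual)

    def test_mode_selects_the_ic_centre(self):
        t = table(16, 500, 4000, 2_000_000)
        point = compute_bcpnn(t, mode="point")
        posterior = compute_bcpnn(t, mode="posterior")
        assert point.ic_2sd == pytest.approx(point.ic - 2 * math.sqrt(point.v_ic))
        assert posterior.ic_2sd == pytest.approx(posterior.e_ic - 2 * math.sqrt(posterior.v_ic))
        # with a small observed count and a huge N the posterior expectation
        # is heavily shrunk below the point IC
        assert posterior.e_ic < point.ic


class TestCriteriaAndRanking:
    def test_all_four_criteria_fire_on_strong_signal(self):
        res = evaluate_signal(table(16, 510, 4078, 18_000_000))
        assert res.flags.ror and res.flags.prr and res.flags.bcpnn and res.flags.ebgm
        assert res.flags.overall

    def test_low_case_count_disables_ror_and_prr(self):
        res = evaluate_signal(table(2, 5, 50, 10_000))
        assert not res.flags.ror
        assert not res.flags.prr

    def test_ranking_orders_by_ror_and_drops_unflagged(self):
        strong1 = evaluate_signal(table(10, 50, 100, 100_000), drug="Mid")
        strong2 = evaluate_signal(table(30, 50, 100, 100_000), drug="Top")
        weak = evaluate_signal(table(2, 2, 100, 100_000), drug="TwoCases")
        ranked = rank_signals([weak, strong1, strong2])
        assert list(ranked["drug"]) == ["Top", "Mid"]

    def test_rank_ties_break_alphabetically(self):
        a = evaluate_signal(table(10, 50, 100, 100_000), drug="Btez")
        b = evaluate_signal(table(10, 50, 100, 100_000), drug="Atez")
        ranked = rank_signals([a, b])
        assert list(ranked["drug"]) == ["Atez", "Btez"]


class TestBuildContingency:
    def test_each_report_lands_in_one_cell(self, four_cell_reports):
        t = build_contingency(four_cell_reports, "DrugX", "Guillain-Barre syndrome")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
        assert t.n == len(four_cell_reports)

    def test_repeated_drug_mention_counts_once(self, four_cell_reports):
        from conftest import make_record
        from gbsig.faers import ReportSet

        rec = make_record("dup", drugs=(("DrugX", "PS"), ("DrugX", "SS")))
        rs = ReportSet(records=(rec,) + four_cell_reports.records)
        t = build_contingency(rs, "DrugX", "Guillain-Barre syndrome")
        assert t.a == 2
        assert t.n == 5

    def test_absent_drug_gives_zero_a_not_error(self, four_cell_reports):
        t = build_contingency(four_cell_reports, "Nosuchdrug", "Guillain-Barre syndrome")
        assert t.a == 0
        assert t.c == 2


class TestInversion:
    @given(
        a=st.integers(min_value=3, max_value=200),
        b=st.integers(min_value=3, max_value=2000),
        c=st.integers(min_value=3, max_value=5000),
        d=st.integers(min_value=1000, max_value=10_000_000),
    )
    @settings(max_examples=25, deadline=None)
    def test_round_trip_recovers_cells(self, a, b, c, d):
        ror, _, _ = compute_ror(table(a, b, c, d))
        prr, _, _, chi2 = compute_prr_chi2(table(a, b, c, d))
        # near-independent tables are not identifiable from their statistics;
        # the inversion is meant for elevated published signals
        assume(ror > 1.2 and chi2 > 4.0)
        rec = invert_contingency(a, ror, prr, chi2)
        assert rec.b == pytest.approx(b, rel=1e-3)
        assert rec.c == pytest.approx(c, rel=1e-3)
        assert rec.d == pytest.approx(d, rel=1e-3)

    def test_forward_recomputation_matches_inputs(self):
        rec = invert_contingency(16, 138.91, 134.71, 2115.68)
        ror, _, _ = compute_ror(rec)
        prr, _, _, chi2 = compute_prr_chi2(rec)
        assert ror == pytest.approx(138.91, rel=1e-4)
        assert prr == pytest.approx(134.71, rel=1e-4)
        assert chi2 == pytest.approx(2115.68, rel=1e-4)

    def test_published_rows_recover_plausible_margins(self):
        # the event margin a+c stays near the study's total case count and
        # the report total lands at FAERS scale
        rec16 = invert_contingency(16, 138.91, 134.71, 2115.68)
        assert rec16.c == pytest.approx(4078, abs=15)
        assert rec16.n == pytest.approx(1.82e7, rel=0.02)
        rec3 = invert_contingency(3, 60.62, 59.81, 173.4)
        assert rec3.a + rec3.c == pytest.approx(4094, rel=0.10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(UsageError):
            invert_contingency(0, 10.0, 9.0, 50.0)
        with pytest.raises(UsageError):
            invert_contingency(5, -1.0, 9.0, 50.0)

    def test_unsatisfiable_statistics_raise_inversion_error(self):
        # chi-square far above its achievable bound for these ROR/PRR at a=3
        with pytest.raises(InversionError) as err:
            invert_contingency(3, 60.62, 59.81, 5e6)
        assert err.value.best_residual is None or err.value.best_residual > 1e-6
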