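"""Subgroup extraction, combination summaries, the 2x2 table and the exact test."""

import math

import numpy as np
import pytest
from scipy.stats import contingency as sp_contingency
from scipy.stats import fisher_exact as sp_fisher

import trackermine as tm
from trackermine.analysis import N_TRACKERS, TwoByTwoTable

from _oracles import conditional_mle_grid, fisher_p_enumeration


def cohort_from_counts(combo_counts, diff_significant=1.0):
    """Cohort with given per-combination user counts, all clinically reduced."""
    combos = {
        "food_only": (0, 30, 0),
        "glucose_only": (30, 0, 0),
        "exercise_only": (0, 0, 30),
        "glucose_exercise": (30, 0, 15),
        "glucose_food": (130, 30, 0),
        "food_exercise": (0, 30, 15),
        "all_three": (130, 100, 30),
    }
    usage, hba1c = [], []
    i = 0
    for combo, n in combo_counts.items():
        g, f, e = combos[combo]
        for _ in range(n):
            i += 1
            pid = f"P{i:02d}"
            usage.append(tm.UsageRecord(pid, g, f, e))
            hba1c.append(tm.HbA1cRecord(pid, 8.0, round(8.0 - diff_significant, 2)))
    return tm.Cohort.from_records(usage, hba1c)


class TestClassification:
    @pytest.mark.parametrize(
        "counts,combo",
        [
            ((0, 3, 0), "food_only"),
            ((10, 0, 4), "glucose_exercise"),
            ((0, 0, 0), "none"),
            ((1, 1, 1), "all_three"),
            ((5, 2, 0), "glucose_food"),
        ],
    )
    def test_combination_is_exact_used_set(self, counts, combo):
        g, f, e = counts
        assert tm.classify_combination(tm.UsageRecord("P1", g, f, e)) == combo

    def test_n_trackers_consistent(self):
        for combo, k in N_TRACKERS.items():
            assert combo.count("_") >= 0  # sanity on the label set
            assert 0 <= k <= 3


class TestExtractSoi:
    def test_threshold_is_inclusive(self):
        cohort = tm.Cohort.from_records(
            [tm.UsageRecord("P1", 10, 0, 0), tm.UsageRecord("P2", 10, 0, 0)],
            [tm.HbA1cRecord("P1", 8.0, 7.5), tm.HbA1cRecord("P2", 8.0, 7.6)],
        )
        soi = tm.extract_soi(cohort, 0.5)
        assert soi.participant_ids == ["P1"]  # diff exactly 0.5 included

    def test_non_users_excluded_even_when_improved(self):
        cohort = tm.Cohort.from_records(
            [tm.UsageRecord("P1", 0, 0, 0)], [tm.HbA1cRecord("P1", 9.0, 7.0)]
        )
        assert len(tm.extract_soi(cohort, 0.5)) == 0

    def test_default_synthetic_cohort_has_29_soi_of_39_users(self, cohort):
        assert len(cohort) == 48
        assert len(tm.software_users(cohort)) == 39
        assert len(tm.extract_soi(cohort)) == 29

    def test_partition_of_software_users(self, cohort):
        users = tm.software_users(cohort)
        soi = tm.extract_soi(cohort)
        rest = [u for u, h in users if h.a1c6month_diff < 0.5 - 1e-9]
        assert len(soi) + len(rest) == len(users)


class TestSummaries:
    STUDY_COUNTS = {
        "food_only": 2, "glucose_only": 7, "exercise_only": 0,
        "glucose_exercise": 11, "glucose_food": 3, "food_exercise": 0,
        "all_three": 6,
    }

    def test_single_dual_triple_shares(self):
        cohort = cohort_from_counts(self.STUDY_COUNTS)
        shares = tm.tracker_count_shares(tm.summarize_groups(cohort))
        assert shares["single"] == {"n": 9, "pct": 31}
        assert shares["dual"] == {"n": 14, "pct": 48}
        assert shares["triple"] == {"n": 6, "pct": 21}

    def test_singleton_group_reports_zero_sd(self):
        cohort = cohort_from_counts({"food_only": 1})
        (summary,) = [s for s in tm.summarize_groups(cohort) if s.n_users]
        assert summary.combination == "food_only"
        assert summary.sd_reduction == 0.0

    def test_mean_and_sample_sd(self):
        usage = [tm.UsageRecord(f"P{i}", 10, 0, 0) for i in range(3)]
        hba1c = [tm.HbA1cRecord(f"P{i}", 8.0, 8.0 - d) for i, d in enumerate((1.0, 1.5, 2.0))]
        summaries = tm.summarize_groups(tm.Cohort.from_records(usage, hba1c))
        s = next(s for s in summaries if s.combination == "glucose_only")
        assert s.mean_reduction == pytest.approx(1.5)
        assert s.sd_reduction == pytest.approx(0.5)


class TestTwoByTwo:
    def test_default_synthetic_cohort_reproduces_study_table(self, cohort):
        table = tm.build_2x2(tm.software_users(cohort))
        assert (table.a, table.b, table.c, table.d) == (6, 6, 23, 4)
        assert table.n == 39

    def test_all_users_below_threshold(self):
        cohort = cohort_from_counts({"all_three": 2, "glucose_only": 3}, diff_significant=0.1)
        table = tm.build_2x2(cohort)
        assert (table.a, table.c) == (0, 0) and (table.b, table.d) == (2, 3)

    def test_zero_use_participant_rejected(self):
        cohort = tm.Cohort.from_records(
            [tm.UsageRecord("P1", 0, 0, 0)], [tm.HbA1cRecord("P1", 8.0, 7.0)]
        )
        with pytest.raises(ValueError, match="software users"):
            tm.build_2x2(cohort)


class TestFisherExact:
    def test_study_table_rounds_to_published_estimates(self):
        res = tm.fisher_exact(TwoByTwoTable(6, 6, 23, 4))
        assert round(res.odds_ratio, 2) == 0.18
        assert round(res.p_two_sided, 2) == 0.04

    def test_conditional_mle_differs_from_sample_odds_ratio(self):
        table = TwoByTwoTable(6, 6, 23, 4)
        assert table.sample_odds_ratio() == pytest.approx(24 / 138)
        assert round(table.sample_odds_ratio(), 2) == 0.17
        assert conditional_mle_grid(6, 6, 23, 4) == pytest.approx(
            tm.fisher_exact(table).odds_ratio, rel=3e-3
        )

    def test_symmetric_table(self):
        res = tm.fisher_exact(TwoByTwoTable(5, 5, 5, 5))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_degenerate_margin(self):
        res = tm.fisher_exact(TwoByTwoTable(0, 0, 3, 4))
        assert res.degenerate and res.p_two_sided == 1.0 and math.isnan(res.odds_ratio)

    def test_invariance_under_transpose_and_label_swap(self):
        base = TwoByTwoTable(6, 6, 23, 4)
        p = tm.fisher_exact(base).p_two_sided
        assert tm.fisher_exact(TwoByTwoTable(6, 23, 6, 4)).p_two_sided == pytest.approx(p)
        assert tm.fisher_exact(TwoByTwoTable(4, 23, 6, 6)).p_two_sided == pytest.approx(p)

    def test_odds_ratio_monotone_in_first_cell(self):
        # fixed margins r1=12, r2=27, c1=29 as in the study table
        ors = []
        for a in range(2, 13):
            table = TwoByTwoTable(a, 12 - a, 29 - a, 27 - (29 - a))
            ors.append(tm.fisher_exact(table).odds_ratio)
        finite = [o for o in ors if math.isfinite(o)]
        assert finite == sorted(finite)
        assert ors[0] == 0.0 and math.isinf(ors[-1])

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_enumeration_and_grid_oracles(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 9, size=4))
        table = TwoByTwoTable(a, b, c, d)
        res = tm.fisher_exact(table)
        if res.degenerate:
            assert res.p_two_sided == 1.0
            return
        assert res.p_two_sided == pytest.approx(fisher_p_enumeration(a, b, c, d), rel=1e-9)
        want_or = conditional_mle_grid(a, b, c, d)
        if math.isinf(want_or):
            assert math.isinf(res.odds_ratio)
        else:
            assert res.odds_ratio == pytest.approx(want_or, rel=1e-2, abs=1e-3)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_scipy_reference(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b, c, d = (int(x) for x in rng.integers(1, 9, size=4))
        res = tm.fisher_exact(TwoByTwoTable(a, b, c, d))
        ref_or = sp_contingency.odds_ratio([[a, b], [c, d]], kind="conditional").statistic
        _, ref_p = sp_fisher([[a, b], [c, d]])
        assert res.odds_ratio == pytest.approx(ref_or, rel=1e-6)
        assert res.p_two_sided == pytest.approx(ref_p, rel=1e-9)


class TestRunPipeline:
    def test_report_contains_headline_numbers(self, cohort):
        report = tm.run_pipeline(cohort, mine=False)
        assert report["two_by_two"] == {"a": 6, "b": 6, "c": 23, "d": 4}
        assert round(report["odds_ratio_conditional_mle"], 2) == 0.18
        assert round(report["p_two_sided"], 2) == 0.04
        assert report["tracker_count_shares"]["single"]["pct"] == 31
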