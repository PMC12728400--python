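import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from vaxcheck import errors
from vaxcheck.umars import (
    ALL_ITEMS,
    IMPACT_ITEMS,
    SUBSCALE_ITEMS,
    UmarsSheet,
    aggregate_item_means,
    agreement_proportions,
    compare_groups,
    compare_groups_from_stats,
    read_sheets_csv,
    round_half_up,
    sample_size_for_mean,
    score_sheets,
)


def make_sheet(rater_id="r1", stratum="dermatologist", fill=4, **overrides):
    scores = {item: fill for item in ALL_ITEMS}
    scores.update(overrides)
    return UmarsSheet(rater_id=rater_id, stratum=stratum, scores=scores)


def random_sheets(n, seed=0):
    rng = np.random.default_rng(seed)
    return [
        make_sheet(
            rater_id=f"r{i}",
            stratum="dermatologist" if i % 3 else "public_health_physician",
            **{item: int(rng.integers(1, 6)) for item in ALL_ITEMS},
        )
        for i in range(n)
    ]


class TestSheetValidation:
    def test_item_counts_enforced(self):
        with pytest.raises(errors.MalformedSheetError):
            UmarsSheet("r", "dermatologist", {"e1": 5})

    def test_score_range_enforced(self):
        with pytest.raises(errors.MalformedSheetError):
            make_sheet(e1=6)
        with pytest.raises(errors.MalformedSheetError):
            make_sheet(e1=0)

    def test_unknown_stratum_rejected(self):
        with pytest.raises(errors.MalformedSheetError):
            make_sheet(stratum="nurse")

    def test_twenty_six_items(self):
        assert len(ALL_ITEMS) == 26
        assert [len(v) for v in SUBSCALE_ITEMS.values()] == [5, 4, 3, 4]


class TestScoring:
    def test_constant_sheet_scores_five_everywhere(self):
        summary = score_sheets([make_sheet(fill=5)])
        for subscale in SUBSCALE_ITEMS:
            assert summary.subscale_stats[subscale].mean == 5.0
        assert summary.total_stats.mean == 5.0

    def test_total_is_mean_of_subscale_means_per_rater(self):
        sheets = random_sheets(30)
        summary = score_sheets(sheets)
        for sheet, total in zip(sheets, summary.per_rater_totals):
            expected = np.mean([sheet.subscale_mean(s) for s in SUBSCALE_ITEMS])
            assert total == pytest.approx(expected, abs=1e-12)

    def test_subscale_mean_bounded_by_item_means(self):
        sheets = random_sheets(25, seed=4)
        summary = score_sheets(sheets)
        for subscale, items in SUBSCALE_ITEMS.items():
            item_means = [summary.item_stats[i].mean for i in items]
            s = summary.subscale_stats[subscale].mean
            assert min(item_means) - 1e-12 <= s <= max(item_means) + 1e-12

    def test_na_items_dropped_from_that_raters_mean(self):
        sheet = make_sheet(e1=None, e2=5, e3=5, e4=5, e5=None)
        assert sheet.subscale_mean("engagement") == 5.0

    def test_all_na_subscale_is_undefined(self):
        sheet = make_sheet(a1=None, a2=None, a3=None)
        assert np.isnan(sheet.subscale_mean("aesthetics"))
        assert np.isnan(sheet.total_score())

    def test_empty_input_rejected(self):
        with pytest.raises(errors.EmptyInputError):
            score_sheets([])

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        sheets = random_sheets(10, seed=9)
        rows = [
            {"rater_id": s.rater_id, "stratum": s.stratum, **s.scores} for s in sheets
        ]
        path = tmp_path / "survey.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        loaded = read_sheets_csv(str(path))
        assert [s.scores for s in loaded] == [s.scores for s in sheets]
        assert score_sheets(loaded).total_stats == score_sheets(sheets).total_stats


class TestAggregateFromItemMeans:
    def test_subscale_and_total_identities(self):
        agg = aggregate_item_means(
            {
                "engagement": [3.83, 4.33, 3.50, 3.52, 4.26],
                "functionality": [4.33, 4.67, 4.46, 4.41],
                "aesthetics": [4.09, 3.78, 3.78],
                "information": [4.74, 4.52, 4.54, 4.80],
            }
        )
        assert round_half_up(agg["engagement"], 2) == 3.89
        assert round_half_up(agg["functionality"], 2) == 4.47
        assert round_half_up(agg["aesthetics"], 2) == 3.88
        assert round_half_up(agg["total"], 2) == 4.22

    def test_wrong_item_count_rejected(self):
        with pytest.raises(errors.InvalidParameterError):
            aggregate_item_means({"engagement": [4.0, 4.0]})


class TestGroupComparison:
    def test_identical_groups_null_case(self):
        cmp = compare_groups([3, 4, 5, 4], [3, 4, 5, 4])
        assert cmp.t == 0.0
        assert cmp.two_sided_p == pytest.approx(1.0)

    def test_pooled_hand_computed_example(self):
        cmp = compare_groups([1, 2, 3], [4, 5, 6], variant="pooled")
        assert cmp.t == pytest.approx(-3.674, abs=5e-4)
        assert cmp.df == 4
        assert cmp.two_sided_p == pytest.approx(0.0213, abs=2e-4)

    @pytest.mark.parametrize("variant, equal_var", [("pooled", True), ("welch", False)])
    def test_agrees_with_reference_implementation(self, variant, equal_var):
        rng = np.random.default_rng(12)
        a = rng.normal(4.2, 0.5, size=29)
        b = rng.normal(4.0, 0.6, size=17)
        ours = compare_groups(a, b, variant=variant)
        ref = sps.ttest_ind(a, b, equal_var=equal_var)
        assert ours.t == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.two_sided_p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_summary_statistic_input_matches_reference(self):
        ours = compare_groups_from_stats(4.28, 0.48, 29, 4.12, 0.51, 17)
        ref = sps.ttest_ind_from_stats(4.28, 0.48, 29, 4.12, 0.51, 17, equal_var=False)
        assert ours.t == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.two_sided_p == pytest.approx(ref.pvalue, rel=1e-12)
        assert ours.two_sided_p > 0.05  # similar group means

    def test_swapping_groups_negates_t_preserves_p(self):
        a, b = [1.0, 2.0, 3.5], [2.0, 4.0, 4.5, 5.0]
        ab = compare_groups(a, b)
        ba = compare_groups(b, a)
        assert ab.t == pytest.approx(-ba.t)
        assert ab.two_sided_p == pytest.approx(ba.two_sided_p)

    def test_welch_equals_pooled_for_balanced_equal_variance(self):
        a, b = [1, 2, 3, 4], [2, 3, 4, 5]
        w = compare_groups(a, b, "welch")
        p = compare_groups(a, b, "pooled")
        assert w.t == pytest.approx(p.t)
        assert w.df == pytest.approx(p.df)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(errors.InsufficientNError):
            compare_groups([1], [2, 3])
        with pytest.raises(errors.ZeroVarianceError):
            compare_groups([2, 2, 2], [2, 2, 2], variant="pooled")


class TestSampleSize:
    def test_planning_value_for_the_survey(self):
        assert sample_size_for_mean(sd=0.45, precision=0.15, confidence=0.95) == 35

    def test_precision_equal_to_sd(self):
        # ceil(1.96**2) = 4
        assert sample_size_for_mean(sd=0.45, precision=0.45, confidence=0.95) == 4

    @given(
        sd=st.floats(min_value=0.05, max_value=2.0),
        precision=st.floats(min_value=0.01, max_value=1.0),
        confidence=st.floats(min_value=0.5, max_value=0.999),
    )
    def test_minimality(self, sd, precision, confidence):
        n = sample_size_for_mean(sd, precision, confidence)
        z = float(sps.norm.ppf(0.5 + confidence / 2))
        assert z * sd / np.sqrt(n) <= precision
        if n > 1:
            assert z * sd / np.sqrt(n - 1) > precision

    def test_monotone_in_parameters(self):
        base = sample_size_for_mean(0.45, 0.15, 0.95)
        assert sample_size_for_mean(0.60, 0.15, 0.95) >= base
        assert sample_size_for_mean(0.45, 0.10, 0.95) >= base
        assert sample_size_for_mean(0.45, 0.15, 0.99) >= base

    def test_invalid_parameters_rejected(self):
        for bad in [(-1, 0.1, 0.95), (0.45, 0, 0.95), (0.45, 0.1, 1.0)]:
            with pytest.raises(errors.InvalidParameterError):
                sample_size_for_mean(*bad)


class TestAgreement:
    def test_39_of_46(self):
        scores = [5] * 20 + [4] * 19 + [3] * 4 + [2] * 3
        result = agreement_proportions({"p1": scores})["p1"]
        assert (result.n_agree, result.n, result.percent) == (39, 46, 85)

    def test_18_of_46(self):
        scores = [4] * 18 + [3] * 28
        assert agreement_proportions({"p3": scores})["p3"].percent == 39

    def test_zero_agreement(self):
        assert agreement_proportions({"p1": [1, 2, 3] * 3 + [1]})["p1"].percent == 0

    def test_percent_rounds_half_up(self):
        # 1/8 = 12.5% -> 13
        assert agreement_proportions({"p1": [4] + [1] * 7})["p1"].percent == 13

    def test_impact_summary_from_sheets(self):
        sheets = random_sheets(20, seed=2)
        summary = score_sheets(sheets)
        assert set(summary.impact) == set(IMPACT_ITEMS)
        for item, result in summary.impact.items():
            manual = sum(1 for s in sheets if s.scores[item] >= 4)
            assert result.n_agree == manual
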