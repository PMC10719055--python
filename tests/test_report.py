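"""Aggregate tables, rounding convention, and the origin chi-square test."""

import pandas as pd
import pytest

from cpcf_npm.pipeline import assess_products
from cpcf_npm.report import (
    chi_square_from_counts,
    compare_origin,
    format_percentage,
    summarize_labelling,
    summarize_nutrient_content,
    summarize_nutrient_performance,
    summarize_subcategories,
)
from cpcf_npm.synthetic import MarketConfig, generate_market


class TestFormatPercentage:
    @pytest.mark.parametrize(
        "count,denom,expected",
        [
            (606, 1635, 37.1),
            (391, 556, 70.3),
            (0, 7, 0.0),
            (14, 176, 8.0),   # half-away-from-zero: 7.954... -> 8.0
            (1, 8, 12.5),
            (1, 16, 6.3),     # 6.25 rounds away from zero
        ],
    )
    def test_rounding_convention(self, count, denom, expected):
        assert format_percentage(count, denom) == expected

    def test_zero_denominator_is_an_error(self):
        with pytest.raises(ValueError):
            format_percentage(0, 0)


def frame(rows):
    return pd.DataFrame(rows)


def assessment_row(**kw):
    base = dict(
        product_id="x", country="TH", manufacturer_origin="national",
        subcategory="other_snacks_finger_foods", auto_failed=False,
        no_added_sugar="met", sugar_energy_lt_15pct="met", sodium_limit="met",
        fat_limit="met", n_applicable=4, n_met=4, nutrient_pass=True,
        energy_kcal_per_100g=400.0, sugar_g_per_100g=2.0, sodium_mg_per_100g=10.0,
        fat_g_per_100g=2.0, satfat_g_per_100g=0.5,
        **{f"L{i}": "met" for i in range(1, 13)},
        group_breastfeeding=True, group_claims=True, group_clarity=True,
        labelling_pass=True,
    )
    base.update(kw)
    return base


class TestSubcategoryTable:
    def test_toy_distribution(self):
        rows = [assessment_row(product_id=str(i)) for i in range(9)]
        rows.append(
            assessment_row(
                product_id="c", subcategory="confectionery_sweet_spreads_fruit_chews",
                auto_failed=True,
            )
        )
        table = summarize_subcategories(frame(rows))
        cell = table[
            (table.stratum == "All products")
            & (table.subcategory == "confectionery_sweet_spreads_fruit_chews")
        ].iloc[0]
        assert (cell["percentage"], cell["count"]) == (10.0, 1)

    def test_absent_subcategory_rendered_as_zero_count(self):
        table = summarize_subcategories(frame([assessment_row()]))
        fruit = table[
            (table.stratum == "All products") & (table.subcategory == "fruit_fresh_or_dry")
        ].iloc[0]
        assert fruit["count"] == 0 and fruit["percentage"] == 0.0

    def test_published_malaysia_style_counts(self):
        rows = (
            [assessment_row(product_id=f"c{i}", country="MY",
                            subcategory="confectionery_sweet_spreads_fruit_chews",
                            auto_failed=True) for i in range(14)]
            + [assessment_row(product_id=f"f{i}", country="MY",
                              subcategory="fruit_fresh_or_dry") for i in range(3)]
            + [assessment_row(product_id=f"o{i}", country="MY") for i in range(159)]
        )
        table = summarize_subcategories(frame(rows))
        my = table[table.stratum == "MY"].set_index("subcategory")
        assert my.loc["confectionery_sweet_spreads_fruit_chews", "percentage"] == 8.0
        assert my.loc["fruit_fresh_or_dry", "percentage"] == 1.7
        assert my.loc["other_snacks_finger_foods", "percentage"] == 90.3


class TestNutrientPerformanceTable:
    def test_median_and_range_of_requirements_met(self):
        rows = [
            assessment_row(product_id=str(i), n_met=m, nutrient_pass=(m == 4))
            for i, m in enumerate([4, 3, 2, 0])
        ]
        table = summarize_nutrient_performance(frame(rows))
        overall = table[table.stratum == "All products"].iloc[0]
        assert overall["n_met_median"] == 2.5
        assert (overall["n_met_min"], overall["n_met_max"]) == (0, 4)

    def test_sugar_denominator_excludes_fruit_subcategory(self):
        rows = [assessment_row(product_id=str(i)) for i in range(5)] + [
            assessment_row(
                product_id="fr", subcategory="fruit_fresh_or_dry",
                sugar_energy_lt_15pct="not_applicable", n_applicable=3, n_met=3,
            )
        ]
        table = summarize_nutrient_performance(frame(rows))
        overall = table[table.stratum == "All products"].iloc[0]
        assert overall["sugar_energy_lt_15pct_denominator"] == 5
        assert overall["sodium_limit_denominator"] == 6
        # denominator bookkeeping: applicable + exempt = assessed
        assert overall["sugar_energy_lt_15pct_denominator"] + 1 == overall["n"]

    def test_confectionery_input_is_rejected(self):
        with pytest.raises(ValueError, match="auto-failed"):
            summarize_nutrient_performance(frame([assessment_row(auto_failed=True)]))

    def test_empty_input_is_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_nutrient_performance(frame([assessment_row()]).iloc[:0])


class TestNutrientContentTable:
    def test_median_and_missing_exclusion(self):
        rows = [
            assessment_row(product_id="a", sodium_mg_per_100g=0.0),
            assessment_row(product_id="b", sodium_mg_per_100g=10.0),
            assessment_row(product_id="c", sodium_mg_per_100g=20.0),
            assessment_row(product_id="d", sodium_mg_per_100g=None),
            assessment_row(product_id="e", sodium_mg_per_100g=None),
        ]
        table = summarize_nutrient_content(frame(rows))
        overall = table[table.stratum == "All products"].iloc[0]
        assert overall["sodium_n"] == 3
        assert overall["sodium_median"] == 10.0

    def test_even_count_median_is_mean_of_middle_two(self):
        rows = [
            assessment_row(product_id=str(i), sugar_g_per_100g=v)
            for i, v in enumerate([2.0, 4.0, 6.0, 8.0])
        ]
        table = summarize_nutrient_content(frame(rows))
        assert table[table.stratum == "All products"].iloc[0]["sugar_median"] == 5.0


class TestLabellingTable:
    def test_all_ideal_rows_give_100_percent(self):
        table = summarize_labelling(frame([assessment_row(product_id=str(i)) for i in range(4)]))
        overall = table[table.stratum == "All products"].iloc[0]
        assert overall["met_all_percentage"] == 100.0
        assert all(overall[f"L{i}_percentage"] == 100.0 for i in range(1, 13))

    def test_l3_blocks_breastfeeding_subtotal(self):
        rows = [
            assessment_row(product_id=str(i), L3="not_met", group_breastfeeding=False,
                           labelling_pass=False)
            for i in range(3)
        ]
        overall = summarize_labelling(frame(rows)).iloc[-1]
        assert overall["breastfeeding_percentage"] == 0.0
        assert overall["breastfeeding_count"] == 0

    def test_fruit_percentage_denominator_restricted(self):
        rows = [
            assessment_row(product_id=f"f{i}", L12=("met" if i < 5 else "not_met"))
            for i in range(8)
        ] + [
            assessment_row(product_id=f"n{i}", L12="not_applicable") for i in range(4)
        ]
        overall = summarize_labelling(frame(rows)).iloc[-1]
        assert overall["L12_denominator"] == 8
        assert overall["L12_count"] == 5
        assert overall["L12_percentage"] == 62.5


class TestCompareOrigin:
    def test_reconstructed_published_comparison(self):
        res = chi_square_from_counts(23, 165, 59, 391)
        assert res.statistic == pytest.approx(0.122, abs=0.001)
        assert res.p_value == pytest.approx(0.727, abs=0.0005)

    def test_identical_proportions_give_zero_statistic(self):
        res = chi_square_from_counts(10, 20, 10, 20)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_extreme_separation(self):
        res = chi_square_from_counts(20, 20, 0, 20)
        assert res.statistic == pytest.approx(40.0)
        assert res.p_value < 1e-9

    def test_degenerate_marginal_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_from_counts(0, 20, 0, 20)

    def test_statistic_invariant_under_row_and_column_swap(self):
        a = chi_square_from_counts(23, 165, 59, 391)
        swapped_rows = chi_square_from_counts(59, 391, 23, 165)
        swapped_cols = chi_square_from_counts(165 - 23, 165, 391 - 59, 391)
        assert a.statistic == pytest.approx(swapped_rows.statistic)
        assert a.statistic == pytest.approx(swapped_cols.statistic)

    def test_unknown_origin_excluded_from_dataframe_path(self):
        rows = (
            [assessment_row(product_id=f"n{i}", manufacturer_origin="national",
                            nutrient_pass=(i == 0)) for i in range(10)]
            + [assessment_row(product_id=f"i{i}", manufacturer_origin="international",
                              nutrient_pass=(i < 2)) for i in range(10)]
            + [assessment_row(product_id="u", manufacturer_origin="unknown")]
        )
        res = compare_origin(frame(rows))
        assert res.n_excluded_unknown == 1
        assert res.table == [[1, 9], [2, 8]]


def test_every_percentage_cell_recomputable_from_count_and_denominator():
    records, _ = generate_market(MarketConfig(n_products=400, seed=9))
    result = assess_products(records, dedup=False)
    assessed = result.assessments[~result.assessments.auto_failed]
    for table in (
        summarize_subcategories(result.assessments),
        summarize_nutrient_performance(assessed),
        summarize_labelling(result.assessments),
    ):
        for col in [c for c in table.columns if c.endswith("_percentage") or c == "percentage"]:
            stem = col[: -len("_percentage")] if col.endswith("_percentage") else ""
            ccol = f"{stem}_count" if stem else "count"
            dcol = f"{stem}_denominator" if stem else "denominator"
            for _, row in table.iterrows():
                if row[dcol]:
                    assert row[col] == format_percentage(int(row[ccol]), int(row[dcol]))
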