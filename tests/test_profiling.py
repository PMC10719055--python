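"""Nutrient normalization, added-sugar detection and the four composition rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpcf_npm.profiling import (
    AddedSugarResult,
    NutrientRequirement,
    Provenance,
    Reason,
    Status,
    detect_added_sugar,
    evaluate_nutrient_requirements,
    normalize_nutrients,
    salt_to_sodium,
    sugar_energy_limit_g_per_100kcal,
)
from cpcf_npm.records import (
    FingerFoodSubcategory,
    IngredientEntry,
    NutrientDeclaration,
    NutrientValues,
)

SUB = FingerFoodSubcategory
R = NutrientRequirement


def profile_from(energy=None, sugar=None, sodium=None, salt=None, fat=None, satfat=None):
    return normalize_nutrients(
        NutrientDeclaration(
            per_100g=NutrientValues(
                energy_kcal=energy, total_sugar_g=sugar, sodium_mg=sodium,
                salt_g=salt, total_fat_g=fat, saturated_fat_g=satfat,
            )
        )
    )


def no_sugar() -> AddedSugarResult:
    return AddedSugarResult(found=False)


class TestConversions:
    @pytest.mark.parametrize("salt,sodium", [(1.0, 0.4), (0.0, 0.0), (2.5, 1.0)])
    def test_salt_to_sodium(self, salt, sodium):
        assert salt_to_sodium(salt) == pytest.approx(sodium)

    def test_negative_salt_is_an_error(self):
        with pytest.raises(ValueError):
            salt_to_sodium(-0.1)

    def test_percent_energy_and_per_100kcal_from_fat(self):
        p = profile_from(energy=450.0, fat=10.0)
        assert p.pct_energy_fat == pytest.approx(20.0)
        assert p.fat_g_per_100kcal == pytest.approx(10.0 * 100 / 450)

    def test_sugar_at_3_75_g_per_100kcal_is_15_percent_energy(self):
        p = profile_from(energy=400.0, sugar=15.0)
        assert p.sugar_g_per_100kcal == pytest.approx(3.75)
        assert p.pct_energy_sugar == pytest.approx(15.0)

    def test_salt_chain_to_sodium_per_100kcal(self):
        p = profile_from(energy=400.0, salt=0.5)
        assert p.sodium_mg_per_100g == pytest.approx(200.0)
        assert p.sodium_mg_per_100kcal == pytest.approx(50.0)
        assert Provenance.converted_from_salt in p.provenance["sodium_mg_per_100g"]

    def test_declared_sodium_wins_over_salt(self):
        p = profile_from(energy=400.0, sodium=10.0, salt=0.5)
        assert p.sodium_mg_per_100g == 10.0
        assert p.provenance["sodium_mg_per_100g"] == [Provenance.declared]

    def test_per_serving_rescaled(self):
        decl = NutrientDeclaration(
            serving_size_g=25.0,
            per_serving=NutrientValues(energy_kcal=100.0, total_sugar_g=2.5),
        )
        p = normalize_nutrients(decl)
        assert p.energy_kcal_per_100g == pytest.approx(400.0)
        assert p.sugar_g_per_100g == pytest.approx(10.0)
        assert Provenance.converted_from_serving in p.provenance["sugar_g_per_100g"]

    def test_per_serving_without_serving_size_degrades_to_absent(self, caplog):
        decl = NutrientDeclaration(per_serving=NutrientValues(total_sugar_g=2.5))
        with caplog.at_level("WARNING"):
            p = normalize_nutrients(decl)
        assert p.sugar_g_per_100g is None
        assert "serving size" in caplog.text

    def test_kj_only_energy_converted(self):
        p = profile_from()
        decl = NutrientDeclaration(per_100g=NutrientValues(energy_kj=1799.12))
        p = normalize_nutrients(decl)
        assert p.energy_kcal_per_100g == pytest.approx(1799.12 / 4.184)

    def test_zero_energy_leaves_per_100kcal_absent(self):
        p = profile_from(energy=0.0, sugar=5.0)
        assert p.sugar_g_per_100kcal is None
        assert p.pct_energy_sugar is None

    def test_absent_inputs_propagate_to_absent_outputs(self):
        p = profile_from(energy=400.0)
        assert p.sugar_g_per_100g is None
        assert p.sodium_mg_per_100kcal is None

    @given(
        energy=st.floats(10.0, 900.0),
        value=st.floats(0.0, 60.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_per_100kcal_conversion_identity(self, energy, value):
        p = profile_from(energy=energy, sugar=value, fat=value)
        assert p.sugar_g_per_100kcal * energy / 100.0 == pytest.approx(value, rel=1e-9, abs=1e-12)
        assert p.fat_g_per_100kcal * energy / 100.0 == pytest.approx(value, rel=1e-9, abs=1e-12)


class TestAddedSugarDetection:
    def entries(self, *names):
        return [IngredientEntry(name=n) for n in names]

    def test_glucose_syrup_matches_two_terms(self):
        res = detect_added_sugar(self.entries("rice flour", "glucose syrup"))
        assert res.found is True
        assert {t for _, t in res.matches} == {"glucose", "syrup"}

    def test_lemon_and_lime_juice_are_exempt(self):
        assert detect_added_sugar(self.entries("apple", "lemon juice")).found is False
        assert detect_added_sugar(self.entries("lime juice")).found is False

    def test_other_fruit_juice_triggers(self):
        res = detect_added_sugar(self.entries("concentrated apple juice"))
        assert res.found is True

    def test_plain_ingredients_do_not_trigger(self):
        assert detect_added_sugar(self.entries("wheat flour", "salt", "vegetable oil")).found is False

    def test_maltodextrin_is_outside_the_default_lexicon(self):
        assert detect_added_sugar(self.entries("maltodextrin")).found is False

    def test_nonsugar_sweetener_triggers(self):
        assert detect_added_sugar(self.entries("sucralose")).found is True

    def test_token_boundaries_respected(self):
        # "sugarsnap" must not match the term "sugar"
        assert detect_added_sugar(self.entries("sugarsnap peas")).found is False

    def test_empty_list_is_absent_evidence(self):
        assert detect_added_sugar([]).found is None


class TestRequirementEvaluation:
    def test_all_inside_thresholds_passes(self):
        p = profile_from(energy=400.0, sugar=2.0, sodium=20.0, fat=8.0)
        a = evaluate_nutrient_requirements(SUB.other_snacks_finger_foods, p, no_sugar())
        assert a.overall_pass and a.n_met == a.n_applicable == 4

    def test_sodium_conjunction_fails_on_per_100g_limb(self):
        # 60 mg/100 g at 500 kcal/100 g = 12 mg/100 kcal: per-kcal limb passes,
        # per-100g limb fails, requirement fails
        p = profile_from(energy=500.0, sugar=2.0, sodium=60.0, fat=8.0)
        a = evaluate_nutrient_requirements(SUB.other_snacks_finger_foods, p, no_sugar())
        assert a.results[R.sodium_limit].status is Status.not_met
        assert a.results[R.sodium_limit].reason is Reason.threshold_fail

    def test_fruit_subcategory_sugar_exemption(self):
        p = profile_from(energy=350.0, sugar=40.0, sodium=5.0, fat=1.0)
        a = evaluate_nutrient_requirements(SUB.fruit_fresh_or_dry, p, no_sugar())
        assert a.results[R.sugar_energy_lt_15pct].status is Status.not_applicable
        assert a.n_applicable == 3
        assert a.overall_pass

    def test_missing_sodium_declaration_fails_with_reason(self):
        p = profile_from(energy=400.0, sugar=2.0, fat=2.0)
        a = evaluate_nutrient_requirements(SUB.other_snacks_finger_foods, p, no_sugar())
        res = a.results[R.sodium_limit]
        assert res.status is Status.not_met and res.reason is Reason.missing_declaration
        assert not a.overall_pass

    def test_missing_ingredient_list_fails_added_sugar_rule(self):
        p = profile_from(energy=400.0, sugar=2.0, sodium=10.0, fat=2.0)
        a = evaluate_nutrient_requirements(
            SUB.other_snacks_finger_foods, p, AddedSugarResult(found=None)
        )
        res = a.results[R.no_added_sugar]
        assert res.status is Status.not_met and res.reason is Reason.missing_declaration

    def test_confectionery_auto_fails_regardless_of_composition(self):
        p = profile_from(energy=400.0, sugar=0.5, sodium=1.0, fat=0.5)
        a = evaluate_nutrient_requirements(
            SUB.confectionery_sweet_spreads_fruit_chews, p, no_sugar()
        )
        assert a.auto_failed and not a.overall_pass
        assert all(r.reason is Reason.auto_fail_confectionery for r in a.results.values())

    def test_undefined_subcategory_is_an_error(self):
        with pytest.raises(ValueError):
            evaluate_nutrient_requirements(None, profile_from(energy=400.0), no_sugar())


class TestBoundaries:
    """Inequality strictness exactly as printed: < for sugar-energy and both
    sodium limbs, ≤ for fat."""

    def test_sodium_exactly_50_per_100g_fails(self):
        p = profile_from(energy=500.0, sugar=1.0, sodium=50.0, fat=1.0)
        a = evaluate_nutrient_requirements(SUB.other_snacks_finger_foods, p, no_sugar())
        assert a.results[R.sodium_limit].status is Status.not_met

    def test_sodium_exactly_50_per_100kcal_fails(self):
        # 40 mg/100 g at 80 kcal/100 g = 50 mg/100 kcal
        p = profile_from(energy=80.0, sugar=0.5, sodium=40.0, fat=0.5)
        a = evaluate_nutrient_requirements(SUB.other_snacks_finger_foods, p, no_sugar())
        assert a.results[R.sodium_limit].status is Status.not_met

    def test_fat_exactly_4_5_per_100kcal_passes(self):
        p = profile_from(energy=400.0, sugar=1.0, sodium=5.0, fat=18.0)
        assert p.fat_g_per_100kcal == pytest.approx(4.5)
        a = evaluate_nutrient_requirements(SUB.other_snacks_finger_foods, p, no_sugar())
        assert a.results[R.fat_limit].status is Status.met

    def test_sugar_exactly_15_percent_energy_fails(self):
        p = profile_from(energy=400.0, sugar=15.0, sodium=5.0, fat=1.0)
        assert p.pct_energy_sugar == pytest.approx(15.0)
        a = evaluate_nutrient_requirements(SUB.other_snacks_finger_foods, p, no_sugar())
        assert a.results[R.sugar_energy_lt_15pct].status is Status.not_met

    def test_threshold_constant_is_3_75(self):
        assert sugar_energy_limit_g_per_100kcal() == 3.75


@given(
    energy=st.floats(50.0, 800.0),
    sugar=st.one_of(st.none(), st.floats(0.0, 80.0)),
    sodium=st.one_of(st.none(), st.floats(0.0, 800.0)),
    fat=st.one_of(st.none(), st.floats(0.0, 40.0)),
    bump=st.sampled_from(["sugar", "sodium", "fat"]),
    factor=st.floats(1.0, 10.0),
)
@settings(max_examples=150, deadline=None)
def test_increasing_a_nutrient_never_flips_fail_to_pass(energy, sugar, sodium, fat, bump, factor):
    rank = {Status.met: 0, Status.not_applicable: 0, Status.not_met: 1}
    before = evaluate_nutrient_requirements(
        SUB.other_snacks_finger_foods,
        profile_from(energy=energy, sugar=sugar, sodium=sodium, fat=fat),
        no_sugar(),
    )
    values = {"sugar": sugar, "sodium": sodium, "fat": fat}
    if values[bump] is None:
        return
    values[bump] *= factor
    after = evaluate_nutrient_requirements(
        SUB.other_snacks_finger_foods,
        profile_from(energy=energy, **values),
        no_sugar(),
    )
    for req in R:
        assert rank[after.results[req].status] >= rank[before.results[req].status]
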