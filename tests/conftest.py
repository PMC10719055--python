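import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from cpcf_npm.records import (
    ClaimCategory,
    FingerFoodSubcategory,
    IngredientEntry,
    NPMCategory,
    NutrientDeclaration,
    NutrientValues,
    ProductRecord,
)


def make_record(**overrides) -> ProductRecord:
    """A plain, valid finger-food record; override any field."""
    base = dict(
        product_id="P1",
        country="TH",
        brand="TinyBites",
        descriptive_name="Baby Apple Puffs",
        flavour="Apple",
        manufacturer="Alpha Foods",
        manufacturer_origin="national",
        age_statement_months=8,
        ingredient_list=[
            IngredientEntry(name="rice flour", is_fruit=False),
            IngredientEntry(name="apple", percentage=30.0, is_fruit=True),
        ],
        declarations=NutrientDeclaration(
            per_100g=NutrientValues(
                energy_kcal=450.0, total_sugar_g=10.0, sodium_mg=20.0,
                total_fat_g=2.0, saturated_fat_g=0.5,
            )
        ),
        category_hint=NPMCategory.dry_finger_food_snack,
        subcategory_hint=FingerFoodSubcategory.other_snacks_finger_foods,
    )
    base.update(overrides)
    return ProductRecord(**base)


@pytest.fixture
def ideal_record() -> ProductRecord:
    """A constructed product that meets all twelve labelling requirements:
    age 6+ displayed, breastfeeding message present, no adverse flags, no
    claims, name in ingredient order, fruit percentages stated."""
    return make_record(
        age_statement_months=6,
        marketed_under_6mo=False,
        has_bf_continuation_message=True,
        suggests_bm_superiority=False,
        promotes_bottle_feeding=False,
        claims=[],
        descriptive_name="Apple Banana Puffs",
        ingredient_list=[
            IngredientEntry(name="rice flour", is_fruit=False),
            IngredientEntry(name="apple", percentage=30.0, is_fruit=True),
            IngredientEntry(name="banana", percentage=10.0, is_fruit=True),
        ],
    )


def pytest_make_parametrize_id(config, val):
    if isinstance(val, (ClaimCategory, FingerFoodSubcategory, NPMCategory)):
        return val.value
    return None
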