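"""Straight-line re-statement of the assessment rules, used as ground truth.

This module is a deliberately plain, rule-by-rule transcription of the
adapted NPM for CPCF: no shared helpers with the engine modules, no lexicon
files, no dispatch — just the rules written out.  The synthetic-market
generator uses it to compute the ground-truth verdicts shipped with every
generated dataset, and the test suite uses it as the independent oracle the
rule engine must agree with.  Keep it boring; its value is that it is easy
to check against the written rules by eye.
"""

from __future__ import annotations

import re

from .records import FingerFoodSubcategory, ProductRecord

MET = "met"
NOT_MET = "not_met"
NA = "not_applicable"

# Added sugar/sweetener terms: mono-/disaccharides, syrups, nectars, honey,
# fruit juices (except lemon/lime) and nonsugar sweeteners.
_SUGAR_TERMS = (
    "sugar", "juice", "sucrose", "dextrose", "fructose", "glucose", "maltose",
    "galactose", "trehalose", "syrup", "nectar", "honey", "malted barley",
    "malt extract", "molasses",
    "sweetener", "aspartame", "sucralose", "saccharin", "stevia",
    "steviol glycosides", "acesulfame", "cyclamate", "neotame", "advantame",
    "thaumatin", "sorbitol", "xylitol", "maltitol", "mannitol", "isomalt",
    "lactitol", "erythritol",
)


def _per_100g(record: ProductRecord, field: str):
    decl = record.declarations
    v = getattr(decl.per_100g, field, None) if decl.per_100g else None
    if v is not None:
        return v
    s = getattr(decl.per_serving, field, None) if decl.per_serving else None
    if s is not None and decl.serving_size_g is not None:
        return s * 100.0 / decl.serving_size_g
    return None


def _energy_kcal(record: ProductRecord):
    kcal = _per_100g(record, "energy_kcal")
    if kcal is not None:
        return kcal
    kj = _per_100g(record, "energy_kj")
    if kj is not None:
        return kj / 4.184
    return None


def _sodium_mg(record: ProductRecord):
    na = _per_100g(record, "sodium_mg")
    if na is not None:
        return na
    salt = _per_100g(record, "salt_g")
    if salt is not None:
        return salt / 2.5 * 1000.0
    return None


def _ingredient_has_added_sugar(name: str) -> bool:
    text = name.lower()
    # lemon/lime juice never counts as an added sugar
    text = text.replace("lemon juice", " ").replace("lime juice", " ")
    return any(re.search(rf"\b{re.escape(t)}\b", text) for t in _SUGAR_TERMS)


def nutrient_verdicts(
    record: ProductRecord, subcategory: FingerFoodSubcategory
) -> dict[str, str]:
    """The four composition requirements, rule by rule."""
    if subcategory == FingerFoodSubcategory.confectionery_sweet_spreads_fruit_chews:
        # confectionery automatically fails the whole model
        return {
            "no_added_sugar": NOT_MET,
            "sugar_energy_lt_15pct": NOT_MET,
            "sodium_limit": NOT_MET,
            "fat_limit": NOT_MET,
        }

    out: dict[str, str] = {}

    # (1) no added sugar/sweetener; no ingredient list = missing info = fail
    if not record.ingredient_list:
        out["no_added_sugar"] = NOT_MET
    elif any(_ingredient_has_added_sugar(e.name) for e in record.ingredient_list):
        out["no_added_sugar"] = NOT_MET
    else:
        out["no_added_sugar"] = MET

    energy = _energy_kcal(record)

    # (2) <15% of total energy from total sugar; fruit (fresh or dry) exempt
    if subcategory == FingerFoodSubcategory.fruit_fresh_or_dry:
        out["sugar_energy_lt_15pct"] = NA
    else:
        sugar = _per_100g(record, "total_sugar_g")
        if sugar is None or energy is None or energy <= 0:
            out["sugar_energy_lt_15pct"] = NOT_MET
        else:
            out["sugar_energy_lt_15pct"] = MET if sugar * 4.0 / energy * 100.0 < 15.0 else NOT_MET

    # (3) sodium <50 mg/100 kcal AND <50 mg/100 g
    sodium = _sodium_mg(record)
    if sodium is None or energy is None or energy <= 0:
        out["sodium_limit"] = NOT_MET
    else:
        out["sodium_limit"] = MET if (sodium < 50.0 and sodium / energy * 100.0 < 50.0) else NOT_MET

    # (4) total fat ≤4.5 g/100 kcal
    fat = _per_100g(record, "total_fat_g")
    if fat is None or energy is None or energy <= 0:
        out["fat_limit"] = NOT_MET
    else:
        out["fat_limit"] = MET if fat / energy * 100.0 <= 4.5 else NOT_MET

    return out


def labelling_verdicts(record: ProductRecord) -> dict[str, str]:
    """The twelve labelling requirements, rule by rule.

    Claims are read from the pre-coded claim categories (the generator always
    codes them, mirroring the study's coding protocol).
    """
    out: dict[str, str] = {}
    age = record.age_statement_months

    # L1: displays minimum recommendation of at least 6 months (no age = fail)
    out["L1"] = MET if (age is not None and age >= 6) else NOT_MET
    # L2: not marketed as suitable for <6 months
    bad = record.marketed_under_6mo is True or (age is not None and age < 6)
    out["L2"] = NOT_MET if bad else MET
    # L3: message on continued breastfeeding to 2 years and beyond (must be present)
    out["L3"] = MET if record.has_bf_continuation_message is True else NOT_MET
    # L4: no suggestion of superiority/equivalence to breast milk
    out["L4"] = NOT_MET if record.suggests_bm_superiority is True else MET
    # L5: no bottle-feeding recommendation/promotion
    out["L5"] = NOT_MET if record.promotes_bottle_feeding is True else MET

    # L6-L10: no claim of each of the five categories
    cats = {c.category.value for c in record.claims if c.category is not None}
    out["L6"] = NOT_MET if "nonpermitted_compositional" in cats else MET
    out["L7"] = NOT_MET if "nutrient_content" in cats else MET
    out["L8"] = NOT_MET if "nutrient_function" in cats else MET
    out["L9"] = NOT_MET if "disease_risk_reduction" in cats else MET
    out["L10"] = NOT_MET if "other" in cats else MET

    # L11/L12: name/ingredient-list clarity; no ingredient list = fail both
    if not record.ingredient_list:
        out["L11"] = NOT_MET
        out["L12"] = NOT_MET
        return out

    name = (record.descriptive_name or "").lower()
    mentioned = [
        (name.find(e.name.lower()), i)
        for i, e in enumerate(record.ingredient_list)
        if e.name.lower() in name
    ]
    mentioned.sort()
    order = [i for _, i in mentioned]
    out["L11"] = MET if order == sorted(order) else NOT_MET

    fruit = [e for e in record.ingredient_list if e.is_fruit is True]
    if not fruit:
        out["L12"] = NA
    else:
        out["L12"] = MET if all(e.percentage is not None for e in fruit) else NOT_MET
    return out


def group_passes(verdicts: dict[str, str]) -> dict[str, bool]:
    groups = {
        "breastfeeding": ("L1", "L2", "L3", "L4", "L5"),
        "claims": ("L6", "L7", "L8", "L9", "L10"),
        "clarity": ("L11", "L12"),
    }
    return {g: all(verdicts[k] != NOT_MET for k in ks) for g, ks in groups.items()}
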