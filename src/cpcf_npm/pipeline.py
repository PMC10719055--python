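"""End-to-end assessment pipeline: dedup → categorize → profile → label-assess.

Mirrors the study's flow: within-country duplicates are removed, products are
screened for CPCF status, allocated to NPM categories, and the dry finger
foods/snacks are assessed.  Confectionery/sweet spreads/fruit chews fail the
model automatically and — as in the published tables — are excluded from the
labelling assessment, which covers only the remaining assessed products.
Stage counts are tracked for the flowchart-style run log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .categorize import CategoryRules, NeedsManualCoding, assign_npm_category, assign_subcategory, is_cpcf
from .labelling import LABELLING_IDS, ClaimLexicon, LabellingAssessment, assess_labelling
from .profiling import (
    AddedSugarLexicon,
    NutrientAssessment,
    NutrientRequirement,
    detect_added_sugar,
    evaluate_nutrient_requirements,
    normalize_nutrients,
)
from .records import FingerFoodSubcategory, NPMCategory, ProductRecord, dedup_products


@dataclass
class PipelineResult:
    """Everything one assessment run produces."""

    assessments: pd.DataFrame
    nutrient: list[NutrientAssessment] = field(default_factory=list)
    labelling: list[LabellingAssessment] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (product_id, why)


ASSESSMENT_COLUMNS = [
    "product_id", "country", "manufacturer_origin", "subcategory", "auto_failed",
    *[r.value for r in NutrientRequirement],
    "n_applicable", "n_met", "nutrient_pass",
    "energy_kcal_per_100g", "sugar_g_per_100g", "sodium_mg_per_100g",
    "fat_g_per_100g", "satfat_g_per_100g",
    *LABELLING_IDS,
    "group_breastfeeding", "group_claims", "group_clarity", "labelling_pass",
]


def assess_products(
    records: Sequence[ProductRecord],
    *,
    sugar_lexicon: Optional[AddedSugarLexicon] = None,
    claim_lexicon: Optional[ClaimLexicon] = None,
    rules: Optional[CategoryRules] = None,
    dedup: bool = True,
) -> PipelineResult:
    """Run the full assessment over a product table.

    Returns one assessment row per dry finger food/snack; labelling columns
    are left empty for confectionery (auto-failed, never label-assessed).
    Products outside the finger-food category are counted but not profiled;
    products that cannot be categorized are skipped with a reason rather than
    guessed.
    """
    counts: dict[str, int] = {"input": len(records)}
    if dedup:
        kept: list[ProductRecord] = []
        by_country: dict[str, list[ProductRecord]] = {}
        for r in records:
            by_country.setdefault(r.country, []).append(r)
        for country in sorted(by_country):
            unique, _ = dedup_products(by_country[country])
            kept.extend(unique)
    else:
        kept = list(records)
    counts["after_dedup"] = len(kept)

    skipped: list[tuple[str, str]] = []
    cpcf = []
    for r in kept:
        ok, _criteria = is_cpcf(r)
        if ok:
            cpcf.append(r)
        else:
            skipped.append((r.product_id, "not identified as CPCF"))
    counts["cpcf_identified"] = len(cpcf)

    finger_foods: list[tuple[ProductRecord, FingerFoodSubcategory]] = []
    for r in cpcf:
        try:
            category = assign_npm_category(r, rules)
        except NeedsManualCoding as exc:
            skipped.append((r.product_id, str(exc)))
            continue
        if category is not NPMCategory.dry_finger_food_snack:
            skipped.append((r.product_id, f"category {category.value}: not profiled"))
            continue
        finger_foods.append((r, assign_subcategory(r, rules)))
    counts["finger_foods_identified"] = len(finger_foods)

    nutrient_assessments: list[NutrientAssessment] = []
    labelling_assessments: list[LabellingAssessment] = []
    rows: list[dict] = []
    n_conf = 0
    for record, subcategory in finger_foods:
        profile = normalize_nutrients(record.declarations)
        added = detect_added_sugar(record.ingredient_list, sugar_lexicon)
        nut = evaluate_nutrient_requirements(
            subcategory, profile, added, product_id=record.product_id
        )
        nutrient_assessments.append(nut)
        row: dict = {
            "product_id": record.product_id,
            "country": record.country,
            "manufacturer_origin": record.manufacturer_origin.value,
            "subcategory": subcategory.value,
            "auto_failed": nut.auto_failed,
            **{req.value: res.status.value for req, res in nut.results.items()},
            "n_applicable": nut.n_applicable,
            "n_met": nut.n_met,
            "nutrient_pass": nut.overall_pass,
            "energy_kcal_per_100g": profile.energy_kcal_per_100g,
            "sugar_g_per_100g": profile.sugar_g_per_100g,
            "sodium_mg_per_100g": profile.sodium_mg_per_100g,
            "fat_g_per_100g": profile.fat_g_per_100g,
            "satfat_g_per_100g": profile.satfat_g_per_100g,
        }
        if nut.auto_failed:
            n_conf += 1
            row.update({lid: None for lid in LABELLING_IDS})
            row.update(
                group_breastfeeding=None, group_claims=None, group_clarity=None,
                labelling_pass=None,
            )
        else:
            lab = assess_labelling(record, claim_lexicon)
            labelling_assessments.append(lab)
            row.update({lid: lab.results[lid].status.value for lid in LABELLING_IDS})
            row.update(
                group_breastfeeding=lab.group_pass["breastfeeding"],
                group_claims=lab.group_pass["claims"],
                group_clarity=lab.group_pass["clarity"],
                labelling_pass=lab.overall_pass,
            )
        rows.append(row)

    counts["confectionery_auto_fail"] = n_conf
    counts["assessed"] = len(finger_foods) - n_conf
    return PipelineResult(
        assessments=pd.DataFrame(rows, columns=ASSESSMENT_COLUMNS),
        nutrient=nutrient_assessments,
        labelling=labelling_assessments,
        stage_counts=counts,
        skipped=skipped,
    )
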