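"""Synthetic market generator with known ground truth.

The study's per-product dataset is not public, so every pipeline stage is
exercised on synthetic markets that reproduce the *statistical shape* the
analysis assumes: right-skewed (log-normal) nutrient contents whose medians
sit near the published overall medians, the published subcategory mix,
added-sugar prevalence, per-field missingness, claim carriage rates and
labelling-flag rates.  Each generated dataset ships with ground-truth
verdicts computed by the straight-line rule module (:mod:`cpcf_npm.reference`)
— never by the engine under test — and with analytically expected pass rates
(:func:`expected_rates`) for convergence checks.

The default :class:`MarketConfig` IS the study-scale preset; its parameter
values are calibration conveniences matching the published marginals, not
claims about any real market.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from . import reference
from .records import (
    ClaimCategory,
    ClaimRecord,
    FingerFoodSubcategory,
    IngredientEntry,
    ManufacturerOrigin,
    NPMCategory,
    NutrientDeclaration,
    NutrientValues,
    ProductRecord,
)

logger = logging.getLogger(__name__)

_SUB = FingerFoodSubcategory


class DistConfig(BaseModel):
    """A nutrient-content distribution, parameterized by its median.

    ``lognormal``: median * exp(sigma * Z).  ``fixed``: a point mass (handy
    for boundary checks).  ``gamma``: shape/median parameterization; has no
    closed-form pass rate here, so :func:`expected_rates` falls back to
    Monte Carlo for it.
    """

    family: Literal["lognormal", "fixed", "gamma"] = "lognormal"
    median: float = Field(gt=0)
    sigma: float = Field(default=0.0, ge=0)
    shape: Optional[float] = Field(default=None, gt=0)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(n, self.median)
        if self.family == "lognormal":
            return self.median * np.exp(self.sigma * rng.standard_normal(n))
        scale = self.median / stats.gamma.ppf(0.5, self.shape)
        return rng.gamma(self.shape, scale, size=n)


_FRUITS = ("Apple", "Banana", "Mango", "Strawberry", "Pear", "Pineapple", "Blueberry", "Peach")
_FORMS = ("Puffs", "Rusks", "Biscuits", "Rice Cakes", "Crisps", "Wafers", "Melts", "Sticks")
_CONF_FORMS = ("Fruit Chews", "Gummies", "Marshmallows", "Sweet Spread")
_GRAINS = ("rice flour", "wheat flour", "corn flour", "oat flour")
_SUGAR_INGREDIENTS = ("glucose syrup", "honey", "malt extract", "cane sugar", "fructose", "sucralose")
_BRANDS = ("TinyBites", "LittleMunch", "HappyTots", "BubGrub", "MiniMeals",
           "SnackSprout", "WeeTreats", "Nibblers", "FirstTaste", "GrowWell")
_MANUFACTURERS = ("Alpha Foods", "Beta Nutrition", "Gamma Snacks", "Delta Dairy", "Epsilon Organics")

_CLAIM_TEXTS: dict[ClaimCategory, tuple[str, ...]] = {
    ClaimCategory.nonpermitted_compositional: (
        "No added sugar or salt", "No preservatives", "No artificial colours"),
    ClaimCategory.nutrient_content: (
        "Source of iron and B1", "Essential vitamins and minerals for babies", "High in calcium"),
    ClaimCategory.nutrient_function: (
        "Supports brain development", "Helps build strong bones"),
    ClaimCategory.disease_risk_reduction: (
        "Reduces the risk of anaemia",),
    ClaimCategory.other: (
        "Easy to grasp and hold", "Dissolves easily", "Perfect for little hands"),
}


class MarketConfig(BaseModel):
    """Parameters of a synthetic CPCF finger-food/snack market.

    Defaults are the study-scale preset: 606 products split across the seven
    country codes with the published subcategory mix; log-normal nutrient
    contents with medians near the published overall medians (total sugar
    12.4 g, sodium 71 mg, total fat 2.7 g per 100 g); per-field missingness
    matching the published per-nutrient declaration counts; claim and
    labelling-flag rates from the published overall labelling table.
    """

    n_products: int = Field(default=606, ge=0)
    seed: int = 0
    country_weights: dict[str, float] = Field(
        default_factory=lambda: {
            "KH": 84, "ID": 122, "LA": 51, "MY": 176, "PH": 43, "TH": 87, "VN": 43,
        }
    )
    subcategory_probs: dict[FingerFoodSubcategory, float] = Field(
        default_factory=lambda: {
            _SUB.confectionery_sweet_spreads_fruit_chews: 50 / 606,
            _SUB.fruit_fresh_or_dry: 8 / 606,
            _SUB.other_snacks_finger_foods: 548 / 606,
        }
    )
    p_added_sugar: float = Field(default=0.723, ge=0, le=1)
    nutrient_distributions: dict[str, DistConfig] = Field(
        default_factory=lambda: {
            "energy": DistConfig(median=430.0, sigma=0.4),
            "sugar": DistConfig(median=12.4, sigma=1.1),
            "sodium": DistConfig(median=71.0, sigma=2.0),
            "fat": DistConfig(median=2.7, sigma=1.3),
            "satfat": DistConfig(median=0.3, sigma=1.2),
        }
    )
    missingness_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "energy": 0.02,
            "sugar": 0.104,
            "sodium": 0.029,
            "fat": 0.0,
            "satfat": 0.32,
            "ingredient_list": 0.02,
            "age_statement": 0.15,
        }
    )
    claim_rates: dict[ClaimCategory, float] = Field(
        default_factory=lambda: {
            ClaimCategory.nonpermitted_compositional: 0.887,
            ClaimCategory.nutrient_content: 0.513,
            ClaimCategory.nutrient_function: 0.194,
            ClaimCategory.disease_risk_reduction: 0.013,
            ClaimCategory.other: 0.897,
        }
    )
    labelling_flag_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "marketed_under_6mo_true": 0.10,
            "marketed_under_6mo_absent": 0.10,
            "bf_message_true": 0.306,
            "bf_message_absent": 0.10,
            "bm_superiority_true": 0.009,
            "bottle_promotion_true": 0.009,
            "child_image_true": 0.90,
        }
    )
    p_international: float = Field(default=0.703, ge=0, le=1)
    p_contains_fruit: float = Field(default=0.568, ge=0, le=1)
    p_fruit_pct_stated: float = Field(default=0.633, ge=0, le=1)
    p_name_order_ok: float = Field(default=0.642, ge=0, le=1)
    p_salt_declared: float = Field(default=0.3, ge=0, le=1)
    p_per_serving_only: float = Field(default=0.1, ge=0, le=1)
    p_kj_only: float = Field(default=0.1, ge=0, le=1)

    @model_validator(mode="after")
    def _validate(self) -> "MarketConfig":
        for name, probs in (
            ("claim_rates", self.claim_rates.values()),
            ("labelling_flag_rates", self.labelling_flag_rates.values()),
            ("missingness_rates", self.missingness_rates.values()),
        ):
            if any(not (0 <= p <= 1) for p in probs):
                raise ValueError(f"{name}: probabilities must lie in [0, 1]")
        if any(w < 0 for w in self.country_weights.values()) or not self.country_weights:
            raise ValueError("country_weights: weights must be non-negative and non-empty")
        total = sum(self.subcategory_probs.values())
        if self.subcategory_probs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"subcategory_probs: must sum to 1, got {total}")
        missing = {"energy", "sugar", "sodium", "fat", "satfat"} - set(self.nutrient_distributions)
        if missing:
            raise ValueError(f"nutrient_distributions: missing entries for {sorted(missing)}")
        return self


@dataclass
class GroundTruth:
    """Per-product rule verdicts plus expected aggregate pass rates.

    ``nutrient`` and ``labelling`` hold one row per product (labelling only
    for non-confectionery products, which are the ones the model assesses);
    verdict columns contain ``met`` / ``not_met`` / ``not_applicable``.
    """

    nutrient: pd.DataFrame
    labelling: pd.DataFrame
    expected: dict[str, float] = field(default_factory=dict)


def _bern(rng: np.random.Generator, p: float) -> bool:
    return bool(rng.random() < p)


def _tri_state(rng: np.random.Generator, p_true: float, p_absent: float) -> Optional[bool]:
    u = rng.random()
    if u < p_true:
        return True
    if u < p_true + p_absent:
        return None
    return False


def generate_market(config: MarketConfig) -> tuple[list[ProductRecord], GroundTruth]:
    """Generate a synthetic market and its ground truth.

    Fully reproducible for a given ``config.seed``.  Ingredient lists are
    constructed to realize the drawn added-sugar status; missingness is
    applied after value generation; ground truth is computed by the
    straight-line rule module on the finished records.
    """
    rng = np.random.default_rng(config.seed)
    countries = sorted(config.country_weights)
    cw = np.array([config.country_weights[c] for c in countries], dtype=float)
    cw = cw / cw.sum()
    subs = list(config.subcategory_probs)
    sp = np.array([config.subcategory_probs[s] for s in subs], dtype=float)
    m = config.missingness_rates
    fl = config.labelling_flag_rates
    dists = config.nutrient_distributions

    records: list[ProductRecord] = []
    nutrient_rows: list[dict] = []
    labelling_rows: list[dict] = []

    for i in range(config.n_products):
        country = countries[rng.choice(len(countries), p=cw)]
        sub: FingerFoodSubcategory = subs[rng.choice(len(subs), p=sp)] if subs else _SUB.other_snacks_finger_foods
        origin = (
            ManufacturerOrigin.international
            if _bern(rng, config.p_international)
            else ManufacturerOrigin.national
        )

        # --- ingredient list and name, realizing the drawn properties -----
        ingredients: list[IngredientEntry] = []
        fruits = [str(f) for f in rng.choice(_FRUITS, size=2, replace=False)]
        if sub is _SUB.fruit_fresh_or_dry:
            name = f"Baby Freeze-Dried {fruits[0]}"
            pct = 100.0 if _bern(rng, config.p_fruit_pct_stated) else None
            ingredients = [IngredientEntry(name=fruits[0].lower(), percentage=pct, is_fruit=True)]
            flavour = fruits[0]
        elif sub is _SUB.confectionery_sweet_spreads_fruit_chews:
            form = str(rng.choice(_CONF_FORMS))
            name = f"Baby {fruits[0]} {form}"
            flavour = fruits[0]
            ingredients = [
                IngredientEntry(name="glucose syrup"),
                IngredientEntry(name=f"{fruits[0].lower()} puree", percentage=float(rng.integers(20, 60)), is_fruit=True),
            ]
        else:
            form = str(rng.choice(_FORMS))
            grain = str(rng.choice(_GRAINS))
            contains_fruit = _bern(rng, config.p_contains_fruit)
            order_ok = _bern(rng, config.p_name_order_ok)
            if contains_fruit:
                n_fruit = 2 if (not order_ok or _bern(rng, 0.5)) else 1
                used = fruits[:n_fruit]
                pcts = sorted(rng.uniform(5, 40, size=n_fruit), reverse=True)
                # one per-product draw: labels state all fruit percentages or none
                pct_stated = _bern(rng, config.p_fruit_pct_stated)
                fruit_entries = [
                    IngredientEntry(
                        name=f.lower(),
                        percentage=round(p, 1) if pct_stated else None,
                        is_fruit=True,
                    )
                    for f, p in zip(used, pcts)
                ]
                name_fruits = used if order_ok else used[::-1]
                name = f"Baby {' '.join(name_fruits)} {form}"
                flavour = " ".join(used)
            else:
                fruit_entries = []
                name = f"Baby {form}"
                flavour = None
            ingredients = [IngredientEntry(name=grain, is_fruit=False), *fruit_entries]
            if _bern(rng, config.p_added_sugar):
                ingredients.append(IngredientEntry(name=str(rng.choice(_SUGAR_INGREDIENTS))))
            elif _bern(rng, 0.1):
                ingredients.append(IngredientEntry(name="lemon juice"))
            ingredients.append(IngredientEntry(name="vegetable oil", is_fruit=False))

        if _bern(rng, m.get("ingredient_list", 0.0)):
            ingredients = []

        # --- nutrient declaration ----------------------------------------
        energy = float(dists["energy"].sample(rng, 1)[0])
        sugar = float(dists["sugar"].sample(rng, 1)[0])
        sodium = float(dists["sodium"].sample(rng, 1)[0])
        fat = float(dists["fat"].sample(rng, 1)[0])
        satfat = min(float(dists["satfat"].sample(rng, 1)[0]), fat)

        vals: dict[str, Optional[float]] = {
            "energy_kcal": energy,
            "energy_kj": None,
            "total_sugar_g": sugar,
            "sodium_mg": sodium,
            "salt_g": None,
            "total_fat_g": fat,
            "saturated_fat_g": satfat,
        }
        if _bern(rng, config.p_kj_only):
            vals["energy_kj"] = energy * 4.184
            vals["energy_kcal"] = None
        if _bern(rng, config.p_salt_declared):
            vals["salt_g"] = sodium * 2.5 / 1000.0
            vals["sodium_mg"] = None
        for nutrient, keys in (
            ("energy", ("energy_kcal", "energy_kj")),
            ("sugar", ("total_sugar_g",)),
            ("sodium", ("sodium_mg", "salt_g")),
            ("fat", ("total_fat_g",)),
            ("satfat", ("saturated_fat_g",)),
        ):
            if _bern(rng, m.get(nutrient, 0.0)):
                for k in keys:
                    vals[k] = None

        if _bern(rng, config.p_per_serving_only):
            serving = float(rng.choice([10.0, 15.0, 20.0, 25.0, 30.0]))
            serv_vals = {
                k: (None if v is None else v * serving / 100.0) for k, v in vals.items()
            }
            decl = NutrientDeclaration(
                serving_size_g=serving, per_serving=NutrientValues(**serv_vals)
            )
        else:
            decl = NutrientDeclaration(per_100g=NutrientValues(**vals))

        # --- labelling flags and claims ----------------------------------
        age = None
        if not _bern(rng, m.get("age_statement", 0.0)):
            age = int(rng.choice([6, 7, 8, 9, 10, 12], p=[0.35, 0.1, 0.2, 0.1, 0.05, 0.2]))
        claims = [
            ClaimRecord(category=cat, text=str(rng.choice(_CLAIM_TEXTS[cat])))
            for cat, rate in config.claim_rates.items()
            if _bern(rng, rate)
        ]
        if _bern(rng, 0.05):
            claims.append(ClaimRecord(text="Proudly made in small batches"))

        rec = ProductRecord(
            product_id=f"{country}-{i:05d}",
            country=country,
            brand=str(rng.choice(_BRANDS)),
            subbrand=f"S{i:05d}",  # unique token: synthetic markets contain no duplicates
            descriptive_name=name,
            flavour=flavour,
            manufacturer=str(rng.choice(_MANUFACTURERS)),
            manufacturer_origin=origin,
            age_statement_months=age,
            marketed_under_6mo=_tri_state(
                rng, fl["marketed_under_6mo_true"], fl["marketed_under_6mo_absent"]
            ),
            has_bf_continuation_message=_tri_state(
                rng, fl["bf_message_true"], fl["bf_message_absent"]
            ),
            suggests_bm_superiority=_tri_state(rng, fl["bm_superiority_true"], 0.1),
            promotes_bottle_feeding=_tri_state(rng, fl["bottle_promotion_true"], 0.1),
            has_child_image=_bern(rng, fl["child_image_true"]),
            ingredient_list=ingredients,
            claims=claims,
            declarations=decl,
            category_hint=NPMCategory.dry_finger_food_snack,
            subcategory_hint=sub,
        )
        records.append(rec)

        verdicts = reference.nutrient_verdicts(rec, sub)
        applicable = [v for v in verdicts.values() if v != reference.NA]
        auto = sub is _SUB.confectionery_sweet_spreads_fruit_chews
        nutrient_rows.append(
            {
                "product_id": rec.product_id,
                "country": country,
                "subcategory": sub.value,
                "auto_failed": auto,
                **verdicts,
                "n_applicable": len(applicable),
                "n_met": sum(v == reference.MET for v in applicable),
                "overall_pass": (not auto) and all(v == reference.MET for v in applicable),
            }
        )
        if not auto:
            lab = reference.labelling_verdicts(rec)
            gp = reference.group_passes(lab)
            labelling_rows.append(
                {
                    "product_id": rec.product_id,
                    "country": country,
                    **lab,
                    **{f"group_{g}": v for g, v in gp.items()},
                    "overall_pass": all(gp.values()),
                }
            )

    truth = GroundTruth(
        nutrient=pd.DataFrame(
            nutrient_rows,
            columns=["product_id", "country", "subcategory", "auto_failed",
                     "no_added_sugar", "sugar_energy_lt_15pct", "sodium_limit", "fat_limit",
                     "n_applicable", "n_met", "overall_pass"],
        ),
        labelling=pd.DataFrame(
            labelling_rows,
            columns=["product_id", "country", *[f"L{i}" for i in range(1, 13)],
                     "group_breastfeeding", "group_claims", "group_clarity", "overall_pass"],
        ),
        expected=expected_rates(config),
    )
    return records, truth


# --------------------------------------------------------------------------
# Analytic expected pass rates
# --------------------------------------------------------------------------


def _log_params(d: DistConfig) -> tuple[float, float]:
    return math.log(d.median), d.sigma


def _p_lt(d: DistConfig, limit: float) -> float:
    """P(X < limit) for one nutrient draw."""
    if d.family == "fixed" or (d.family == "lognormal" and d.sigma == 0):
        return float(d.median < limit)
    mu, sg = _log_params(d)
    return float(stats.norm.cdf((math.log(limit) - mu) / sg))


def _p_ratio_lt(num: DistConfig, den: DistConfig, limit: float) -> float:
    """P(X/Y * 100 < limit) for independent log-normal/fixed draws."""
    mu = math.log(num.median) - math.log(den.median)
    sg = math.hypot(num.sigma if num.family == "lognormal" else 0.0,
                    den.sigma if den.family == "lognormal" else 0.0)
    b = math.log(limit / 100.0)
    if sg == 0:
        return float(mu < b)
    return float(stats.norm.cdf((b - mu) / sg))


def _p_sodium_joint(na: DistConfig, en: DistConfig) -> float:
    """P(sodium < 50 mg/100 g AND sodium/energy*100 < 50 mg/100 kcal)."""
    a, b = math.log(50.0), math.log(0.5)
    mu_x, sg_x = _log_params(na)
    mu_y, sg_y = _log_params(en)
    sg_x = sg_x if na.family == "lognormal" else 0.0
    sg_y = sg_y if en.family == "lognormal" else 0.0
    if sg_x == 0 and sg_y == 0:
        return float(mu_x < a and mu_x - mu_y < b)
    if sg_x == 0:
        return float(mu_x < a) * float(stats.norm.sf((mu_x - b - mu_y) / sg_y))
    if sg_y == 0:
        return float(stats.norm.cdf((min(a, b + mu_y) - mu_x) / sg_x))
    mean = np.array([mu_x, mu_x - mu_y])
    cov = np.array([[sg_x**2, sg_x**2], [sg_x**2, sg_x**2 + sg_y**2]])
    return float(stats.multivariate_normal(mean=mean, cov=cov).cdf(np.array([a, b])))


def expected_rates(config: MarketConfig, n_mc: int = 100_000) -> dict[str, float]:
    """Expected per-requirement pass rates among assessed (non-confectionery)
    products implied by a :class:`MarketConfig`.

    Nutrient-threshold rates are closed-form for the log-normal/fixed
    families (a normal CDF, and a bivariate normal CDF for the two-limb
    sodium rule); any ``gamma`` distribution triggers a Monte-Carlo fallback
    at ``n_mc`` replicates with a logged warning.  Rates for requirements
    with restricted applicability (sugar-energy, fruit percentage) are
    conditional on the requirement being applicable.
    """
    p_conf = config.subcategory_probs.get(_SUB.confectionery_sweet_spreads_fruit_chews, 0.0)
    p_fruit_sub = config.subcategory_probs.get(_SUB.fruit_fresh_or_dry, 0.0)
    p_other_sub = config.subcategory_probs.get(_SUB.other_snacks_finger_foods, 0.0)
    denom = p_fruit_sub + p_other_sub
    if denom == 0:
        raise ValueError("no assessable (non-confectionery) mass in subcategory_probs")
    w_f, w_o = p_fruit_sub / denom, p_other_sub / denom

    m = config.missingness_rates
    d = config.nutrient_distributions
    mc_needed = any(d[k].family == "gamma" for k in ("energy", "sugar", "sodium", "fat"))
    if mc_needed:
        logger.warning(
            "gamma distribution has no closed-form pass rate; falling back to "
            "Monte Carlo with %d replicates (SE of a rate p is sqrt(p(1-p)/%d))",
            n_mc, n_mc,
        )
        rng = np.random.default_rng(config.seed + 1_000_003)
        en = d["energy"].sample(rng, n_mc)
        su = d["sugar"].sample(rng, n_mc)
        na = d["sodium"].sample(rng, n_mc)
        fa = d["fat"].sample(rng, n_mc)
        p_sugar_ok = float(np.mean(su * 4.0 / en * 100.0 < 15.0))
        p_sodium_ok = float(np.mean((na < 50.0) & (na / en * 100.0 < 50.0)))
        p_fat_ok = float(np.mean(fa / en * 100.0 <= 4.5))
    else:
        p_sugar_ok = _p_ratio_lt(d["sugar"], d["energy"], 3.75)  # 15% energy = 3.75 g/100 kcal
        p_sodium_ok = _p_sodium_joint(d["sodium"], d["energy"])
        p_fat_ok = _p_ratio_lt(d["fat"], d["energy"], 4.5)

    decl = lambda *keys: math.prod(1.0 - m.get(k, 0.0) for k in keys)
    fl = config.labelling_flag_rates

    rates: dict[str, float] = {
        "no_added_sugar": decl("ingredient_list") * (w_f + w_o * (1.0 - config.p_added_sugar)),
        "sugar_energy_lt_15pct": decl("sugar", "energy") * p_sugar_ok,
        "sodium_limit": decl("sodium", "energy") * p_sodium_ok,
        "fat_limit": decl("fat", "energy") * p_fat_ok,
        "L1": 1.0 - m.get("age_statement", 0.0),
        "L2": 1.0 - fl["marketed_under_6mo_true"],
        "L3": fl["bf_message_true"],
        "L4": 1.0 - fl["bm_superiority_true"],
        "L5": 1.0 - fl["bottle_promotion_true"],
        **{
            reference_lid: 1.0 - config.claim_rates.get(cat, 0.0)
            for cat, reference_lid in (
                (ClaimCategory.nonpermitted_compositional, "L6"),
                (ClaimCategory.nutrient_content, "L7"),
                (ClaimCategory.nutrient_function, "L8"),
                (ClaimCategory.disease_risk_reduction, "L9"),
                (ClaimCategory.other, "L10"),
            )
        },
        "L11": decl("ingredient_list")
        * (w_f + w_o * ((1.0 - config.p_contains_fruit)
                        + config.p_contains_fruit * config.p_name_order_ok)),
    }
    # L12 conditional on applicability (NA iff list present and fruit-free)
    p_has_fruit = w_f + w_o * config.p_contains_fruit
    p_applicable = 1.0 - decl("ingredient_list") * (1.0 - p_has_fruit)
    if p_applicable > 0:
        rates["L12"] = decl("ingredient_list") * p_has_fruit * config.p_fruit_pct_stated / p_applicable
    else:
        rates["L12"] = float("nan")
    return rates
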