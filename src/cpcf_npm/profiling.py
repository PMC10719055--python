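"""Nutrient normalization and the four nutrient-composition requirements.

The adapted NPM for CPCF applies four composition requirements to dry finger
foods/snacks:

1. **no added sugar/sweetener** — no ingredient matches the added-sugar
   lexicon (mono-/disaccharides, syrups, nectars, honey, fruit juices and
   concentrates excluding lemon/lime juice, and nonsugar sweeteners);
2. **< 15% of total energy from total sugar** — not applicable to the
   "fruit (fresh or dry)" subcategory; 15% of energy at 4 kcal/g equals
   3.75 g sugar per 100 kcal;
3. **sodium < 50 mg/100 kcal AND < 50 mg/100 g** — a conjunction, both limbs
   must hold; where only salt is declared, sodium = salt / 2.5;
4. **total fat ≤ 4.5 g/100 kcal**.

Inequalities are exactly as printed (strict for sugar-energy and both sodium
limbs, non-strict for fat) and are applied to exact declared values, with no
rounding.  A product categorized as "confectionery, sweet spreads and fruit
chews" automatically fails the whole model.  Missing label information needed
by a requirement fails that requirement.  A product passes the composition
assessment only if every applicable requirement is met.
"""

from __future__ import annotations

import enum
import logging
import re
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

from pydantic import BaseModel, Field

from .records import FingerFoodSubcategory, IngredientEntry, NutrientDeclaration

logger = logging.getLogger(__name__)

KCAL_PER_KJ = 1 / 4.184
KCAL_PER_G_SUGAR = 4.0   # Atwater, carbohydrate
KCAL_PER_G_FAT = 9.0     # Atwater, fat
SALT_TO_SODIUM_DIVISOR = 2.5

SUGAR_ENERGY_LIMIT_PCT = 15.0
SODIUM_LIMIT_MG_PER_100KCAL = 50.0
SODIUM_LIMIT_MG_PER_100G = 50.0
FAT_LIMIT_G_PER_100KCAL = 4.5


def sugar_energy_limit_g_per_100kcal() -> float:
    """Sugar ceiling expressed per 100 kcal: 15% of energy at 4 kcal/g → 3.75 g."""
    return SUGAR_ENERGY_LIMIT_PCT / 100.0 * 100.0 / KCAL_PER_G_SUGAR


def salt_to_sodium(salt: float) -> float:
    """Convert declared salt to sodium (same unit): sodium = salt / 2.5."""
    if salt < 0:
        raise ValueError("salt content cannot be negative")
    return salt / SALT_TO_SODIUM_DIVISOR


class Provenance(str, enum.Enum):
    declared = "declared"
    converted_from_salt = "converted_from_salt"
    converted_from_serving = "converted_from_serving"
    converted_from_kj = "converted_from_kj"


class NutrientProfile(BaseModel):
    """Normalized nutrient values per 100 g, per 100 kcal and as % of energy.

    Every field is optional; absence means the label did not declare the
    inputs needed to compute it.  ``provenance`` records, per per-100 g
    field, how the value was obtained.
    """

    energy_kcal_per_100g: Optional[float] = Field(default=None, ge=0)
    sugar_g_per_100g: Optional[float] = Field(default=None, ge=0)
    sodium_mg_per_100g: Optional[float] = Field(default=None, ge=0)
    fat_g_per_100g: Optional[float] = Field(default=None, ge=0)
    satfat_g_per_100g: Optional[float] = Field(default=None, ge=0)
    sugar_g_per_100kcal: Optional[float] = Field(default=None, ge=0)
    sodium_mg_per_100kcal: Optional[float] = Field(default=None, ge=0)
    fat_g_per_100kcal: Optional[float] = Field(default=None, ge=0)
    pct_energy_sugar: Optional[float] = Field(default=None, ge=0)
    pct_energy_fat: Optional[float] = Field(default=None, ge=0)
    provenance: dict[str, list[Provenance]] = Field(default_factory=dict)


def normalize_nutrients(decl: NutrientDeclaration) -> NutrientProfile:
    """Normalize a label declaration into a :class:`NutrientProfile`.

    Per-100 g declared values take precedence; otherwise per-serving values
    are rescaled by ``100 / serving_size_g``.  Energy declared only in kJ is
    converted at 4.184 kJ/kcal.  Declared sodium wins over salt-derived
    sodium (salt / 2.5, g → mg).  Per-100 kcal and %-energy fields are
    computed only when the per-100 g value and a positive energy density are
    both available.  Absent inputs propagate to absent outputs.
    """
    per100: dict[str, float] = {}
    prov: dict[str, list[Provenance]] = {}

    def take(field: str) -> tuple[Optional[float], list[Provenance]]:
        g = getattr(decl.per_100g, field, None) if decl.per_100g else None
        if g is not None:
            return g, [Provenance.declared]
        s = getattr(decl.per_serving, field, None) if decl.per_serving else None
        if s is not None:
            if decl.serving_size_g is None:
                logger.warning(
                    "per-serving %s declared without serving size; value unusable", field
                )
                return None, []
            return s * 100.0 / decl.serving_size_g, [Provenance.converted_from_serving]
        return None, []

    for field in ("total_sugar_g", "sodium_mg", "salt_g", "total_fat_g", "saturated_fat_g",
                  "energy_kcal", "energy_kj"):
        v, p = take(field)
        if v is not None:
            per100[field] = v
            prov[field] = p

    energy = per100.get("energy_kcal")
    energy_prov = prov.get("energy_kcal", [])
    if energy is None and "energy_kj" in per100:
        energy = per100["energy_kj"] / 4.184
        energy_prov = prov["energy_kj"] + [Provenance.converted_from_kj]

    sodium = per100.get("sodium_mg")
    sodium_prov = prov.get("sodium_mg", [])
    if sodium is None and "salt_g" in per100:
        sodium = salt_to_sodium(per100["salt_g"]) * 1000.0  # g -> mg
        sodium_prov = prov["salt_g"] + [Provenance.converted_from_salt]

    out = NutrientProfile(
        energy_kcal_per_100g=energy,
        sugar_g_per_100g=per100.get("total_sugar_g"),
        sodium_mg_per_100g=sodium,
        fat_g_per_100g=per100.get("total_fat_g"),
        satfat_g_per_100g=per100.get("saturated_fat_g"),
    )
    p = {}
    if energy is not None:
        p["energy_kcal_per_100g"] = energy_prov
    if sodium is not None:
        p["sodium_mg_per_100g"] = sodium_prov
    for src, dst in (
        ("total_sugar_g", "sugar_g_per_100g"),
        ("total_fat_g", "fat_g_per_100g"),
        ("saturated_fat_g", "satfat_g_per_100g"),
    ):
        if src in prov:
            p[dst] = prov[src]
    out.provenance = p

    if energy is not None:
        if energy > 0:
            if out.sugar_g_per_100g is not None:
                out.sugar_g_per_100kcal = out.sugar_g_per_100g / energy * 100.0
                out.pct_energy_sugar = out.sugar_g_per_100g * KCAL_PER_G_SUGAR / energy * 100.0
            if out.sodium_mg_per_100g is not None:
                out.sodium_mg_per_100kcal = out.sodium_mg_per_100g / energy * 100.0
            if out.fat_g_per_100g is not None:
                out.fat_g_per_100kcal = out.fat_g_per_100g / energy * 100.0
                out.pct_energy_fat = out.fat_g_per_100g * KCAL_PER_G_FAT / energy * 100.0
        else:
            logger.warning("energy density is zero; per-100 kcal values undefined")
    return out


# --------------------------------------------------------------------------
# Added-sugar lexicon
# --------------------------------------------------------------------------


class AddedSugarLexicon:
    """Token-boundary matcher over an editable term list with exception phrases."""

    def __init__(self, terms: Sequence[str], exceptions: Sequence[str]):
        self.terms = [t.casefold() for t in terms]
        self.exceptions = [e.casefold() for e in exceptions]
        self._term_res = [(t, re.compile(rf"\b{re.escape(t)}\b")) for t in self.terms]
        self._exc_res = [re.compile(rf"\b{re.escape(e)}\b") for e in self.exceptions]

    @classmethod
    def from_file(cls, path: Union[str, Path, None] = None) -> "AddedSugarLexicon":
        if path is None:
            path = Path(str(resources.files("cpcf_npm").joinpath("data/added_sugar_lexicon.txt")))
        terms: list[str] = []
        exceptions: list[str] = []
        bucket = terms
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "[exceptions]":
                bucket = exceptions
                continue
            bucket.append(line)
        return cls(terms, exceptions)

    def match(self, name: str) -> list[str]:
        """Terms matching ``name``, with matches inside exception phrases removed."""
        low = name.casefold()
        exc_spans = [m.span() for rx in self._exc_res for m in rx.finditer(low)]
        hits = []
        for term, rx in self._term_res:
            for m in rx.finditer(low):
                a, b = m.span()
                if not any(ea <= a and b <= eb for ea, eb in exc_spans):
                    hits.append(term)
                    break
        return hits


_DEFAULT_LEXICON: Optional[AddedSugarLexicon] = None


def default_added_sugar_lexicon() -> AddedSugarLexicon:
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        _DEFAULT_LEXICON = AddedSugarLexicon.from_file()
    return _DEFAULT_LEXICON


class AddedSugarResult(BaseModel):
    """Outcome of scanning an ingredient list for added sugars/sweeteners.

    ``found is None`` encodes *no ingredient list on the label*: absent
    evidence, which downstream fails the no-added-sugar requirement as
    missing information.
    """

    found: Optional[bool]
    matches: list[tuple[str, str]] = Field(default_factory=list)


def detect_added_sugar(
    ingredients: Sequence[IngredientEntry],
    lexicon: Optional[AddedSugarLexicon] = None,
) -> AddedSugarResult:
    """Scan an ordered ingredient list against the added-sugar lexicon.

    Matching is token-boundary and case-insensitive; the lemon/lime-juice
    exception is applied before the generic juice term.  Matches are returned
    as ``(ingredient name, matched term)`` pairs for audit.
    """
    if not ingredients:
        return AddedSugarResult(found=None)
    lexicon = lexicon or default_added_sugar_lexicon()
    matches = [(e.name, term) for e in ingredients for term in lexicon.match(e.name)]
    return AddedSugarResult(found=bool(matches), matches=matches)


# --------------------------------------------------------------------------
# Requirement evaluation
# --------------------------------------------------------------------------


class NutrientRequirement(str, enum.Enum):
    no_added_sugar = "no_added_sugar"
    sugar_energy_lt_15pct = "sugar_energy_lt_15pct"
    sodium_limit = "sodium_limit"
    fat_limit = "fat_limit"


NUTRIENT_REQUIREMENTS = tuple(NutrientRequirement)


class Status(str, enum.Enum):
    met = "met"
    not_met = "not_met"
    not_applicable = "not_applicable"


class Reason(str, enum.Enum):
    threshold_pass = "threshold_pass"
    threshold_fail = "threshold_fail"
    missing_declaration = "missing_declaration"
    lexicon_match = "lexicon_match"
    exempt_subcategory = "exempt_subcategory"
    auto_fail_confectionery = "auto_fail_confectionery"


class RequirementResult(BaseModel):
    requirement_id: str
    status: Status
    reason: Reason
    evidence: str = ""


class NutrientAssessment(BaseModel):
    """A product's verdict against the four composition requirements."""

    product_id: str = ""
    subcategory: FingerFoodSubcategory
    auto_failed: bool
    results: dict[NutrientRequirement, RequirementResult]
    n_applicable: int
    n_met: int
    overall_pass: bool


def _threshold_result(
    req: NutrientRequirement,
    value: Optional[float],
    ok: bool,
    evidence: str,
    missing_evidence: str,
) -> RequirementResult:
    if value is None:
        return RequirementResult(
            requirement_id=req.value,
            status=Status.not_met,
            reason=Reason.missing_declaration,
            evidence=missing_evidence,
        )
    return RequirementResult(
        requirement_id=req.value,
        status=Status.met if ok else Status.not_met,
        reason=Reason.threshold_pass if ok else Reason.threshold_fail,
        evidence=evidence,
    )


def evaluate_nutrient_requirements(
    subcategory: FingerFoodSubcategory,
    profile: NutrientProfile,
    added_sugar: AddedSugarResult,
    product_id: str = "",
) -> NutrientAssessment:
    """Apply the four composition requirements to one product.

    See the module docstring for the rules.  ``overall_pass`` is true iff the
    product is not confectionery and every applicable requirement is met;
    ``not_applicable`` results neither pass nor fail the product.
    """
    if subcategory is None:
        raise ValueError("subcategory is required to evaluate nutrient requirements")

    R = NutrientRequirement
    if subcategory is FingerFoodSubcategory.confectionery_sweet_spreads_fruit_chews:
        results = {
            req: RequirementResult(
                requirement_id=req.value,
                status=Status.not_met,
                reason=Reason.auto_fail_confectionery,
                evidence="confectionery, sweet spreads and fruit chews are de facto unsuitable",
            )
            for req in R
        }
        return NutrientAssessment(
            product_id=product_id,
            subcategory=subcategory,
            auto_failed=True,
            results=results,
            n_applicable=4,
            n_met=0,
            overall_pass=False,
        )

    results: dict[NutrientRequirement, RequirementResult] = {}

    # (1) no added sugar/sweetener
    if added_sugar.found is None:
        results[R.no_added_sugar] = RequirementResult(
            requirement_id=R.no_added_sugar.value,
            status=Status.not_met,
            reason=Reason.missing_declaration,
            evidence="no ingredient list on label",
        )
    elif added_sugar.found:
        results[R.no_added_sugar] = RequirementResult(
            requirement_id=R.no_added_sugar.value,
            status=Status.not_met,
            reason=Reason.lexicon_match,
            evidence="; ".join(f"{ing}: {term}" for ing, term in added_sugar.matches),
        )
    else:
        results[R.no_added_sugar] = RequirementResult(
            requirement_id=R.no_added_sugar.value,
            status=Status.met,
            reason=Reason.threshold_pass,
            evidence="no lexicon term matched",
        )

    # (2) <15% of total energy from total sugar (fruit subcategory exempt)
    if subcategory is FingerFoodSubcategory.fruit_fresh_or_dry:
        results[R.sugar_energy_lt_15pct] = RequirementResult(
            requirement_id=R.sugar_energy_lt_15pct.value,
            status=Status.not_applicable,
            reason=Reason.exempt_subcategory,
            evidence="not applicable to fruit (fresh or dry)",
        )
    else:
        pct = profile.pct_energy_sugar
        results[R.sugar_energy_lt_15pct] = _threshold_result(
            R.sugar_energy_lt_15pct,
            pct,
            pct is not None and pct < SUGAR_ENERGY_LIMIT_PCT,
            f"{pct if pct is None else round(pct, 3)}% of energy from sugar (limit <15%)",
            "total sugar and/or energy not declared",
        )

    # (3) sodium <50 mg/100 kcal AND <50 mg/100 g — conjunction
    na_g, na_kcal = profile.sodium_mg_per_100g, profile.sodium_mg_per_100kcal
    if na_g is None or na_kcal is None:
        results[R.sodium_limit] = RequirementResult(
            requirement_id=R.sodium_limit.value,
            status=Status.not_met,
            reason=Reason.missing_declaration,
            evidence="sodium/salt and/or energy not declared",
        )
    else:
        ok = na_g < SODIUM_LIMIT_MG_PER_100G and na_kcal < SODIUM_LIMIT_MG_PER_100KCAL
        results[R.sodium_limit] = RequirementResult(
            requirement_id=R.sodium_limit.value,
            status=Status.met if ok else Status.not_met,
            reason=Reason.threshold_pass if ok else Reason.threshold_fail,
            evidence=f"{round(na_g, 3)} mg/100 g, {round(na_kcal, 3)} mg/100 kcal (both limits <50)",
        )

    # (4) total fat ≤4.5 g/100 kcal
    fat = profile.fat_g_per_100kcal
    results[R.fat_limit] = _threshold_result(
        R.fat_limit,
        fat,
        fat is not None and fat <= FAT_LIMIT_G_PER_100KCAL,
        f"{fat if fat is None else round(fat, 3)} g fat/100 kcal (limit ≤4.5)",
        "total fat and/or energy not declared",
    )

    applicable = [r for r in results.values() if r.status is not Status.not_applicable]
    n_met = sum(r.status is Status.met for r in applicable)
    return NutrientAssessment(
        product_id=product_id,
        subcategory=subcategory,
        auto_failed=False,
        results=results,
        n_applicable=len(applicable),
        n_met=n_met,
        overall_pass=n_met == len(applicable),
    )
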