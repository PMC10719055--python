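"""The twelve labelling requirements and claim classification.

The adapted NPM for CPCF groups its labelling requirements into three blocks:

* **Protection and promotion of breastfeeding** (L1–L5): minimum age of at
  least 6 months displayed; not marketed as suitable under 6 months; a
  message on continued breastfeeding to 2 years and beyond; no suggestion of
  superiority/equivalence to breast milk; no bottle-feeding promotion.
* **Claims** (L6–L10): no claim of any of the five categories
  (nonpermitted compositional, nutrient content, nutrient function, disease
  risk reduction, other).
* **Name and ingredient-list clarity** (L11–L12): product name reflects
  ingredients in descending order; percentage of fruit stated (only for
  fruit-containing products).

Missing label information that a requirement needs fails that requirement —
this bites L1 (no printed age) and L3 (no breastfeeding message), and L11/L12
when no ingredient list is present.  For L2/L4/L5 the requirement is the
*absence* of a bad practice, so an uncoded flag passes.  ``not_applicable``
results never block a group.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml
from pydantic import BaseModel

from .profiling import Reason, RequirementResult, Status
from .records import ClaimCategory, ClaimRecord, IngredientEntry, ProductRecord

MIN_AGE_MONTHS = 6

LABELLING_IDS = tuple(f"L{i}" for i in range(1, 13))

GROUPS: dict[str, tuple[str, ...]] = {
    "breastfeeding": ("L1", "L2", "L3", "L4", "L5"),
    "claims": ("L6", "L7", "L8", "L9", "L10"),
    "clarity": ("L11", "L12"),
}

CLAIM_REQUIREMENT: dict[ClaimCategory, str] = {
    ClaimCategory.nonpermitted_compositional: "L6",
    ClaimCategory.nutrient_content: "L7",
    ClaimCategory.nutrient_function: "L8",
    ClaimCategory.disease_risk_reduction: "L9",
    ClaimCategory.other: "L10",
}


class ClaimLexicon(BaseModel):
    """Per-category regex pattern lists with an explicit precedence order."""

    precedence: list[ClaimCategory]
    patterns: dict[ClaimCategory, list[str]]

    @classmethod
    def from_file(cls, path: Union[str, Path, None] = None) -> "ClaimLexicon":
        if path is None:
            path = Path(str(resources.files("cpcf_npm").joinpath("data/claim_lexicon.yaml")))
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(
            precedence=[ClaimCategory(c) for c in raw["precedence"]],
            patterns={ClaimCategory(c): list(ps) for c, ps in raw["patterns"].items()},
        )

    def compiled(self) -> dict[ClaimCategory, list[re.Pattern]]:
        return {
            c: [re.compile(p, re.IGNORECASE) for p in ps] for c, ps in self.patterns.items()
        }


_DEFAULT_CLAIM_LEXICON: Optional[ClaimLexicon] = None
_COMPILED: Optional[dict[ClaimCategory, list[re.Pattern]]] = None


def default_claim_lexicon() -> ClaimLexicon:
    global _DEFAULT_CLAIM_LEXICON, _COMPILED
    if _DEFAULT_CLAIM_LEXICON is None:
        _DEFAULT_CLAIM_LEXICON = ClaimLexicon.from_file()
        _COMPILED = _DEFAULT_CLAIM_LEXICON.compiled()
    return _DEFAULT_CLAIM_LEXICON


def classify_claim(text: str, lexicon: Optional[ClaimLexicon] = None) -> Optional[ClaimCategory]:
    """Classify a claim text; first category (in precedence order) whose
    pattern fires wins.  Returns ``None`` when nothing fires, leaving the
    text for manual coding."""
    if lexicon is None:
        default_claim_lexicon()
        compiled = _COMPILED
        lexicon = _DEFAULT_CLAIM_LEXICON
    else:
        compiled = lexicon.compiled()
    assert lexicon is not None and compiled is not None
    for cat in lexicon.precedence:
        if any(rx.search(text) for rx in compiled.get(cat, [])):
            return cat
    return None


class LabellingAssessment(BaseModel):
    """A product's verdict against the twelve labelling requirements."""

    product_id: str = ""
    results: dict[str, RequirementResult]
    group_pass: dict[str, bool]
    overall_pass: bool


def _result(lid: str, status: Status, reason: Reason, evidence: str = "") -> RequirementResult:
    return RequirementResult(requirement_id=lid, status=status, reason=reason, evidence=evidence)


def _met(lid: str, evidence: str = "") -> RequirementResult:
    return _result(lid, Status.met, Reason.threshold_pass, evidence)


def _fail(lid: str, evidence: str = "") -> RequirementResult:
    return _result(lid, Status.not_met, Reason.threshold_fail, evidence)


def _missing(lid: str, evidence: str) -> RequirementResult:
    return _result(lid, Status.not_met, Reason.missing_declaration, evidence)


def evaluate_breastfeeding_requirements(record: ProductRecord) -> dict[str, RequirementResult]:
    """L1–L5: age display, under-6-months marketing, breastfeeding message,
    breast-milk superiority, bottle promotion.

    L1 and L3 require evidence *present* on the label, so absence fails them;
    L2/L4/L5 prohibit a practice, so an uncoded flag counts as met.  An age
    statement under 6 months fails both L1 and L2 (the product markets itself
    as suitable below 6 months).
    """
    out: dict[str, RequirementResult] = {}
    age = record.age_statement_months
    if age is None:
        out["L1"] = _missing("L1", "no age of introduction on label")
    elif age >= MIN_AGE_MONTHS:
        out["L1"] = _met("L1", f"age statement {age} months")
    else:
        out["L1"] = _fail("L1", f"age statement {age} months < 6")

    marketed_under_6 = record.marketed_under_6mo is True or (age is not None and age < MIN_AGE_MONTHS)
    out["L2"] = (
        _fail("L2", "marketed as suitable for <6 months")
        if marketed_under_6
        else _met("L2")
    )

    if record.has_bf_continuation_message is True:
        out["L3"] = _met("L3", "breastfeeding continuation message present")
    elif record.has_bf_continuation_message is False:
        out["L3"] = _fail("L3", "no breastfeeding continuation message")
    else:
        out["L3"] = _missing("L3", "breastfeeding message not coded / absent")

    out["L4"] = (
        _fail("L4", "suggests superiority/equivalence to breast milk")
        if record.suggests_bm_superiority is True
        else _met("L4")
    )
    out["L5"] = (
        _fail("L5", "recommends or promotes bottle feeding")
        if record.promotes_bottle_feeding is True
        else _met("L5")
    )
    return out


def evaluate_claim_requirements(
    claims: Sequence[ClaimRecord], lexicon: Optional[ClaimLexicon] = None
) -> dict[str, RequirementResult]:
    """L6–L10: the requirement for a claim category fails iff any claim of
    that category is present.  Pre-coded categories are authoritative; texts
    without one are classified with the lexicon; texts the lexicon cannot
    place block nothing (they are retained for manual coding)."""
    present: dict[ClaimCategory, list[str]] = {}
    for claim in claims:
        if claim.text is None and claim.category is None:
            raise ValueError("claim with neither text nor category")
        cat = claim.category
        if cat is None and claim.text is not None:
            cat = classify_claim(claim.text, lexicon)
        if cat is not None:
            present.setdefault(cat, []).append(claim.text or "<pre-coded>")
    out = {}
    for cat, lid in CLAIM_REQUIREMENT.items():
        if cat in present:
            out[lid] = _fail(lid, "; ".join(present[cat]))
        else:
            out[lid] = _met(lid)
    return out


def _name_order_met(name: str, ingredients: Sequence[IngredientEntry]) -> Optional[bool]:
    """L11 core: do the ingredients mentioned in the product name appear in
    the same relative order as in the (descending) ingredient list?

    Matching is longest-first, case-insensitive containment of ingredient
    names in the product name; a name mentioning no listed ingredient is met
    vacuously (returns None)."""
    low = name.casefold()
    positions: list[tuple[int, int]] = []  # (position in name, index in list)
    claimed: list[tuple[int, int]] = []  # spans already matched, longest first
    for idx, entry in sorted(
        enumerate(ingredients), key=lambda t: -len(t[1].name)
    ):
        for m in re.finditer(re.escape(entry.name.casefold()), low):
            a, b = m.span()
            if not any(ca < b and a < cb for ca, cb in claimed):
                claimed.append((a, b))
                positions.append((a, idx))
                break
    if not positions:
        return None
    positions.sort()
    list_order = [idx for _, idx in positions]
    return list_order == sorted(list_order)


def evaluate_clarity_requirements(record: ProductRecord) -> dict[str, RequirementResult]:
    """L11–L12: name/ingredient-order consistency and fruit percentages.

    No ingredient list → both fail as missing information.  L12 is not
    applicable to products with no fruit ingredient; otherwise every fruit
    ingredient must carry a percentage."""
    out: dict[str, RequirementResult] = {}
    if not record.ingredient_list:
        out["L11"] = _missing("L11", "no ingredient list on label")
        out["L12"] = _missing("L12", "no ingredient list on label")
        return out

    ordered = _name_order_met(record.descriptive_name or "", record.ingredient_list)
    if ordered is None:
        out["L11"] = _met("L11", "name mentions no listed ingredient (vacuously met)")
    elif ordered:
        out["L11"] = _met("L11", "name order matches ingredient list order")
    else:
        out["L11"] = _fail("L11", "name order contradicts ingredient list order")

    fruit = [e for e in record.ingredient_list if e.is_fruit is True]
    if not fruit:
        out["L12"] = _result(
            "L12", Status.not_applicable, Reason.exempt_subcategory, "no fruit ingredient"
        )
    elif all(e.percentage is not None for e in fruit):
        out["L12"] = _met("L12", "all fruit ingredients carry a percentage")
    else:
        missing = [e.name for e in fruit if e.percentage is None]
        out["L12"] = _missing("L12", f"fruit without percentage: {', '.join(missing)}")
    return out


def assess_labelling(
    record: ProductRecord, lexicon: Optional[ClaimLexicon] = None
) -> LabellingAssessment:
    """Aggregate L1–L12 with group subtotals; ``not_applicable`` never blocks."""
    results: dict[str, RequirementResult] = {}
    results.update(evaluate_breastfeeding_requirements(record))
    results.update(evaluate_claim_requirements(record.claims, lexicon))
    results.update(evaluate_clarity_requirements(record))
    group_pass = {
        g: all(results[lid].status is not Status.not_met for lid in lids)
        for g, lids in GROUPS.items()
    }
    return LabellingAssessment(
        product_id=record.product_id,
        results={lid: results[lid] for lid in LABELLING_IDS},
        group_pass=group_pass,
        overall_pass=all(group_pass.values()),
    )
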