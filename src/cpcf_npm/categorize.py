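"""CPCF identification, NPM category allocation and finger-food subcategories.

A product counts as a commercially produced complementary food (CPCF) when at
least one of four label criteria marks it as intended for children under
3 years: an age-of-introduction statement below 36 months, a "baby"/"infant"/
"toddler"-type text marker, an image of a young child, or any other
presentation of suitability (bottle imagery or preparation instructions
involving a bottle).

Category and subcategory allocation mirror the study's protocol, where trained
coders assigned products manually: a pre-coded hint on the record is always
authoritative, and a transparent keyword rule file (shipped in
``data/category_rules.txt``, editable) is the fallback.  A product no rule
matches raises :class:`NeedsManualCoding` — the engine never guesses.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .records import FingerFoodSubcategory, NPMCategory, ProductRecord

CPCF_AGE_LIMIT_MONTHS = 36

_TEXT_MARKER_RE = re.compile(
    r"\b(baby|babies|infant|toddler|young child|little one|bub|bebe|bébé)\b", re.IGNORECASE
)


class NeedsManualCoding(ValueError):
    """No categorization rule fired; the product needs a human coder (or a hint)."""


def default_rules_path() -> Path:
    return Path(str(resources.files("cpcf_npm").joinpath("data/category_rules.txt")))


class CategoryRules:
    """Ordered ``pattern => value`` rules parsed from the rule file."""

    def __init__(self, category_rules, subcategory_rules):
        self.category_rules: list[tuple[re.Pattern, NPMCategory]] = category_rules
        self.subcategory_rules: list[tuple[re.Pattern, FingerFoodSubcategory]] = subcategory_rules

    @classmethod
    def from_file(cls, path: Union[str, Path, None] = None) -> "CategoryRules":
        path = Path(path) if path is not None else default_rules_path()
        section = None
        cat: list[tuple[re.Pattern, NPMCategory]] = []
        sub: list[tuple[re.Pattern, FingerFoodSubcategory]] = []
        for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1]
                continue
            if "=>" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'pattern => value'")
            pattern, value = (s.strip() for s in line.split("=>", 1))
            rx = re.compile(pattern, re.IGNORECASE)
            if section == "category":
                cat.append((rx, NPMCategory(value)))
            elif section == "subcategory":
                sub.append((rx, FingerFoodSubcategory(value)))
            else:
                raise ValueError(f"{path}:{lineno}: rule outside a [category]/[subcategory] section")
        return cls(cat, sub)


_DEFAULT_RULES: Optional[CategoryRules] = None


def _rules(rules: Optional[CategoryRules]) -> CategoryRules:
    global _DEFAULT_RULES
    if rules is not None:
        return rules
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = CategoryRules.from_file()
    return _DEFAULT_RULES


def _label_text(record: ProductRecord) -> str:
    return " ".join(
        s for s in (record.brand, record.subbrand, record.descriptive_name, record.flavour) if s
    )


def is_cpcf(record: ProductRecord) -> tuple[bool, set[str]]:
    """Decide CPCF status; returns the matched criteria for audit.

    Criteria: ``age_lt_3y`` (printed introduction age < 36 months),
    ``text_marker`` (baby/infant/toddler wording), ``child_image`` (coded
    flag), ``other_presentation`` (bottle imagery / other coded presentation).
    All-absent evidence yields ``(False, set())`` — never an error.
    """
    matched: set[str] = set()
    if record.age_statement_months is not None and record.age_statement_months < CPCF_AGE_LIMIT_MONTHS:
        matched.add("age_lt_3y")
    if _TEXT_MARKER_RE.search(_label_text(record)):
        matched.add("text_marker")
    if record.has_child_image is True:
        matched.add("child_image")
    if record.promotes_bottle_feeding is True:
        matched.add("other_presentation")
    return bool(matched), matched


def assign_npm_category(
    record: ProductRecord, rules: Optional[CategoryRules] = None
) -> NPMCategory:
    """Allocate a CPCF to one of the six NPM categories.

    The pre-coded ``category_hint`` is authoritative; otherwise the keyword
    rule file is applied to the label text, first match wins.  Condiments,
    powders, seasonings and flosses fall under ``other_cpcf``.
    """
    if record.category_hint is not None:
        return record.category_hint
    text = _label_text(record)
    for rx, category in _rules(rules).category_rules:
        if rx.search(text):
            return category
    raise NeedsManualCoding(
        f"product {record.product_id!r}: no category rule matches {text!r}; "
        "set category_hint or extend the rule file"
    )


def assign_subcategory(
    record: ProductRecord, rules: Optional[CategoryRules] = None
) -> FingerFoodSubcategory:
    """Assign a dry finger food/snack to one of the three subcategories.

    Order of resolution: pre-coded hint; confectionery keywords; an
    all-fruit ingredient list (single-ingredient fruit products are
    "fruit (fresh or dry)"); fruit keywords; otherwise "other snacks and
    finger foods" (biscuits, rusks, chips/crisps, rice cakes, ...).
    """
    if record.subcategory_hint is not None:
        return record.subcategory_hint
    if record.category_hint is not None and record.category_hint != NPMCategory.dry_finger_food_snack:
        raise ValueError(
            f"product {record.product_id!r}: subcategory is defined only for dry finger foods/snacks"
        )
    text = _label_text(record)
    r = _rules(rules)
    conf = FingerFoodSubcategory.confectionery_sweet_spreads_fruit_chews
    for rx, sub in r.subcategory_rules:
        if sub is conf and rx.search(text):
            return conf
    if record.ingredient_list and all(e.is_fruit is True for e in record.ingredient_list):
        return FingerFoodSubcategory.fruit_fresh_or_dry
    for rx, sub in r.subcategory_rules:
        if rx.search(text):
            return sub
    return FingerFoodSubcategory.other_snacks_finger_foods
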