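"""Product-label data schema, I/O, uniqueness rules and double-entry reconciliation.

One :class:`ProductRecord` holds everything extracted from a single unique
product's label: identity fields, the age-of-introduction statement, coded
marketing flags, the ordered ingredient list, claims, and the nutrient content
declaration.  Every optional field distinguishes *absent from the label*
(``None``) from an explicit false/zero value — the assessment rules treat
missing label information as a failure of the affected requirement, so the
distinction must survive parsing and round-tripping.

The on-disk dialect is a flat CSV (UTF-8, comma) with one row per product; the
column dictionary is documented in ``docs/column_dictionary.md``.  A JSON
mirror uses identical field names.
"""

from __future__ import annotations

import enum
import io
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, Field, model_validator

logger = logging.getLogger(__name__)

STUDY_COUNTRIES = ("KH", "ID", "LA", "MY", "PH", "TH", "VN")
"""ISO-3166 codes of the seven Southeast-Asian study countries (any code is accepted)."""


class ManufacturerOrigin(str, enum.Enum):
    national = "national"
    international = "international"
    unknown = "unknown"


class NPMCategory(str, enum.Enum):
    """The six product categories of the adapted NPM for CPCF."""

    dry_cereal = "dry_cereal"
    soft_wet_spoonable = "soft_wet_spoonable"
    wet_meal_chunky = "wet_meal_chunky"
    dry_finger_food_snack = "dry_finger_food_snack"
    juice_drink = "juice_drink"
    other_cpcf = "other_cpcf"


class FingerFoodSubcategory(str, enum.Enum):
    """Subcategories of dry finger foods/snacks; defined only for that category."""

    confectionery_sweet_spreads_fruit_chews = "confectionery_sweet_spreads_fruit_chews"
    fruit_fresh_or_dry = "fruit_fresh_or_dry"
    other_snacks_finger_foods = "other_snacks_finger_foods"


class ClaimCategory(str, enum.Enum):
    nonpermitted_compositional = "nonpermitted_compositional"
    nutrient_content = "nutrient_content"
    nutrient_function = "nutrient_function"
    disease_risk_reduction = "disease_risk_reduction"
    other = "other"


class IngredientEntry(BaseModel):
    """One entry of the ordered (descending-content) ingredient list."""

    name: str
    percentage: Optional[float] = Field(default=None, ge=0, le=100)
    is_fruit: Optional[bool] = None


class ClaimRecord(BaseModel):
    """A label claim: free text, a pre-coded category, or both."""

    text: Optional[str] = None
    category: Optional[ClaimCategory] = None

    @model_validator(mode="after")
    def _text_or_category(self) -> "ClaimRecord":
        if self.text is None and self.category is None:
            raise ValueError("a claim needs at least one of text/category")
        return self


class NutrientValues(BaseModel):
    """Declared nutrient amounts on one basis (per 100 g or per serving)."""

    energy_kcal: Optional[float] = Field(default=None, ge=0)
    energy_kj: Optional[float] = Field(default=None, ge=0)
    total_sugar_g: Optional[float] = Field(default=None, ge=0)
    sodium_mg: Optional[float] = Field(default=None, ge=0)
    salt_g: Optional[float] = Field(default=None, ge=0)
    total_fat_g: Optional[float] = Field(default=None, ge=0)
    saturated_fat_g: Optional[float] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _satfat_le_fat(self) -> "NutrientValues":
        if (
            self.saturated_fat_g is not None
            and self.total_fat_g is not None
            and self.saturated_fat_g > self.total_fat_g + 1e-9
        ):
            raise ValueError("saturated fat exceeds total fat")
        return self

    def is_empty(self) -> bool:
        return all(v is None for v in self.model_dump().values())


class NutrientDeclaration(BaseModel):
    """Label nutrient declaration: per-100 g and/or per-serving values.

    ``serving_size_g`` is required to make per-serving values usable; a
    declaration carrying per-serving values without a serving size is accepted
    (it occurs on real labels) and degrades to absent values at normalization
    time, with a warning.
    """

    serving_size_g: Optional[float] = Field(default=None, gt=0)
    per_100g: Optional[NutrientValues] = None
    per_serving: Optional[NutrientValues] = None

    @property
    def basis(self) -> Optional[str]:
        has_g = self.per_100g is not None and not self.per_100g.is_empty()
        has_s = self.per_serving is not None and not self.per_serving.is_empty()
        if has_g and has_s:
            return "both"
        if has_g:
            return "per_100g"
        if has_s:
            return "per_serving"
        return None


class ProductRecord(BaseModel):
    """All label information extracted for one unique product.

    Coded flags (``marketed_under_6mo``, ``has_bf_continuation_message``,
    ``suggests_bm_superiority``, ``promotes_bottle_feeding``,
    ``has_child_image``) are tri-state: ``True`` / ``False`` / ``None``
    (= not coded / absent from label).
    """

    product_id: str
    country: str
    brand: str
    subbrand: Optional[str] = None
    descriptive_name: Optional[str] = None
    flavour: Optional[str] = None
    manufacturer: Optional[str] = None
    manufacturer_origin: ManufacturerOrigin = ManufacturerOrigin.unknown
    age_statement_months: Optional[int] = Field(default=None, ge=0)
    marketed_under_6mo: Optional[bool] = None
    has_bf_continuation_message: Optional[bool] = None
    suggests_bm_superiority: Optional[bool] = None
    promotes_bottle_feeding: Optional[bool] = None
    has_child_image: Optional[bool] = None
    ingredient_list: list[IngredientEntry] = Field(default_factory=list)
    claims: list[ClaimRecord] = Field(default_factory=list)
    declarations: NutrientDeclaration = Field(default_factory=NutrientDeclaration)
    category_hint: Optional[NPMCategory] = None
    subcategory_hint: Optional[FingerFoodSubcategory] = None


# --------------------------------------------------------------------------
# CSV dialect
# --------------------------------------------------------------------------

_BOOL_COLS = (
    "marketed_under_6mo",
    "has_bf_continuation_message",
    "suggests_bm_superiority",
    "promotes_bottle_feeding",
    "has_child_image",
)

_NUTRIENT_FIELDS = (
    "energy_kcal",
    "energy_kj",
    "total_sugar_g",
    "sodium_mg",
    "salt_g",
    "total_fat_g",
    "saturated_fat_g",
)

COLUMNS: tuple[str, ...] = (
    "product_id",
    "country",
    "brand",
    "subbrand",
    "descriptive_name",
    "flavour",
    "manufacturer",
    "manufacturer_origin",
    "age_statement_months",
    *_BOOL_COLS,
    "category_hint",
    "subcategory_hint",
    "serving_size_g",
    *(f"{f}_100g" for f in _NUTRIENT_FIELDS),
    *(f"{f}_serv" for f in _NUTRIENT_FIELDS),
    "ingredients",
    "claims",
)

_ING_RE = re.compile(
    r"^(?P<name>.*?)(?:\s*\((?P<pct>\d+(?:\.\d+)?)%\))?(?:\s*\[(?P<fruit>fruit|nonfruit)\])?$"
)


def _fmt_num(x: Optional[float]) -> str:
    if x is None:
        return ""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def encode_ingredients(entries: Sequence[IngredientEntry]) -> str:
    parts = []
    for e in entries:
        s = e.name
        if e.percentage is not None:
            s += f" ({_fmt_num(e.percentage)}%)"
        if e.is_fruit is True:
            s += " [fruit]"
        elif e.is_fruit is False:
            s += " [nonfruit]"
        parts.append(s)
    return "; ".join(parts)


def decode_ingredients(cell: str) -> list[IngredientEntry]:
    entries: list[IngredientEntry] = []
    for part in cell.split(";"):
        part = part.strip()
        if not part:
            continue
        m = _ING_RE.match(part)
        assert m is not None  # regex is total
        fruit = {"fruit": True, "nonfruit": False, None: None}[m.group("fruit")]
        pct = float(m.group("pct")) if m.group("pct") else None
        entries.append(IngredientEntry(name=m.group("name").strip(), percentage=pct, is_fruit=fruit))
    return entries


def encode_claims(claims: Sequence[ClaimRecord]) -> str:
    parts = []
    for c in claims:
        cat = c.category.value if c.category else ""
        if c.category and c.text:
            parts.append(f"{cat}::{c.text}")
        elif c.category:
            parts.append(f"{cat}::")
        else:
            parts.append(c.text or "")
    return " | ".join(parts)


def decode_claims(cell: str) -> list[ClaimRecord]:
    claims = []
    for part in cell.split("|"):
        part = part.strip()
        if not part:
            continue
        if "::" in part:
            cat, text = part.split("::", 1)
            claims.append(
                ClaimRecord(category=ClaimCategory(cat.strip()), text=text.strip() or None)
            )
        else:
            claims.append(ClaimRecord(text=part))
    return claims


def record_to_row(rec: ProductRecord) -> dict[str, str]:
    """Flatten one record into the CSV dialect (all values as strings)."""
    row = {c: "" for c in COLUMNS}
    row["product_id"] = rec.product_id
    row["country"] = rec.country
    row["brand"] = rec.brand
    for f in ("subbrand", "descriptive_name", "flavour", "manufacturer"):
        row[f] = getattr(rec, f) or ""
    row["manufacturer_origin"] = rec.manufacturer_origin.value
    row["age_statement_months"] = (
        "" if rec.age_statement_months is None else str(rec.age_statement_months)
    )
    for f in _BOOL_COLS:
        v = getattr(rec, f)
        row[f] = "" if v is None else ("true" if v else "false")
    row["category_hint"] = rec.category_hint.value if rec.category_hint else ""
    row["subcategory_hint"] = rec.subcategory_hint.value if rec.subcategory_hint else ""
    row["serving_size_g"] = _fmt_num(rec.declarations.serving_size_g)
    for basis, suffix in ((rec.declarations.per_100g, "100g"), (rec.declarations.per_serving, "serv")):
        if basis is None:
            continue
        for f in _NUTRIENT_FIELDS:
            row[f"{f}_{suffix}"] = _fmt_num(getattr(basis, f))
    row["ingredients"] = encode_ingredients(rec.ingredient_list)
    row["claims"] = encode_claims(rec.claims)
    return row


class RowParseError(ValueError):
    """A row could not be converted to a valid :class:`ProductRecord`."""


def _opt_float(cell: str, row_idx: int, col: str) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise RowParseError(f"row {row_idx}: malformed numeric cell in column '{col}': {cell!r}")


def _opt_bool(cell: str, row_idx: int, col: str) -> Optional[bool]:
    cell = cell.strip().lower()
    if cell == "":
        return None
    if cell in ("true", "1", "yes"):
        return True
    if cell in ("false", "0", "no"):
        return False
    raise RowParseError(f"row {row_idx}: malformed boolean cell in column '{col}': {cell!r}")


def row_to_record(row: dict[str, str], row_idx: int = 0) -> ProductRecord:
    get = lambda c: str(row.get(c, "") if row.get(c) is not None else "").strip()
    country, brand = get("country"), get("brand")
    if not country or not brand:
        raise RowParseError(f"row {row_idx}: mandatory identity fields missing (country, brand)")

    def values_for(suffix: str) -> Optional[NutrientValues]:
        kw = {f: _opt_float(get(f"{f}_{suffix}"), row_idx, f"{f}_{suffix}") for f in _NUTRIENT_FIELDS}
        vals = NutrientValues(**kw)
        return None if vals.is_empty() else vals

    age = _opt_float(get("age_statement_months"), row_idx, "age_statement_months")
    return ProductRecord(
        product_id=get("product_id") or f"row{row_idx}",
        country=country,
        brand=brand,
        subbrand=get("subbrand") or None,
        descriptive_name=get("descriptive_name") or None,
        flavour=get("flavour") or None,
        manufacturer=get("manufacturer") or None,
        manufacturer_origin=ManufacturerOrigin(get("manufacturer_origin") or "unknown"),
        age_statement_months=None if age is None else int(age),
        **{f: _opt_bool(get(f), row_idx, f) for f in _BOOL_COLS},
        category_hint=NPMCategory(get("category_hint")) if get("category_hint") else None,
        subcategory_hint=(
            FingerFoodSubcategory(get("subcategory_hint")) if get("subcategory_hint") else None
        ),
        declarations=NutrientDeclaration(
            serving_size_g=_opt_float(get("serving_size_g"), row_idx, "serving_size_g"),
            per_100g=values_for("100g"),
            per_serving=values_for("serv"),
        ),
        ingredient_list=decode_ingredients(get("ingredients")),
        claims=decode_claims(get("claims")),
    )


Source = Union[str, Path, io.TextIOBase, pd.DataFrame]


def parse_product_table(
    source: Source,
    *,
    delimiter: str = ",",
    encoding: str = "utf-8",
    on_error: str = "log",
) -> list[ProductRecord]:
    """Read a product table (CSV path/stream or DataFrame) into records.

    Empty cells become absent values (never zero).  Unknown columns are
    ignored with a warning.  Rows that fail validation are rejected and
    logged (``on_error='log'``, default) or raise (``on_error='raise'``).
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=delimiter, encoding=encoding, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in COLUMNS]
    if unknown:
        logger.warning("ignoring unknown columns: %s", unknown)
    records: list[ProductRecord] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            records.append(row_to_record({k: str(v) for k, v in row.items()}, row_idx=i))
        except (RowParseError, ValueError) as exc:
            if on_error == "raise":
                raise
            logger.warning("rejected row %d: %s", i, exc)
    return records


def write_product_table(records: Iterable[ProductRecord], path: Union[str, Path, io.TextIOBase]) -> None:
    """Write records in the products.csv dialect (UTF-8, comma)."""
    df = pd.DataFrame([record_to_row(r) for r in records], columns=list(COLUMNS))
    df.to_csv(path, index=False)


def write_product_json(records: Iterable[ProductRecord], path: Union[str, Path]) -> None:
    data = [r.model_dump(mode="json") for r in records]
    Path(path).write_text(json.dumps(data, indent=1), encoding="utf-8")


def read_product_json(path: Union[str, Path]) -> list[ProductRecord]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return [ProductRecord.model_validate(d) for d in data]


# --------------------------------------------------------------------------
# Uniqueness (dedup) and double-entry reconciliation
# --------------------------------------------------------------------------

_WS_RE = re.compile(r"\s+")


def _norm(value: object) -> str:
    return _WS_RE.sub(" ", str(value if value is not None else "").strip()).casefold()


def _uniqueness_key(rec: ProductRecord) -> tuple:
    # Package size/type never enters the key: single- vs multi-serving packs of
    # the same product collapse to one.
    return (
        _norm(rec.brand),
        _norm(rec.subbrand),
        _norm(rec.descriptive_name),
        rec.age_statement_months,
        _norm(rec.manufacturer),
        _norm(rec.flavour),
    )


def dedup_products(
    records: Sequence[ProductRecord],
) -> tuple[list[ProductRecord], list[tuple[str, str]]]:
    """Collapse within-country duplicates.

    Two records are the same product iff they agree on brand, subbrand,
    descriptive name, age statement, manufacturer and flavour after
    case/whitespace normalization.  The first occurrence is kept.

    Raises ``ValueError`` on cross-country input: dedup is a within-country
    operation, so callers must group by country first.
    """
    countries = {r.country for r in records}
    if len(countries) > 1:
        raise ValueError(f"dedup_products requires records from one country, got {sorted(countries)}")
    seen: dict[tuple, ProductRecord] = {}
    dropped: list[tuple[str, str]] = []
    unique: list[ProductRecord] = []
    for rec in records:
        key = _uniqueness_key(rec)
        if key in seen:
            dropped.append((seen[key].product_id, rec.product_id))
        else:
            seen[key] = rec
            unique.append(rec)
    return unique, dropped


DEFAULT_CHECK_FIELDS: tuple[str, ...] = (
    "country",
    "brand",
    "subbrand",
    "descriptive_name",
    "flavour",
    "manufacturer",
    "manufacturer_origin",
    "age_statement_months",
    *_BOOL_COLS,
    "serving_size_g",
    *(f"{f}_100g" for f in _NUTRIENT_FIELDS),
    *(f"{f}_serv" for f in _NUTRIENT_FIELDS),
    "ingredients",
    "claims",
)
"""Fields entering the double-entry error check (configurable; the study did
not publish its field set)."""


class DiscrepancyReport(BaseModel):
    """Outcome of comparing two independent transcriptions of the same labels."""

    n_records_compared: int
    n_fields_compared: int
    n_mismatches: int
    mismatch_rate: float
    threshold: float
    passed: bool
    mismatches: list[tuple[str, str, str, str]] = Field(default_factory=list)

    @model_validator(mode="after")
    def _rate_consistent(self) -> "DiscrepancyReport":
        if self.n_fields_compared:
            expected = self.n_mismatches / self.n_fields_compared
            if abs(self.mismatch_rate - expected) > 1e-12:
                raise ValueError("mismatch_rate inconsistent with counts")
        return self


def reconcile_double_entry(
    entry_a: Sequence[ProductRecord],
    entry_b: Sequence[ProductRecord],
    *,
    fields: Sequence[str] = DEFAULT_CHECK_FIELDS,
    threshold: float = 0.05,
) -> DiscrepancyReport:
    """Field-by-field comparison of two independently entered datasets.

    Records are matched on ``product_id``; an id present in only one entry
    counts as one whole-record mismatch.  The check passes when the mismatch
    rate is strictly below ``threshold`` (the study repeated its check until
    the error rate was below 5%).
    """
    rows_a = {r.product_id: record_to_row(r) for r in entry_a}
    rows_b = {r.product_id: record_to_row(r) for r in entry_b}
    common = sorted(set(rows_a) & set(rows_b))
    only = sorted(set(rows_a) ^ set(rows_b))
    mismatches: list[tuple[str, str, str, str]] = []
    n_fields = 0
    for pid in common:
        for f in fields:
            n_fields += 1
            va, vb = rows_a[pid].get(f, ""), rows_b[pid].get(f, "")
            if _norm(va) != _norm(vb):
                mismatches.append((pid, f, va, vb))
    for pid in only:
        n_fields += 1
        side_a = "present" if pid in rows_a else "missing"
        side_b = "present" if pid in rows_b else "missing"
        mismatches.append((pid, "<record>", side_a, side_b))
    n_mis = len(mismatches)
    rate = n_mis / n_fields if n_fields else 0.0
    return DiscrepancyReport(
        n_records_compared=len(common) + len(only),
        n_fields_compared=n_fields,
        n_mismatches=n_mis,
        mismatch_rate=rate,
        threshold=threshold,
        passed=rate < threshold,
        mismatches=mismatches,
    )
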