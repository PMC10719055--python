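"""Aggregate reporting: survey-style tables and the origin comparison.

Conventions, fixed package-wide:

* percentages are ``100 * count / denominator`` rounded half-away-from-zero
  to one decimal, always via :func:`format_percentage` (tables are never
  computed through a second path);
* medians of even-sized samples are the mean of the middle two; quartiles
  use the linear-interpolation convention;
* every percentage cell carries its count and denominator, because
  applicability varies by requirement (the sugar-energy rule skips fruit
  products; the fruit-percentage rule applies only to fruit-containing
  products; nutrient-content summaries exclude products without the relevant
  declaration).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
import numpy as np
import pandas as pd
from pydantic import BaseModel
from scipy.stats import chi2_contingency

from .labelling import LABELLING_IDS
from .profiling import NutrientRequirement, Status
from .records import FingerFoodSubcategory

ALL_LABEL = "All products"

_MET = Status.met.value
_NA = Status.not_applicable.value


def format_percentage(count: int, denominator: int) -> float:
    """One-decimal percentage, rounded half-away-from-zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= denominator:
        raise ValueError("count must lie in [0, denominator]")
    pct = Decimal(100 * count) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _strata(df: pd.DataFrame) -> list[tuple[str, pd.DataFrame]]:
    out = [(c, g) for c, g in df.groupby("country", sort=True)]
    out.append((ALL_LABEL, df))
    return out


def _pct_cell(count: int, denom: int) -> dict:
    return {
        "count": int(count),
        "denominator": int(denom),
        "percentage": format_percentage(int(count), int(denom)) if denom else None,
    }


def summarize_subcategories(assessments: pd.DataFrame) -> pd.DataFrame:
    """Per-country (and overall) subcategory distribution as % (n).

    Long format: one row per stratum × subcategory, with explicit zero
    counts for subcategories absent from a stratum.
    """
    rows = []
    subcats = [s.value for s in FingerFoodSubcategory]
    for stratum, g in _strata(assessments):
        for sub in subcats:
            rows.append(
                {
                    "stratum": stratum,
                    "subcategory": sub,
                    **_pct_cell((g["subcategory"] == sub).sum(), len(g)),
                }
            )
    return pd.DataFrame(rows)


def summarize_nutrient_performance(assessments: pd.DataFrame) -> pd.DataFrame:
    """Proportion meeting each composition requirement, among assessed products.

    Input must already exclude confectionery (the auto-failed products the
    published assessment table leaves out); passing any raises.  The
    sugar-energy denominator excludes fruit-subcategory products (the rule
    does not apply to them).  Includes a met-all row-part and the
    median/range of the number of requirements met.
    """
    if len(assessments) == 0:
        raise ValueError("no assessed products (empty denominator)")
    if assessments["auto_failed"].any():
        raise ValueError("confectionery (auto-failed) products must be excluded upstream")
    rows = []
    for stratum, g in _strata(assessments):
        row: dict = {"stratum": stratum, "n": len(g)}
        for req in NutrientRequirement:
            applicable = g[g[req.value] != _NA]
            met = (applicable[req.value] == _MET).sum()
            cell = _pct_cell(met, len(applicable))
            row[f"{req.value}_count"] = cell["count"]
            row[f"{req.value}_denominator"] = cell["denominator"]
            row[f"{req.value}_percentage"] = cell["percentage"]
        met_all = g["nutrient_pass"].sum()
        row.update(
            met_all_count=int(met_all),
            met_all_denominator=len(g),
            met_all_percentage=format_percentage(int(met_all), len(g)),
            n_met_median=float(np.median(g["n_met"])),
            n_met_min=int(g["n_met"].min()),
            n_met_max=int(g["n_met"].max()),
        )
        rows.append(row)
    return pd.DataFrame(rows)


_NUTRIENT_COLS = {
    "sugar": "sugar_g_per_100g",
    "sodium": "sodium_mg_per_100g",
    "fat": "fat_g_per_100g",
    "satfat": "satfat_g_per_100g",
}


def summarize_nutrient_content(assessments: pd.DataFrame) -> pd.DataFrame:
    """Median [IQR] nutrient content per 100 g by country and overall.

    Products without the relevant declaration are excluded from that
    nutrient's n; each cell reports its own n.
    """
    rows = []
    for stratum, g in _strata(assessments):
        row: dict = {"stratum": stratum}
        for label, col in _NUTRIENT_COLS.items():
            values = g[col].dropna().to_numpy(dtype=float)
            row[f"{label}_n"] = int(values.size)
            if values.size:
                row[f"{label}_median"] = float(np.median(values))
                row[f"{label}_q1"] = float(np.percentile(values, 25))
                row[f"{label}_q3"] = float(np.percentile(values, 75))
            else:
                row[f"{label}_median"] = row[f"{label}_q1"] = row[f"{label}_q3"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_labelling(assessments: pd.DataFrame) -> pd.DataFrame:
    """Proportion meeting each labelling requirement among assessed products.

    The fruit-percentage denominator is restricted to products where the
    requirement applies (fruit-containing, or missing the list needed to
    tell).  Group subtotals treat ``not_applicable`` as non-blocking, and a
    met-all row-part summarizes the full conjunction.
    """
    assessed = assessments[~assessments["auto_failed"].astype(bool)]
    if len(assessed) == 0:
        raise ValueError("no assessed products (empty denominator)")
    rows = []
    for stratum, g in _strata(assessed):
        row: dict = {"stratum": stratum, "n": len(g)}
        for lid in LABELLING_IDS:
            applicable = g[g[lid] != _NA]
            met = (applicable[lid] == _MET).sum()
            cell = _pct_cell(met, len(applicable))
            row[f"{lid}_count"] = cell["count"]
            row[f"{lid}_denominator"] = cell["denominator"]
            row[f"{lid}_percentage"] = cell["percentage"]
        for group, col in (
            ("breastfeeding", "group_breastfeeding"),
            ("claims", "group_claims"),
            ("clarity", "group_clarity"),
        ):
            n_pass = g[col].astype(bool).sum()
            row[f"{group}_count"] = int(n_pass)
            row[f"{group}_denominator"] = len(g)
            row[f"{group}_percentage"] = format_percentage(int(n_pass), len(g))
        met_all = g["labelling_pass"].astype(bool).sum()
        row.update(
            met_all_count=int(met_all),
            met_all_denominator=len(g),
            met_all_percentage=format_percentage(int(met_all), len(g)),
        )
        rows.append(row)
    return pd.DataFrame(rows)


class ChiSquareResult(BaseModel):
    """Pearson χ² (no continuity correction) on a 2×2 pass/fail table."""

    table: list[list[int]]  # rows: national, international; cols: pass, fail
    statistic: float
    dof: int
    p_value: float
    n_excluded_unknown: int = 0


def compare_origin(assessments: pd.DataFrame) -> ChiSquareResult:
    """χ² comparison of composition pass rates: national vs international.

    Products of unknown origin are excluded (their count is reported).
    Raises on a degenerate table (any zero marginal).
    """
    assessed = assessments[~assessments["auto_failed"].astype(bool)]
    known = assessed[assessed["manufacturer_origin"].isin(["national", "international"])]
    n_excluded = len(assessed) - len(known)
    table = []
    for origin in ("national", "international"):
        g = known[known["manufacturer_origin"] == origin]
        n_pass = int(g["nutrient_pass"].astype(bool).sum())
        table.append([n_pass, len(g) - n_pass])
    arr = np.array(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate 2x2 table (zero marginal): {table}")
    res = chi2_contingency(arr, correction=False)
    return ChiSquareResult(
        table=table,
        statistic=float(res.statistic),
        dof=int(res.dof),
        p_value=float(res.pvalue),
        n_excluded_unknown=n_excluded,
    )


def chi_square_from_counts(
    pass_a: int, total_a: int, pass_b: int, total_b: int
) -> ChiSquareResult:
    """Pearson χ² directly from two pass/total count pairs."""
    arr = np.array([[pass_a, total_a - pass_a], [pass_b, total_b - pass_b]])
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate 2x2 table (zero marginal): {arr.tolist()}")
    res = chi2_contingency(arr, correction=False)
    return ChiSquareResult(
        table=arr.tolist(), statistic=float(res.statistic), dof=int(res.dof),
        p_value=float(res.pvalue),
    )
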