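# products.csv column dictionary

One row per unique product; UTF-8, comma-separated. Empty cells mean
*absent from the label* — never zero or false. A JSON mirror
(`write_product_json` / `read_product_json`) uses the same field names in
nested form.

## Identity

| column | type | notes |
| --- | --- | --- |
| `product_id` | string | unique within a dataset after dedup |
| `country` | string | ISO-3166-like code (study countries: KH ID LA MY PH TH VN) |
| `brand` | string | mandatory |
| `subbrand` | string | optional |
| `descriptive_name` | string | product name as printed |
| `flavour` | string | optional |
| `manufacturer` | string | optional |
| `manufacturer_origin` | enum | `national` / `international` / `unknown` |

## Age and coded label flags (tri-state: `true` / `false` / empty = not coded)

| column | meaning |
| --- | --- |
| `age_statement_months` | minimum recommended age printed on the label (integer months) |
| `marketed_under_6mo` | text/visual marketing toward children < 6 months |
| `has_bf_continuation_message` | message on continued breastfeeding to 2 years+ |
| `suggests_bm_superiority` | suggests superiority/equivalence to breast milk |
| `promotes_bottle_feeding` | recommends/promotes bottle feeding (incl. bottle imagery) |
| `has_child_image` | image of a child appearing under 3 years |

## Categorization hints (optional; authoritative when present)

| column | values |
| --- | --- |
| `category_hint` | `dry_cereal`, `soft_wet_spoonable`, `wet_meal_chunky`, `dry_finger_food_snack`, `juice_drink`, `other_cpcf` |
| `subcategory_hint` | `confectionery_sweet_spreads_fruit_chews`, `fruit_fresh_or_dry`, `other_snacks_finger_foods` |

## Nutrient declaration

`serving_size_g` plus two column blocks, `*_100g` (per 100 g) and `*_serv`
(per serving), each with: `energy_kcal`, `energy_kj`, `total_sugar_g`,
`sodium_mg`, `salt_g`, `total_fat_g`, `saturated_fat_g`. Declare whichever
basis the label prints; per-serving values require `serving_size_g` to be
usable.

## Structured cells

* `ingredients` — ordered, `"; "`-separated entries in descending content
  order as printed: `name (PCT%) [fruit|nonfruit]`, percentage and fruit
  marker optional, e.g. `apple (30%) [fruit]; rice flour; glucose syrup`.
* `claims` — `" | "`-separated: `category::text`, `category::` (pre-coded,
  no text) or bare `text` (to be classified). Categories:
  `nonpermitted_compositional`, `nutrient_content`, `nutrient_function`,
  `disease_risk_reduction`, `other`.
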