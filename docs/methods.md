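# Methods

## The model

`cpcf_npm` implements an adapted nutrient-profiling model (NPM) for
commercially produced complementary foods (CPCF) in the *dry finger
foods/snacks* category — packaged snack products marketed as suitable for
children under 36 months. The model is a rule system, not a fitted model:
every product receives a deterministic verdict against

**Four nutrient-composition requirements**

1. *No added sugar/sweetener.* An ingredient-list scan against an editable
   lexicon of mono-/disaccharides, syrups, nectars, honey, fruit juices and
   concentrated/powdered fruit juice (lemon/lime juice excepted), and
   nonsugar sweeteners (intense sweeteners and polyols). Matching is
   case-insensitive at token boundaries; a match anywhere in the ordered
   ingredient list fails the requirement. Maltodextrin is deliberately not
   in the default lexicon (it falls outside this model's added-sugar
   definition); the file is plain text and editable.
2. *Total sugar < 15% of energy.* Percent energy from sugar uses the Atwater
   factor 4 kcal/g: `sugar_g/100g × 4 / kcal/100g × 100`. Equivalently the
   ceiling is 3.75 g sugar per 100 kcal. Not applicable to the
   "fruit (fresh or dry)" subcategory.
3. *Sodium < 50 mg/100 kcal AND < 50 mg/100 g.* A conjunction; both limbs
   must hold. Where only salt is declared, sodium = salt / 2.5.
4. *Total fat ≤ 4.5 g/100 kcal* (Atwater 9 kcal/g for the %-energy view).

Inequality strictness is exactly as written — strict for the sugar-energy
rule and both sodium limbs, non-strict for fat — and comparisons are made on
exact declared values with no prior rounding. Products in the
"confectionery, sweet spreads and fruit chews" subcategory automatically
fail the whole model and are excluded from the labelling assessment and the
aggregate assessment tables.

**Twelve labelling requirements** in three groups: protection and promotion
of breastfeeding (L1 minimum age ≥ 6 months displayed; L2 not marketed under
6 months; L3 breastfeeding-continuation message present; L4 no breast-milk
superiority/equivalence suggestion; L5 no bottle-feeding promotion), claims
(L6–L10: none of the five claim categories present), and name/ingredient
clarity (L11 product name reflects ingredients in descending order; L12
fruit percentages stated, applicable only to fruit-containing products).

**Missing-information semantics.** Missing label information needed by a
requirement fails that requirement. Every coded flag is therefore tri-state
(true / false / absent). The asymmetry among the breastfeeding requirements
is intentional: L1 and L3 demand content *present* on the label, so absence
fails them; L2/L4/L5 prohibit a practice, so an uncoded flag passes. This
matches the observed pattern of near-universal passes on the prohibition
items and failure-by-absence on the message item. `not_applicable` verdicts
never pass or fail a product and never block a group subtotal.

## Categorization

CPCF status requires at least one of four criteria: printed introduction age
below 36 months; a baby/infant/toddler text marker; a young-child image
(coded flag); any other presentation of under-3 suitability (bottle imagery
counts here). Category (six NPM categories) and finger-food subcategory
(confectionery / fruit / other snacks) assignment treats a pre-coded hint as
authoritative — mirroring the original human-coder protocol — with a
versioned, editable keyword rule file as the fallback. When no rule fires
the engine raises a needs-manual-coding error rather than guessing, because
a silent misclassification would corrupt every downstream verdict. Single-
ingredient all-fruit products are recognized as "fruit (fresh or dry)"
directly from the ingredient list.

Name-order checking for L11 (the written rule names no algorithm) uses
longest-first, case-insensitive containment of ingredient names in the
product name, with non-overlapping spans; a name mentioning no listed
ingredient passes vacuously.

Claim classification (when a claim text carries no pre-coded category) uses
per-category regex lists applied in a fixed precedence order
(disease-risk-reduction > nutrient-function > nutrient-content >
nonpermitted-compositional > other), seeded from the protocol's quoted
example claims. It is deliberately conservative: unmatched texts are
retained for manual coding and block nothing. Pre-coded categories always
win.

## Normalization and unit conversions

Per-100 g declared values take precedence; per-serving values are rescaled
by 100/serving size (a per-serving declaration without a serving size
degrades to absent, with a warning). Energy declared only in kJ converts at
4.184 kJ/kcal — common on Southeast-Asian labels. Declared sodium wins over
salt-derived sodium when both appear. Every converted field carries a
provenance flag (`declared`, `converted_from_salt`, `converted_from_serving`,
`converted_from_kj`).

## Reporting conventions

Percentages are rounded half-away-from-zero to one decimal and always
computed through one function; every table cell carries its count and
denominator because applicability varies (the sugar-energy denominator
excludes fruit products; the fruit-percentage denominator covers only
products where the rule applies; nutrient-content medians exclude products
without the relevant declaration). Medians of even-sized samples are the
mean of the middle two; quartiles use linear interpolation. The
manufacturer-origin comparison is a Pearson χ² on the 2×2 pass/fail ×
national/international table, no continuity correction, df = 1; unknown
origins are excluded and counted. Source tables of this kind are sometimes
internally inconsistent in their printed rounding; this package fixes one
convention and never chases individual printed cells.

## The synthetic market generator

The study's per-product dataset is not deposited, so `cpcf_npm.synthetic`
generates markets with the statistical structure the analysis assumes and a
known ground truth. The default preset is study-scale: 606 products across
seven country codes; subcategory mix 50/606 confectionery, 8/606 fruit;
added-sugar prevalence 0.723; log-normal nutrient contents (non-negative,
right-skewed, matching the published median ≪ upper-IQR pattern) with
medians near the published overall medians — sugar 12.4 g, sodium 71 mg,
fat 2.7 g, saturated fat 0.3 g per 100 g, energy 430 kcal/100 g (a typical
dry-snack energy density) — and log-sigmas chosen from the published IQR
ratios (0.4, 1.1, 2.0, 1.3, 1.2 respectively); per-nutrient missingness from
the published per-nutrient declaration counts; claim and labelling-flag
rates from the published overall labelling proportions. These presets are
calibration conveniences, not claims about any real market.

Ground truth is computed by `cpcf_npm.reference`, a deliberately plain
straight-line transcription of the rules applied to the finished records —
never by the engine under test — so pipeline-vs-truth agreement is a real
dual-route check. `expected_rates` gives analytic per-requirement pass rates:
thresholds on a log-normal ratio reduce to a normal CDF, the two-limb sodium
rule to a bivariate normal CDF, and the labelling requirements to Bernoulli
algebra; a `gamma` nutrient family has no closed form and falls back to
Monte Carlo (10⁵ replicates, with a warning). Applicability-restricted rates
(sugar-energy, fruit percentage) are conditional on applicability.

**What the generator does not emulate.** Declared values are exact reals
(real labels round); nutrient values are mutually independent given the
subcategory (real sugar/sodium/fat co-vary by product type) and fruit
products share the snack distributions; names and ingredient lists come from
a controlled vocabulary; every product carries a unique synthetic subbrand
token, so generated markets contain no duplicate products (dedup is
exercised on constructed duplicates in the unit tests); and requirement
verdicts are independent across requirements, which makes the synthetic
"met all requirements" share smaller than a real market's, where failures
cluster. Passing the recovery tests therefore demonstrates that the engine
implements the rules exactly and that aggregation is correct — not that any
particular real market would show these rates.

## Problem sizes and numerical choices

The oracle-equivalence suite runs on 1200 generated products including
missing-value patterns; the recovery/convergence check on 5000 products with
a 3-standard-error band per requirement; the acceptance script on the
study-scale 606-product preset. All randomness flows from a single seed
through `numpy.random.default_rng`; identical config and seed give
byte-identical serialized output. The double-entry error check passes only
when the mismatch rate is strictly below the threshold (default 5%), and the
compared field set is configurable because the original protocol does not
publish one. Dedup normalizes case and whitespace before comparing the
six identity fields; package size and type never enter the uniqueness key.

## Known limitations

Keyword categorization and claim lexicons are seeded from a small set of
quoted examples and are intentionally incomplete; borderline physical forms
(e.g. soft fruit bars) need a hint or an extended rule file. Declared
nutrient values are taken at face value — verifying label accuracy by
laboratory analysis is out of scope, as in the original protocol. The claim
texts on real labels are multilingual; this package assumes pre-translated
or pre-coded input.
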