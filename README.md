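# cpcf-npm

Rule engine and reporting pipeline for assessing **commercially produced
complementary food (CPCF) finger foods/snacks** — packaged snacks marketed
for children under 36 months — against an adapted nutrient-profiling model
(NPM): four nutrient-composition requirements and twelve labelling
requirements, as used to benchmark baby-snack markets.

It is written for public-health and nutrition researchers auditing product
labels: you supply (or simulate) a table of label data — one row per unique
product, with nutrient declarations, ordered ingredient list, claims and
coded label flags — and the pipeline returns per-product verdicts plus the
survey-style aggregate tables (subcategory distribution, requirement pass
proportions with correct applicability denominators, nutrient-content
medians/IQRs, and a national-vs-international manufacturer χ² comparison).

## The model in brief

A dry finger food/snack passes the **composition** assessment iff all
applicable requirements hold:

| requirement | rule |
| --- | --- |
| no added sugar/sweetener | no ingredient matches the added-sugar lexicon (lemon/lime juice exempt) |
| total sugar | sugar energy share `4·S/E` < 15% (≡ 3.75 g/100 kcal); fruit subcategory exempt |
| sodium | Na < 50 mg/100 kcal **and** < 50 mg/100 g (salt/2.5 when only salt declared) |
| total fat | F·100/E ≤ 4.5 g/100 kcal |

with S, F in g/100 g, Na in mg/100 g, E in kcal/100 g (Atwater 4 and
9 kcal/g). Confectionery/sweet spreads/fruit chews auto-fail. Missing label
information needed by a requirement fails that requirement. The twelve
labelling requirements cover breastfeeding protection (L1–L5), claims
(L6–L10) and name/ingredient clarity (L11–L12); see `docs/methods.md`.

## Worked example

```python
from cpcf_npm import MarketConfig, generate_market, assess_products
from cpcf_npm.report import summarize_nutrient_performance

records, truth = generate_market(MarketConfig(n_products=606, seed=1))
result = assess_products(records, dedup=False)
print(result.stage_counts)
assessed = result.assessments[~result.assessments.auto_failed]
row = summarize_nutrient_performance(assessed).set_index("stratum").loc["All products"]
print(f"met all four composition requirements: "
      f"{row.met_all_percentage}% (n={int(row.met_all_count)}/{int(row.met_all_denominator)})")
print(f"met sodium requirement: {row.sodium_limit_percentage}%")
```

prints

```
{'input': 606, 'after_dedup': 606, 'cpcf_identified': 606, 'finger_foods_identified': 606, 'confectionery_auto_fail': 63, 'assessed': 543}
met all four composition requirements: 6.4% (n=35/543)
met sodium requirement: 43.6%
```

i.e. of 606 simulated finger foods, 63 are confectionery and auto-fail; of
the 543 assessed, 43.6% meet the two-limb sodium rule and only 6.4% meet all
four composition requirements (the generator draws requirements
independently, so its met-all share is lower than a real market's, where
failures cluster). `truth` carries ground-truth verdicts computed by an
independent straight-line rule transcription, plus analytic expected pass
rates — the basis of the package's recovery tests.

The same pipeline runs from the shell:

```bash
cpcf-npm simulate --seed 1 --n 606 --out market/
cpcf-npm profile --input market/products.csv --out results/
cpcf-npm reconcile --a entry_a.csv --b entry_b.csv --threshold 0.05
```

`profile` writes `assessments.csv` (one row per product, one column per
requirement verdict), the four aggregate tables, and a run log with the
flowchart stage counts. The input dialect is documented in
`docs/column_dictionary.md`.

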