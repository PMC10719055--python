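# Keyword fallback rules for NPM category and finger-food subcategory
# assignment.  The pre-coded hint on a record is always authoritative; these
# rules only fire when no hint is present.  One rule per line,
# "regex => value"; rules are tried top to bottom, first match wins; patterns
# are matched case-insensitively against the product's descriptive name (and
# brand/flavour text).  Edit freely — unmatched products raise a
# needs-manual-coding error rather than being guessed.

[category]
# other CPCF: condiments, powders, seasonings, flosses
\b(seasoning|floss|condiment|sprinkle)s?\b => other_cpcf
\bpowder\b => other_cpcf
# dry cereals / starchy instant foods
\b(porridge|cereal|oatmeal|muesli)\b => dry_cereal
\binstant (rice|noodle)s?\b => dry_cereal
# soft-wet spoonable ready-to-eat
\b(puree|purée|pouch|spoonable|yoghurt|yogurt|custard|dessert)\b => soft_wet_spoonable
# wet meals with chunky pieces
\bchunky\b => wet_meal_chunky
\bmeal with (chunks|pieces)\b => wet_meal_chunky
# juices and other drinks
\b(juice|drink|water|tea|smoothie)\b => juice_drink
# dry finger foods and snacks
\b(puff|rusk|biscuit|cookie|cracker|crisp|chip|melt|wafer|bite|stick|teether|snack|bar)s?\b => dry_finger_food_snack
\brice cakes?\b => dry_finger_food_snack
\b(candy|candies|lollipop|marshmallow|gummy|gummies|chew)s?\b => dry_finger_food_snack
\b(sweet|chocolate|fruit) spread\b => dry_finger_food_snack
\b(freeze[- ]dried|dried) (fruit|apple|banana|mango|strawberry|pear|pineapple)\b => dry_finger_food_snack
\braisins?\b => dry_finger_food_snack

[subcategory]
# confectionery, sweet spreads and fruit chews (automatic NPM failure)
\b(candy|candies|lollipop|marshmallow|gummy|gummies)\b => confectionery_sweet_spreads_fruit_chews
\b(fruit )?chews?\b => confectionery_sweet_spreads_fruit_chews
\b(sweet|chocolate|fruit) spread\b => confectionery_sweet_spreads_fruit_chews
\bjam\b => confectionery_sweet_spreads_fruit_chews
# fruit (fresh or dry)
\b(freeze[- ]dried|dried) (fruit|apple|banana|mango|strawberry|pear|pineapple)\b => fruit_fresh_or_dry
\braisins?\b => fruit_fresh_or_dry
\bfresh fruit\b => fruit_fresh_or_dry
# anything else in the category: biscuits, rusks, chips/crisps, rice cakes, etc.
.* => other_snacks_finger_foods
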