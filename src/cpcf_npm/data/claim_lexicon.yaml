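# Claim classification lexicon: regex pattern lists per claim category.
# Patterns are matched case-insensitively against the claim text.  Categories
# are tried in the precedence order below; the first category with a firing
# pattern wins.  A text firing no pattern stays uncategorized and is retained
# for manual coding.
#
# Seeded from the quoted example claims of the assessment protocol; the full
# claim taxonomy used by trained coders is broader, so this default list is
# deliberately conservative and meant to be extended.

precedence:
  - disease_risk_reduction
  - nutrient_function
  - nutrient_content
  - nonpermitted_compositional
  - other

patterns:
  disease_risk_reduction:
    - 'reduc\w* (the )?risk'
    - '\bprevent\w*\b.*\b(caries|anemia|anaemia|rickets|disease|infection)'
    - 'protect\w* against'
  nutrient_function:
    - '\bsupports?\b'
    - 'helps? (to )?(support|develop|build|strengthen|grow)'
    - 'for (healthy )?(brain|bone|eye|muscle|immune|gut) (development|health|growth|function)'
    - 'aids? digestion'
    - 'growth and development'
    - 'immun(e|ity)'
  nutrient_content:
    - 'source of'
    - '(high|rich|low) in'
    - 'contains? \w* ?(iron|calcium|zinc|dha|protein|fibre|fiber|vitamin)'
    - 'essential (vitamins|minerals|nutrients)'
    - 'with added (iron|calcium|zinc|dha|vitamins?)'
    - 'fortified'
    - '\bvitamins? [a-z]?[0-9]{0,2}\b'
    - '\bcalcium\b|\biron\b|\bdha\b|\bomega.?3\b'
  nonpermitted_compositional:
    - 'no added'
    - '\bno (preservative|colouring|coloring|colour|color|artificial|msg|flavouring|flavoring)s?\b'
    - '(free (of|from)|without) (added )?(sugar|salt|preservative|gluten)s?'
    - '100% natural'
    - '\bnatural\b'
    - '\borganic\b'
    - 'unsweetened'
  other:
    - 'easy to (grasp|hold|chew|eat)'
    - 'dissolv\w+'
    - 'melts? (in|easily)'
    - 'self.?feeding'
    - 'little (hands|fingers)'
    - 'perfect (for|size)'
    - 'convenient|on.the.go|handy'
    - 'first (snack|finger food)'
    - 'texture'
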