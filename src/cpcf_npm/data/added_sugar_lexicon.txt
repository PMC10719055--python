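# Added sugar / sweetener ingredient lexicon.
#
# An ingredient triggers the "no added sugar/sweetener" failure when any term
# below matches at a token boundary (case-insensitive) inside the ingredient
# name, unless the match lies inside one of the [exceptions] phrases
# (lemon/lime juice never counts as an added sugar).
#
# Terms cover mono- and disaccharides, syrups, nectars, honey, fruit juices
# and concentrated/powdered fruit juice, plus nonsugar sweeteners (intense
# sweeteners and polyols).  Maltodextrin is deliberately NOT listed — it is
# outside this model's added-sugar definition.  Edit freely; this file is the
# single source of truth for the matcher.

sugar
juice
sucrose
dextrose
fructose
glucose
maltose
galactose
trehalose
syrup
nectar
honey
malted barley
malt extract
molasses

# nonsugar sweeteners
sweetener
aspartame
sucralose
saccharin
stevia
steviol glycosides
acesulfame
cyclamate
neotame
advantame
thaumatin
sorbitol
xylitol
maltitol
mannitol
isomalt
lactitol
erythritol

[exceptions]
lemon juice
lime juice
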