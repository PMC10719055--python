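product_id,country,brand,descriptive_name,flavour,manufacturer_origin,age_statement_months,serving_size_g,energy_kcal_100g,total_sugar_g_100g,salt_g_100g,ingredients
P1,KH,TinyBites,Baby Apple Puffs,Apple,national,8,,450,10,,apple (30%) [fruit]; rice flour
P2,TH,SnackSprout,Toddler Rusks,,international,12,25,430,,1.0,wheat flour; glucose syrup
P3,MY,GrowWell,Baby Rice Cakes,,unknown,6,,380,2.5,,rice flour
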