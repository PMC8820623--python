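nutrient,rni
protein_g,46
vitamin_a_ug,500
vitamin_e_mg,7.5
thiamin_mg,1.1
riboflavin_mg,1.1
niacin_mg,14
pantothenic_acid_mg,5
folate_ug,400
vitamin_b12_ug,2.4
vitamin_c_mg,45
calcium_mg,1000
copper_mg,1.15
iron_mg,19.6
magnesium_mg,220
potassium_mg,3510
sodium_mg,2000
zinc_mg,4.9
vitamin_b6_mg,1.3
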