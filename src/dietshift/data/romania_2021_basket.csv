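name,consumption_kg_per_capita_year,protein_g_per_100g,land_m2_per_100g_protein
Poultry,22.21,17.1,7.06
Beef,5.05,18.5,163.60
Sheep and goat,2.8,14,184.81
Pig meat,36.9,11,10.73
Meat other,0.19,16.1,7.06
Fish and seafood,8.09,10.9,3.69
Eggs,12.84,10.7,5.65
Milk,599.32,3.3,27.12
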