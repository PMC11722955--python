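name,weight,land_m2_per_100g_protein
Soy,0.5,2.2
Peas,0.3,3.36
Potatoes,0.2,5.18
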