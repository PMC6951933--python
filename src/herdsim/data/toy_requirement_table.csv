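nutrient,maintenance_per_kg_bw,per_kg_milk
nutrient_0,0.00555,0.0628
nutrient_1,0.00382,0.2155
nutrient_2,0.00644,0.1763
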