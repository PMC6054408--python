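species,mean_kg,se_kg,n
clouded_leopard_males,24.4,0.8,5
clouded_leopard_females,12.5,3.2,4
bay_cat,2.8,0.6,3
marbled_cat,2.4,0.0,2
leopard_cat,2.1,0.4,19
flat_headed_cat,1.9,0.3,4
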