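area,species,count,frequency
danum_valley,clouded_leopard_pooled,100,1.032
danum_valley,clouded_leopard_males,90,0.928
danum_valley,clouded_leopard_females,10,0.103
danum_valley,leopard_cat,39,0.402
danum_valley,bay_cat,11,0.113
danum_valley,marbled_cat,42,0.433
danum_valley,flat_headed_cat,1,0.010
tawau,clouded_leopard_pooled,339,0.969
tawau,clouded_leopard_males,302,0.863
tawau,clouded_leopard_females,37,0.106
tawau,leopard_cat,128,0.366
tawau,bay_cat,42,0.120
tawau,marbled_cat,88,0.251
tawau,flat_headed_cat,0,
crocker_range,clouded_leopard_pooled,51,1.256
crocker_range,clouded_leopard_males,46,1.133
crocker_range,clouded_leopard_females,5,0.123
crocker_range,leopard_cat,28,0.690
crocker_range,bay_cat,0,
crocker_range,marbled_cat,11,0.271
crocker_range,flat_headed_cat,0,
tabin,clouded_leopard_pooled,41,0.634
tabin,clouded_leopard_males,36,0.557
tabin,clouded_leopard_females,5,0.077
tabin,leopard_cat,191,2.956
tabin,bay_cat,3,0.046
tabin,marbled_cat,42,0.650
tabin,flat_headed_cat,0,
ulu_segama,clouded_leopard_pooled,83,2.915
ulu_segama,clouded_leopard_males,71,2.494
ulu_segama,clouded_leopard_females,12,0.421
ulu_segama,leopard_cat,494,17.352
ulu_segama,bay_cat,2,0.070
ulu_segama,marbled_cat,7,0.246
ulu_segama,flat_headed_cat,0,
malua,clouded_leopard_pooled,11,0.284
malua,clouded_leopard_males,8,0.207
malua,clouded_leopard_females,3,0.078
malua,leopard_cat,272,7.032
malua,bay_cat,3,0.078
malua,marbled_cat,5,0.129
malua,flat_headed_cat,0,
kinabatangan,clouded_leopard_pooled,15,0.730
kinabatangan,clouded_leopard_males,8,0.389
kinabatangan,clouded_leopard_females,7,0.341
kinabatangan,leopard_cat,21,1.022
kinabatangan,bay_cat,0,
kinabatangan,marbled_cat,5,0.243
kinabatangan,flat_headed_cat,3,0.146
kabili_sepilok,clouded_leopard_pooled,0,
kabili_sepilok,clouded_leopard_males,0,
kabili_sepilok,clouded_leopard_females,0,
kabili_sepilok,leopard_cat,12,0.276
kabili_sepilok,bay_cat,0,
kabili_sepilok,marbled_cat,0,0
kabili_sepilok,flat_headed_cat,0,
danum_palm,clouded_leopard_pooled,0,
danum_palm,clouded_leopard_males,0,
danum_palm,clouded_leopard_females,0,
danum_palm,leopard_cat,624,28.210
danum_palm,bay_cat,0,
danum_palm,marbled_cat,5,0.226
danum_palm,flat_headed_cat,0,
minat_teguh,clouded_leopard_pooled,0,
minat_teguh,clouded_leopard_males,0,
minat_teguh,clouded_leopard_females,0,
minat_teguh,leopard_cat,164,8.367
minat_teguh,bay_cat,0,
minat_teguh,marbled_cat,0,0
minat_teguh,flat_headed_cat,0,
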