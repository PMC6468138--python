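# study_area: DHR
# season: summer
# n_scats: 41
food_id,category,rf_pct
Yeiselu,Buds and twigs,3.2
Nigalo,Bamboo,34.6
Chutro,Buds and twigs,7.9
Jhayu,Lichen,5.6
Ants,Insect,3.3
Paskate,Leaf,3.1
Kharsu seed,Hard mast,5.6
Banko seed,Soft mast,11.8
Maize seed,Crop,12.8
Fern,Fern,10.5
Unidentified,,1.6
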