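# study_area: DHR
# season: autumn
# n_scats: 32
food_id,category,rf_pct
Yeiselu,Buds and twigs,7.5
Nigalo,Bamboo,30.2
Chutro,Buds and twigs,12.5
Jhayu,Lichen,13.3
Kharsu leaf,Leaf,6.7
Guransh,Leaf,17.0
Ants,Insect,4.3
Termites,Insect,3.1
Unidentified,,5.4
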