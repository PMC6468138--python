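# study_area: KSL
# season: autumn
# n_scats: 59
food_id,category,rf_pct
Chutro,Buds and twigs,3.3
Nigalo,Bamboo,21.5
Khanyu seed,Soft mast,7.2
Ghamari,Leaf,7.9
Banjh,Hard mast,8.6
Fern,Fern,15.9
Yeiselu,Buds and twigs,7.8
Guransh,Leaf,13.0
Jhayu,Lichen,9.4
Unidentified,,5.4
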