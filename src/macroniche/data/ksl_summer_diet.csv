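# study_area: KSL
# season: summer
# n_scats: 77
food_id,category,rf_pct
Chutro,Buds and twigs,2.3
Nigalo,Bamboo,24.2
Khanyu seed,Soft mast,3.4
Ghamari,Leaf,5.2
Banjh,Hard mast,7.1
Fern,Fern,9.2
Yeiselu,Buds and twigs,3.4
Banko seed,Soft mast,9.5
Kodo millet,Crop,9.8
Wild pear seed,Soft mast,13.2
Maize seed,Crop,10.2
Unidentified,,2.5
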