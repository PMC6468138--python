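food_id,species,study_area,season,ash_pct,crude_protein_pct,ether_extract_pct,moisture_pct,crude_fiber_pct,available_carbohydrate_pct,note
Yeiselu,Rubus ellipticus,DHR,autumn,9.34,12.17,1.75,12.65,28.17,35.92,
Nigalo,Arundinaria spp.,DHR,autumn,9.10,12.44,1.18,12.04,25.06,40.18,literature composite
Chutro,Berberis aristata,DHR,autumn,5.48,17.86,2.33,9.97,20.13,44.23,literature composite
Jhayu,Lichen,DHR,autumn,5.72,8.94,1.61,14.06,22.24,47.43,literature composite
Kharsu leaf,Quercus semicarpifolia,DHR,autumn,9.97,15.27,3.41,9.21,26.73,35.40,
Guransh,Rhododendron spp.,DHR,autumn,10.23,7.82,2.85,12.13,11.72,55.25,
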