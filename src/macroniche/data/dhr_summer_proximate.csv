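food_id,species,study_area,season,ash_pct,crude_protein_pct,ether_extract_pct,moisture_pct,crude_fiber_pct,available_carbohydrate_pct,note
Yeiselu,Rubus ellipticus,DHR,summer,8.96,12.12,2.71,11.00,22.58,42.62,
Nigalo,Arundinaria spp.,DHR,summer,22.00,20.31,1.66,8.45,22.10,25.48,
Chutro,Berberis aristata,DHR,summer,6.50,18.66,4.33,9.5,21.01,40.00,literature composite
Jhayu,Lichen,DHR,summer,6.20,8.00,2.96,10.90,19.01,52.93,literature composite
Paskate,unknown,DHR,summer,9.76,11.23,1.73,9.91,23.95,43.41,
Kharsu seed,Quercus semicarpifolia,DHR,summer,7.98,4.98,0.90,7.98,9.89,68.28,
Banko seed,Arisaema tortuosum var. curvatum,DHR,summer,8.78,7.12,0.50,7.70,6.90,69.00,
Maize seed,Zea mays,DHR,summer,3.65,8.05,2.82,7.58,2.44,75.46,
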