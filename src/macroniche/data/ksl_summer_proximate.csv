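food_id,species,study_area,season,ash_pct,crude_protein_pct,ether_extract_pct,moisture_pct,crude_fiber_pct,available_carbohydrate_pct,note
Chutro,Berberis aristata,KSL,summer,3.56,9.21,2.23,8.90,44.33,31.77,
Nigalo,Arundinaria spp.,KSL,summer,10.54,8.24,1.40,9.08,45.87,24.87,
Khanyu seed,Ficus semicordata,KSL,summer,12.87,6.99,1.45,8.98,24.16,45.55,
Ghamari,unknown sp.,KSL,summer,10.84,16.03,6.09,9.95,12.66,44.43,
Banjh,Quercus incana,KSL,summer,8.98,9.32,0.37,7.71,38.23,35.40,
Fern,Matteuccia struthiopteris,KSL,summer,6.97,8.00,2.09,8.70,36.17,38.07,
Yeiselu,Rubus ellipticus,KSL,summer,8.56,10.07,2.31,10.13,25.43,43.50,
Banko seed,Arisaema tortuosum var. curvatum,KSL,summer,9.12,11.59,8.90,8.97,9.40,52.01,
Kodo millet,Paspalum scrobiculatum,KSL,summer,9.21,7.02,0.18,14.32,35.18,34.08,
Wild pear seed,Pyrus pyraster,KSL,summer,12.15,3.69,0.12,10.93,41.34,31.78,
Maize seed,Zea mays,KSL,summer,3.65,8.05,2.82,7.90,2.53,75.05,
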