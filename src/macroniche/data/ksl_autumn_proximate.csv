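food_id,species,study_area,season,ash_pct,crude_protein_pct,ether_extract_pct,moisture_pct,crude_fiber_pct,available_carbohydrate_pct,note
Chutro,Berberis aristata,KSL,autumn,6.87,11.64,2.76,9.93,20.51,48.29,
Nigalo,Arundinaria spp.,KSL,autumn,9.45,9.65,3.15,13.10,34.72,29.93,
Khanyu seed,Ficus semicordata,KSL,autumn,11.98,10.58,0.15,8.81,30.28,38.19,
Ghamari,unknown sp.,KSL,autumn,11.87,7.63,3.32,10.78,21.44,44.96,
Banjh,Quercus incana,KSL,autumn,9.87,14.17,3.41,8.19,41.52,22.83,
Fern,Matteuccia struthiopteris,KSL,autumn,7.95,11.11,1.99,8.89,35.25,34.82,
Yeiselu,Rubus ellipticus,KSL,autumn,7.09,11.40,1.72,11.06,20.52,48.21,
Guransh,Rhododendron spp.,KSL,autumn,10.23,7.82,2.85,12.13,10.19,56.78,
Jhayu,Lichen,KSL,autumn,6.73,7.38,3.09,13.35,31.19,38.26,
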