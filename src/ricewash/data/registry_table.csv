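pesticide,linear_low_ug_L,linear_high_ug_L,r2_matrix,loq_ug_kg,rsd_R_pct,rsd_r_pct,recovery_pct,expanded_uncertainty_pct
Acetamiprid,10.0,100.0,0.9917,10.0,8.34,7.36,113.5,12.0
Azoxystrobin,10.0,100.0,0.9834,10.0,13.9,7.02,91.82,39.0
Bitertanol,10.0,100.0,0.9848,10.0,13.1,13.6,102.8,19.0
Bixafen,10.0,100.0,0.983,10.0,11.0,6.16,80.4,30.0
Boscalid,5.0,100.0,0.9874,5.0,11.4,7.5,81.25,29.0
Bupirimate,10.0,100.0,0.9786,10.0,8.48,6.79,98.89,12.0
Buprofezin,10.0,100.0,0.9774,10.0,15.5,6.98,90.69,49.0
Cadusafos,5.0,100.0,0.9885,5.0,12.9,7.01,94.5,36.0
Carbaryl,10.0,100.0,0.9868,10.0,10.6,6.21,103.5,26.0
Carbendazim,10.0,100.0,0.9747,10.0,16.3,14.6,70.02,32.0
Carbofuran,10.0,100.0,0.983,10.0,8.03,6.38,107.9,13.0
Carbofuran-3-hydroxy,10.0,100.0,0.983,10.0,17.0,10.9,103.7,43.0
Carboxin,10.0,100.0,0.9841,10.0,7.7,6.37,103.2,10.0
Chlorantraniliprole,10.0,100.0,0.9819,10.0,8.1,6.81,109.1,13.0
Chlorfenvinphos,10.0,100.0,0.981,10.0,12.3,6.34,82.1,35.0
Chlorpyrifos-methyl,10.0,100.0,0.9958,10.0,15.2,7.07,92.22,38.0
Clofentezine,10.0,100.0,0.9831,10.0,9.13,5.9,83.99,20.0
Coumaphos,50.0,100.0,0.972,50.0,14.4,8.86,80.9,31.0
Cymoxanil,10.0,100.0,0.9983,10.0,13.4,12.31,104.1,22.0
Cyproconazole,10.0,100.0,0.9782,10.0,8.23,6.17,117.1,14.0
Cyprodinil,10.0,100.0,0.9809,10.0,9.84,5.89,89.96,25.0
Demeton-*S*-methylsulfone,10.0,100.0,0.98,10.0,15.9,11.3,103.8,39.0
Diazinon,10.0,100.0,0.9854,10.0,8.93,5.23,101.4,23.0
Dichlorvos,10.0,100.0,0.9825,10.0,11.3,7.41,105.7,31.0
Difenoconazole,10.0,100.0,0.9756,10.0,13.5,7.48,100.7,39.0
Diflubenzuron,10.0,100.0,0.9814,10.0,11.6,6.67,85.69,29.0
Dimethoate,5.0,100.0,0.9874,5.0,12.4,9.72,102.9,32.0
Dimethomorph,10.0,100.0,0.9768,10.0,12.1,6.96,99.78,26.0
Diniconazole,10.0,100.0,0.981,10.0,12.6,7.49,106.8,38.0
DMST,10.0,100.0,0.9842,10.0,10.2,6.51,101.1,28.0
EPN,10.0,100.0,0.9766,10.0,8.49,6.99,89.67,9.0
Epoxiconazole,10.0,100.0,0.9759,10.0,10.4,7.37,110.0,19.0
Ethiofencarb,10.0,100.0,0.9864,10.0,8.54,6.48,110.4,17.0
Ethoprophos,5.0,100.0,0.9857,5.0,12.9,6.26,91.34,37.0
Etrimfos,50.0,100.0,0.9767,50.0,8.08,6.97,90.23,15.0
Fenamidone,10.0,100.0,0.9774,10.0,10.4,7.06,109.8,25.0
Fenamiphos sulfone,5.0,100.0,0.988,5.0,7.02,6.31,94.75,12.0
Fenamiphos sulfoxide,10.0,100.0,0.9809,10.0,7.12,5.5,100.4,8.0
Fenarimol,10.0,100.0,0.975,10.0,10.2,7.66,96.38,23.0
Fenitrothion,10.0,100.0,0.9759,10.0,14.6,9.55,96.56,32.0
Fenoxycarb,10.0,100.0,0.9777,10.0,13.6,6.17,109.5,39.0
Fenpropathrin,10.0,100.0,0.975,10.0,9.19,3.56,78.34,20.0
Fenpropidin,5.0,100.0,0.9839,5.0,9.42,7.68,100.9,13.0
Fenpropimorph,10.0,100.0,0.9778,10.0,8.72,7.56,105.0,8.0
Fenpyroximate,50.0,100.0,0.9639,50.0,13.6,9.79,91.31,24.0
Fenthion oxon sulfone,10.0,100.0,0.9839,10.0,10.2,8.01,114.2,19.0
Fenthion oxon sulfoxide,10.0,100.0,0.9845,10.0,9.18,7.3,108.7,15.0
Fenthion oxon,10.0,100.0,0.9812,10.0,13.5,8.18,99.6,35.0
Fenthion sulfone,10.0,100.0,0.9863,10.0,9.14,5.74,104.3,21.0
Fenthion sulfoxide,10.0,100.0,0.9844,10.0,10.9,6.87,109.1,28.0
Fluopyram,5.0,100.0,0.9863,5.0,8.8,6.06,99.78,21.0
Fluquinconazole,10.0,100.0,0.9788,10.0,13.7,7.18,87.06,33.0
Flutriafol,5.0,100.0,0.9864,5.0,15.7,7.99,106.4,46.0
Fonofos,50.0,100.0,0.9798,50.0,9.71,14.5,80.6,31.0
Fosthiazate,10.0,100.0,0.9801,10.0,9.58,6.62,111.2,20.0
Hexythiazox,10.0,100.0,0.9743,10.0,14.0,9.18,90.38,28.0
Indoxacarb,10.0,100.0,0.9761,10.0,8.92,6.19,109.8,19.0
Iprodione,10.0,100.0,0.9781,10.0,11.8,6.72,72.66,29.0
Iprovalicarb,10.0,100.0,0.9765,10.0,8.66,6.31,107.2,15.0
Isoprocarb,10.0,100.0,0.9791,10.0,9.67,6.1,103.9,23.0
Isoprothiolane,50.0,100.0,0.9802,50.0,11.1,7.33,101.9,24.0
Isoproturon,10.0,100.0,0.9817,10.0,10.6,5.75,98.8,28.0
Kresoxim-methyl,10.0,100.0,0.9772,10.0,13.8,8.66,118.1,36.0
Linuron,10.0,100.0,0.9845,10.0,7.65,5.85,100.4,13.0
Lufenuron,5.0,100.0,0.9817,5.0,15.3,9.83,73.05,46.0
Malaoxon,10.0,100.0,0.9827,10.0,15.3,7.85,97.47,48.0
Malathion,10.0,100.0,0.976,10.0,10.5,6.95,91.7,24.0
Mepanipyrim,10.0,100.0,0.9823,10.0,10.9,6.45,85.49,28.0
Metaflumizone,50.0,100.0,0.979,50.0,10.8,6.9,79.9,20.0
Metalaxyl,5.0,100.0,0.9804,5.0,6.62,5.39,104.4,8.0
Metalaxyl-M,10.0,100.0,0.981,10.0,8.29,6.01,100.6,12.0
Metazachlor,10.0,100.0,0.9818,10.0,12.3,6.64,109.7,34.0
Metconazole,10.0,100.0,0.9815,10.0,11.5,7.69,113.9,27.0
Methiocarb,10.0,100.0,0.9828,10.0,14.4,6.96,90.97,44.0
Methomyl,10.0,100.0,0.9772,10.0,13.7,11.5,100.3,32.0
Metribuzin,10.0,100.0,0.9897,10.0,9.79,7.96,105.4,18.0
Mevinphos,5.0,100.0,0.9878,5.0,13.9,9.43,108.7,34.0
Monocrotophos,5.0,100.0,0.9842,5.0,12.5,9.83,97.15,32.0
Oxadixyl,10.0,100.0,0.9673,10.0,9.08,7.0,108.6,17.0
Paclobutrazole,10.0,100.0,0.9821,10.0,10.3,6.76,115.7,25.0
Paraoxon-ethyl,10.0,100.0,0.9845,10.0,10.2,6.51,94.53,22.0
Paraoxon-methyl,10.0,100.0,0.9803,10.0,9.8,7.41,100.7,17.0
Parathion,10.0,100.0,0.9779,10.0,12.9,7.18,97.65,37.0
Parathion-methyl,10.0,100.0,0.9811,10.0,14.9,8.19,89.33,40.0
Penconazole,10.0,100.0,0.9819,10.0,7.31,11.3,110.0,30.0
Pencycuron,10.0,100.0,0.9811,10.0,16.5,8.55,102.7,47.0
Pendimethalin,50.0,100.0,0.976,50.0,13.2,13.7,73.72,28.0
Phenthoate,10.0,100.0,0.9802,10.0,9.2,7.06,87.69,14.0
Phosalone,10.0,100.0,0.9827,10.0,10.9,8.24,76.55,27.0
Phosmet,10.0,100.0,0.9788,10.0,12.5,5.31,97.77,36.0
Phosphamidon,10.0,100.0,0.9837,10.0,8.0,6.37,100.4,12.0
Phoxim,5.0,100.0,0.9831,5.0,12.3,8.07,100.6,35.0
Pirimiphos-ethyl,50.0,100.0,0.9532,50.0,11.5,8.36,83.72,21.0
Pirimiphos-methyl,5.0,100.0,0.9868,5.0,10.8,6.88,93.54,29.0
Prochloraz,10.0,100.0,0.9781,10.0,12.7,5.8,91.0,37.0
Profenofos,10.0,100.0,0.9747,10.0,17.1,7.46,94.8,49.0
Propiconazole,10.0,100.0,0.9799,10.0,9.01,6.82,96.89,13.0
Propoxur,10.0,100.0,0.983,10.0,9.95,7.33,103.9,23.0
Propyzamide,10.0,100.0,0.9811,10.0,9.94,5.62,96.97,24.0
Prothioconazole-desthio,10.0,100.0,0.9803,10.0,9.35,8.02,111.3,15.0
Pyrazophos,5.0,100.0,0.9869,5.0,12.8,9.56,80.78,24.0
Pyrimethanil,10.0,100.0,0.9809,10.0,7.92,6.84,96.8,10.0
Quinoxyfen,5.0,100.0,0.9872,5.0,13.4,9.59,92.62,31.0
Rotenone,10.0,100.0,0.9815,10.0,11.7,7.37,86.62,29.0
SpinosadA,5.0,100.0,0.9866,5.0,14.6,7.33,97.08,46.0
SpinosadD,10.0,100.0,0.983,10.0,8.55,5.24,108.8,20.0
Spiroxamine,5.0,100.0,0.9862,5.0,12.0,7.5,95.58,25.0
Tebuconazole,50.0,100.0,0.9797,50.0,8.96,6.43,98.45,16.0
Tebufenpyrad,10.0,100.0,0.9848,10.0,13.3,9.44,78.46,34.0
Terbuthylazine,10.0,100.0,0.9809,10.0,10.1,6.64,91.52,24.0
Tetraconazole,10.0,100.0,0.9856,10.0,12.9,7.96,93.76,32.0
Thiabendazole,10.0,100.0,0.9761,10.0,19.7,16.0,112.7,49.0
Thiacloprid,10.0,100.0,0.9882,10.0,9.18,6.53,113.2,20.0
Thiodicarb,10.0,100.0,0.9819,10.0,11.1,8.79,83.66,16.0
Triadimefon,10.0,100.0,0.9805,10.0,10.6,7.92,116.4,22.0
Triadimenol,10.0,100.0,0.9768,10.0,10.3,7.87,119.1,19.0
Tricyclazole,10.0,100.0,0.98,10.0,6.62,5.93,96.8,10.0
Triflumuron,10.0,100.0,0.9786,10.0,9.48,5.24,74.62,19.0
Zoxamide,5.0,100.0,0.9881,5.0,8.69,5.77,80.53,20.0
Fludioxonil,10.0,100.0,0.974,10.0,11.9,6.1,80.95,36.0
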