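pesticide,level_ug_kg,n,cb_mean,cb_sd,cb_censored,ca_mean,ca_sd,ca_censored,significant,pf_printed,reduction_printed,bound_printed
Acetamiprid,50,3,19.2,1.93,False,12.5,1.87,False,True,0.65,34.7,
Azoxystrobin,50,3,32.9,4.5,False,13.2,2.82,False,True,0.4,59.8,
Bixafen,50,3,32.7,0.54,False,24.3,1.71,False,True,0.74,25.8,
Boscalid,50,3,28.0,2.69,False,15.0,1.01,False,True,0.54,46.4,
Bupirimate,50,3,35.2,4.89,False,16.1,2.31,False,True,0.46,54.2,
Buprofezin,50,3,34.4,2.47,False,19.5,1.38,False,True,0.57,43.4,
Cadusafos,50,3,34.5,6.3,False,11.8,0.91,False,True,0.34,65.8,
Carbaryl,50,3,25.4,0.73,False,19.3,1.35,False,True,0.76,24.0,
Carbendazim,50,3,24.2,0.52,False,18.3,2.36,False,True,0.76,24.4,
Carbofuran,50,3,14.6,1.63,False,9.85,1.15,False,True,0.68,32.4,
Carboxin,50,3,,,True,,,True,False,,,
Chlorantraniliprole,50,3,22.8,0.13,False,14.1,0.02,False,True,0.62,38.2,
Chlorfenvinphos,50,3,36.1,1.25,False,22.0,2.28,False,True,0.61,34.0,
Chlorpyrifos-methyl,50,3,24.0,0.23,False,15.9,0.65,False,True,0.66,33.8,
Coumaphos,50,3,,,True,,,True,False,,,
Cyprodinil,50,3,30.0,1.97,False,14.9,0.85,False,True,0.5,50.4,
Diazinon,50,3,37.3,0.34,False,31.7,1.8,False,True,0.85,15.1,
Difenoconazole,50,3,32.7,5.21,False,12.8,1.14,False,True,0.39,61.0,
Diflubenzuron,50,3,37.6,4.07,False,19.2,0.92,False,True,0.51,48.9,
Dimethoate,50,3,13.3,1.26,False,10.7,1.44,False,True,0.8,20.0,
Dimethomorph,50,3,26.7,2.54,False,14.8,1.67,False,True,0.55,44.5,
Diniconazole,50,3,40.6,3.53,False,26.5,1.42,False,True,0.65,34.6,
DMST,50,3,24.9,0.54,False,13.9,0.17,False,True,0.56,44.2,
EPN,50,3,21.5,5.47,False,,,True,False,,,53.6
Epoxiconazole,50,3,41.2,4.64,False,21.3,1.44,False,True,0.52,48.3,
Ethoprophos,50,3,27.3,3.13,False,13.4,1.6,False,True,0.49,50.9,
Etrimfos,50,3,,,True,,,True,False,,,
Fenamidone,50,3,36.3,5.15,False,12.4,1.22,False,True,0.34,65.9,
Fenamiphos sulfone,50,3,14.8,0.59,False,11.3,1.61,False,True,0.76,23.5,
Fenamiphos sulfoxide,50,3,16.8,1.69,False,,,True,False,,,40.4
Fenarimol,50,3,39.6,2.82,False,23.3,1.51,False,True,0.59,41.4,
Fenoxycarb,50,3,35.7,5.81,False,12.9,1.66,False,True,0.36,63.8,
Fenpropidin,50,3,37.2,4.15,False,18.4,1.92,False,True,0.49,50.7,
Fenpropimorph,50,3,39.9,2.73,False,19.1,0.89,False,True,0.48,52.0,
Fenthion oxon sulfone,50,3,23.3,3.6,False,9.88,0.5,False,True,0.42,57.1,
Fenthion oxon sulfoxide,50,3,11.3,1.15,False,,,True,False,,,11.3
Fenthion oxon,50,3,23.8,1.07,False,,,True,False,,,58.0
Fenthion sulfoxide,50,3,23.2,1.82,False,10.5,0.06,False,True,0.45,54.8,
Fluopyram,50,3,32.0,2.28,False,13.1,1.24,False,True,0.41,59.2,
Fluquinconazole,50,3,31.6,0.03,False,19.4,2.59,False,True,0.61,38.8,
Flutriafol,50,3,30.9,3.6,False,13.2,0.8,False,True,0.43,57.3,
Fonofos,50,3,,,True,,,True,False,,,
Fosthiazate,50,3,16.9,2.22,False,13.8,0.65,False,True,0.81,18.7,
Hexythiazox,50,3,13.2,3.31,False,,,True,False,,,24.4
Indoxacarb,50,3,25.3,2.28,False,23.4,4.73,False,False,0.92,7.7,
Iprodione,50,3,26.9,1.95,False,21.8,2.31,False,True,0.81,18.7,
Iprovalicarb,50,3,34.7,5.22,False,15.5,1.25,False,True,0.44,55.4,
Isoprocarb,50,3,22.6,1.45,False,15.7,3.3,False,True,0.69,30.6,
Isoprothiolane,50,3,,,True,,,True,False,,,
Isoproturon,50,3,22.8,2.63,False,10.9,0.73,False,True,0.48,52.0,
Linuron,50,3,28.8,2.17,False,21.1,2.08,False,True,0.73,26.7,
Lufenuron,50,3,13.6,3.86,False,7.57,1.97,False,True,0.55,44.3,
Mepanipyrim,50,3,38.4,3.16,False,24.4,2.02,False,True,0.63,36.6,
Metaflumizone,50,3,,,True,,,True,False,,,
Metalaxyl,50,3,13.9,2.26,False,9.66,0.51,False,True,0.7,30.4,
Metalaxyl-M,50,3,14.8,2.36,False,9.2,0.37,False,True,0.62,37.9,
Metazachlor,50,3,21.3,0.79,False,15.9,2.09,False,True,0.75,25.3,
Metconazole,50,3,37.8,1.66,False,24.7,2.31,False,True,0.65,34.7,
Methiocarb,50,3,30.7,2.36,False,13.0,2.49,False,True,0.55,44.7,
Metrobromuron,50,3,28.1,3.95,False,16.0,0.02,False,True,0.57,42.9,
Metribuzin,50,3,20.3,1.0,False,10.4,0.69,False,True,0.51,49.0,
Oxadixyl,50,3,12.8,1.03,False,9.25,2.52,False,False,0.72,21.8,
Paclobutrazole,50,3,38.6,3.59,False,17.4,1.25,False,True,0.45,54.9,
Parathion,50,3,23.0,2.04,False,18.0,1.56,False,True,0.78,21.8,
Parathion-methyl,50,3,16.3,2.1,False,11.3,0.59,False,True,0.69,30.5,
Penconazole,50,3,40.6,1.35,False,23.8,2.14,False,True,0.59,41.4,
Pencycuron,50,3,29.1,3.95,False,17.1,1.22,False,True,0.59,41.1,
Phenthoate,50,3,34.8,4.92,False,21.6,3.0,False,True,0.62,37.9,
Phosphamidon,50,3,,,True,,,True,False,,,
Pirimiphos-ethyl,50,3,,,True,,,True,False,,,
Pirimiphos-methyl,50,3,32.9,5.57,False,8.86,1.27,False,True,0.27,73.0,
Prochloraz,50,3,22.0,6.35,False,11.4,1.16,False,True,0.52,48.1,
Profenofos,50,3,27.4,2.58,False,13.6,1.63,False,True,0.49,50.5,
Propiconazole,50,3,41.7,5.79,False,14.5,1.72,False,True,0.35,65.4,
Propyzamide,50,3,33.3,0.03,False,20.3,3.53,False,True,0.61,39.1,
Prothioconazole-desthio,50,3,39.8,3.3,False,15.3,0.7,False,True,0.38,61.5,
Pyrazophos,50,3,34.0,1.85,False,23.4,1.31,False,True,0.69,31.3,
Pyrimethanil,50,3,36.2,2.45,False,23.6,1.52,False,True,0.65,34.8,
Quinoxyfen,50,3,12.9,0.87,False,9.28,0.42,False,True,0.71,28.3,
Rotenone,50,3,18.6,1.1,False,,,True,False,,,46.2
SpinosadA,50,3,29.0,1.15,False,13.6,2.1,False,True,0.47,53.1,
SpinosadD,50,3,27.2,0.91,False,14.8,1.06,False,True,0.54,45.6,
Spiroxamine,50,3,37.8,4.59,False,17.7,1.31,False,True,0.47,53.1,
Tebuconazole,50,3,,,True,,,True,False,,,
Tebufenpyrad,50,3,31.6,3.48,False,19.9,1.86,False,True,0.63,37.0,
Terbuthylazine,50,3,35.3,0.4,False,23.9,2.98,False,True,0.68,32.1,
Tetraconazole,50,3,39.5,4.3,False,15.7,1.88,False,True,0.4,60.1,
Thiabendazole,50,3,26.2,6.52,False,12.8,2.49,False,True,0.49,51.3,
Thiacloprid,50,3,28.1,3.11,False,14.6,1.85,False,True,0.52,48.2,
Triadimefon,50,3,37.6,0.61,False,27.1,3.25,False,True,0.72,27.9,
Triadimenol,50,3,38.8,3.35,False,18.9,2.42,False,True,0.49,51.2,
Tricyclazole,50,3,26.6,2.21,False,13.9,1.01,False,True,0.52,47.6,
Triflumuron,50,3,32.0,5.43,False,11.7,1.52,False,True,0.37,63.3,
Zoxamide,50,3,27.5,0.13,False,23.0,1.87,False,True,0.84,16.2,
Fludioxonil,50,3,24.1,1.64,False,24.1,1.96,False,True,1.0,0.21,
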