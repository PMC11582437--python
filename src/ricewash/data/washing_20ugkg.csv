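pesticide,level_ug_kg,n,cb_mean,cb_sd,cb_censored,ca_mean,ca_sd,ca_censored,significant,pf_printed,reduction_printed,bound_printed
Acetamiprid,20,3,,,True,,,True,False,,,
Azoxystrobin,20,3,6.49,0.39,False,,,True,False,,,23.0
Bixafen,20,3,12.4,1.37,False,10.5,1.25,False,False,0.84,15.6,
Boscalid,20,3,7.42,0.84,False,,,True,False,,,32.6
Bupirimate,20,3,,,True,,,True,False,,,
Buprofezin,20,3,10.8,0.67,False,,,True,False,,,7.24
Cadusafos,20,3,7.15,0.82,False,,,True,False,,,30.1
Carbaryl,20,3,,,True,,,True,False,,,
Carbendazim,20,3,,,True,,,True,False,,,
Carbofuran,20,3,,,True,,,True,False,,,
Carboxin,20,3,,,True,,,True,False,,,
Chlorantraniliprole,20,3,,,True,,,True,False,,,
Chlorfenvinphos,20,3,13.0,2.3,False,12.1,1.12,False,False,0.93,6.9,
Chlorpyrifos-methyl,20,3,,,True,,,True,False,,,
Coumaphos,20,3,,,True,,,True,False,,,
Cyprodinil,20,3,10.4,1.57,False,,,True,False,,,3.85
Diazinon,20,3,16.1,0.21,False,15.2,0.31,False,True,0.94,5.8,
Difenoconazole,20,3,,,True,,,True,False,,,
Diflubenzuron,20,3,13.0,0.84,False,10.9,0.77,False,False,0.84,16.2,
Dimethoate,20,3,5.39,0.08,False,5.38,0.34,False,False,0.99,1.0,
Dimethomorph,20,3,,,True,,,True,False,,,
Diniconazole,20,3,13.5,1.81,False,12.5,0.32,False,False,0.93,6.8,
DMST,20,3,,,True,,,True,False,,,
EPN,20,3,,,True,,,True,False,,,
Epoxiconazole,20,3,12.2,1.61,False,9.86,0.38,False,True,0.81,19.1,
Ethoprophos,20,3,,,True,,,True,False,,,
Etrimfos,20,3,,,True,,,True,False,,,
Fenamidone,20,3,,,True,,,True,False,,,
Fenamiphos sulfone,20,3,,,True,,,True,False,,,
Fenamiphos sulfoxide,20,3,,,True,,,True,False,,,
Fenarimol,20,3,12.4,2.43,False,11.1,0.55,False,False,0.89,10.8,
Fenoxycarb,20,3,,,True,,,True,False,,,
Fenpropidin,20,3,11.5,1.98,False,,,True,False,,,12.7
Fenpropimorph,20,3,14.5,2.09,False,10.1,0.05,False,True,0.7,30.4,
Fenthion oxon sulfone,20,3,,,True,,,True,False,,,
Fenthion oxon sulfoxide,20,3,,,True,,,True,False,,,
Fenthion oxon,20,3,,,True,,,True,False,,,
Fenthion sulfoxide,20,3,12.1,1.22,False,,,True,False,,,17.0
Fluopyram,20,3,,,True,,,True,False,,,
Fluquinconazole,20,3,11.8,1.22,False,10.7,0.37,False,False,0.91,9.5,
Flutriafol,20,3,8.3,1.53,False,6.27,0.33,False,True,0.76,24.4,
Fonofos,20,3,,,True,,,True,False,,,
Fosthiazate,20,3,,,True,,,True,False,,,
Hexythiazox,20,3,,,True,,,True,False,,,
Indoxacarb,20,3,11.6,0.48,False,,,True,False,,,14.1
Iprodione,20,3,,,True,,,True,False,,,
Iprovalicarb,20,3,,,True,,,True,False,,,
Isoprocarb,20,3,,,True,,,True,False,,,
Isoprothiolane,20,3,,,True,,,True,False,,,
Isoproturon,20,3,,,True,,,True,False,,,
Linuron,20,3,10.5,1.39,False,,,True,False,,,5.12
Lufenuron,20,3,,,True,,,True,False,,,
Mepanipyrim,20,3,16.7,1.47,False,13.5,0.87,False,True,0.81,18.7,
Metaflumizone,20,3,,,True,,,True,False,,,
Metalaxyl,20,3,,,True,,,True,False,,,
Metalaxyl-M,20,3,,,True,,,True,False,,,
Metazachlor,20,3,,,True,,,True,False,,,
Metconazole,20,3,14.1,0.8,False,13.0,0.68,False,False,0.92,8.0,
Methiocarb,20,3,10.6,2.19,False,10.2,0.53,False,False,0.96,4.14,
Metrobromuron,20,3,,,True,,,True,False,,,
Metribuzin,20,3,,,True,,,True,False,,,
Oxadixyl,20,3,,,True,,,True,False,,,
Paclobutrazole,20,3,11.2,1.81,False,,,True,False,,,10.55
Parathion,20,3,,,True,,,True,False,,,
Parathion-methyl,20,3,,,True,,,True,False,,,
Penconazole,20,3,14.7,1.52,False,13.1,1.2,False,False,0.89,11.22,
Pencycuron,20,3,,,True,,,True,False,,,
Phenthoate,20,3,13.5,1.07,False,,,True,False,,,25.7
Phosphamidon,20,3,,,True,,,True,False,,,
Pirimiphos-ethyl,20,3,,,True,,,True,False,,,
Pirimiphos-methyl,20,3,,,True,,,True,False,,,
Prochloraz,20,3,,,True,,,True,False,,,
Profenofos,20,3,,,True,,,True,False,,,
Propiconazole,20,3,11.6,3.29,False,,,True,False,,,13.7
Propyzamide,20,3,11.2,0.99,False,10.5,0.74,False,False,0.94,6.22,
Prothioconazole-desthio,20,3,11.0,2.09,False,,,True,False,,,8.84
Pyrazophos,20,3,13.2,1.1,False,12.8,0.04,False,False,0.97,2.96,
Pyrimethanil,20,3,12.6,1.23,False,11.4,0.62,False,False,0.9,9.66,
Quinoxyfen,20,3,,,True,,,True,False,,,
Rotenone,20,3,,,True,,,True,False,,,
SpinosadA,20,3,9.73,1.51,False,7.43,0.22,False,True,0.76,23.7,
SpinosadD,20,3,,,True,,,True,False,,,
Spiroxamine,20,3,12.1,1.82,False,8.79,0.54,False,True,0.73,23.7,
Tebuconazole,20,3,,,True,,,True,False,,,
Tebufenpyrad,20,3,12.8,1.48,False,11.0,0.88,False,False,0.86,13.5,
Terbuthylazine,20,3,12.5,1.93,False,,,True,False,,,19.7
Tetraconazole,20,3,11.9,3.1,False,,,True,False,,,16.0
Thiabendazole,20,3,,,True,,,True,False,,,
Thiacloprid,20,3,,,True,,,True,False,,,
Triadimefon,20,3,13.5,0.57,False,,,True,False,,,25.9
Triadimenol,20,3,12.4,1.4,False,,,True,False,,,19.2
Tricyclazole,20,3,,,True,,,True,False,,,
Triflumuron,20,3,,,True,,,True,False,,,
Zoxamide,20,3,12.6,0.47,False,12.6,0.84,False,False,0.99,0.53,
Fludioxonil,20,3,11.5,1.09,False,,,True,False,,,13.0
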