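name,currency,price_year,implied_factor
Bosentan monohydrate,AUD,2004,1.1365208217855418
Peginterferon alfa 2a,GBP,2005,1.6600153198008427
Conjugated vaccine,GBP,2001,1.7618528910356586
Ezetimibe,GBP,2006,1.6286282074613283
Sirolimus,GBP,2003,1.233866972307465
Interferon beta-1a,CAD,2002,1.104063721002925
Ibandronate,GBP,2003,1.233868379602284
Rizatriptan,CAD,2002,1.0846384905660376
Linezolid,CAD,2001,1.1532262481215563
Rivastigmine,CAD,2004,1.043142502414126
Rosiglitazone,GBP,2000,1.7806521315943156
Oseltamivir,USD,2006,0.8455127790359107
Clopidogrel,USD,2002,1.1401796812749003
Memantine,USD,2005,0.8048828065930742
Risperidone,USD,2006,1.0182870393582353
Atomoxetine,GBP,2004,1.687385049921177
Atorvastatin,EUR,2005,1.3663168983442875
Orlistat,EUR,2003,1.382199619047619
Natalizumab,EUR,2005,1.1361864181091876
Oxaliplatin,GBP,2003,1.68220395421436
Rosuvastatin,EUR,2006,1.35237988398818
Trastuzumab,EUR,2005,1.3663166087560805
Cinacalcet,GBP,2004,1.6873978025529166
Sitagliptin,EUR,2006,1.3621832510608816
Rimonabant,USD,2006,1.0182871354535727
Pimecrolimus,CAD,2002,1.1040637142857144
HPV vaccine,CHF,2006,1.0338396462218804
Fulvestrant,EUR,2007,1.195679306544339
Erlotinib,USD,2007,0.8662010343206393
Eplerenone,USD,2001,1.1532261042810632
Raltegravir,CHF,2007,1.0266815505504847
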