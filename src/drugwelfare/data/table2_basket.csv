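name,brand,ratio_amount,ratio_currency,ratio_price_year,ratio_outcome_unit,ratio_target_amount,delta_effect,time_horizon_years,n_users,perspective,user_source
Bosentan monohydrate,Tracleer,55927,AUD,2004,LY,63562.2,3.87,15,,Health care payer,
Peginterferon alfa 2a,Pegasys,10444,GBP,2005,QALY,17337.2,0.3,47.1,,NHS,
Conjugated vaccine,Prevenar,28156,GBP,2001,LY,49606.73,0.0033,10,,Direct cost + cost of work loss,
Ezetimibe,Ezetrol,27475,GBP,2006,LY,44746.56,0.134,24.1,,Health care payer,
Sirolimus,Rapamune,-27047,GBP,2003,LY,-33372.4,1.8,20,,NHS,
Interferon beta-1a,Avonex,44789,CAD,2002,MLY,49449.91,1.21,12,,Societal,
Ibandronate,Bonviva,-20316,GBP,2003,LY,-25067.27,0.019,1.19,,NHS,
Rizatriptan,Maxalt,-6625,CAD,2002,QALY,-7185.73,0.00048,0.0027,,Societal,
Linezolid,Zyvoxid,29945,CAD,2001,QALY,34533.36,6.73,9,,Third-party payer,
Rivastigmine,Exelon,7249,CAD,2004,QALY,7561.74,0.0077,0.46,,Societal,
Rosiglitazone,Avandia,5137,GBP,2000,QALY,9147.21,0.1464,20,,NHS,
Oseltamivir,Tamiflu,-6182,USD,2006,QALY,-5226.96,0.0034,1,,Societal,
Clopidogrel,Plavix,25100,USD,2002,QALY,28618.51,0.55,14.2,,Societal,
Memantine,Ebixa,-6613,USD,2005,QALY,-5322.69,0.0276,2,,Societal,
Risperidone,Risperdal,39890,USD,2006,QALY,40619.47,0.0509,5,,Health care payer (Brazil),
Atomoxetine,Strattera,15224,GBP,2004,QALY,25688.75,0.046,1,,NHS,
Atorvastatin,Lipitor,43667,EUR,2005,QALY,59662.96,0.033,4.8,,Societal (Sweden),
Orlistat,Xenical,13125,EUR,2003,QALY,18141.37,0.0304,1,,Health care system (Sweden),
Natalizumab,Tysabri,-11265,EUR,2005,QALY,-12799.14,0.34,20,,Societal (Sweden),
Oxaliplatin,Eloxatin,4805,GBP,2003,QALY,8082.99,0.68,50,,Health care payer,
Rosuvastatin,Crestor,36548,EUR,2006,QALY,49426.78,0.08,23.5,,Health care payer (Finland),
Trastuzumab,Herceptin,35975,EUR,2005,QALY,49153.24,0.262,25.4,,Societal (Sweden),
Cinacalcet,Mimpara,61890,GBP,2004,QALY,104433.05,0.34,24.1,,Health care payer,
Sitagliptin,Januvia,11547,EUR,2006,QALY,15729.13,0.095,14.2,,Health care payer (UK),
Rimonabant,Acomplia,71973,USD,2006,QALY,73289.18,0.0581,5,,Third-party payer,
Pimecrolimus,Elidel,35000,CAD,2002,QALY,38642.23,0.03,0.5,,Societal,
HPV vaccine,Gardasil,26005,CHF,2006,QALY,26885,0.02,70.55,,Health care payer,
Fulvestrant,Faslodex,-33571,EUR,2007,QALY,-40140.15,0.021,10,,Health care payer (Germany),
Erlotinib,Tarceva,-212700,USD,2007,QALY,-184240.96,0.01,2,,Health care payer,
Eplerenone,Inspra,20579,USD,2001,QALY,23732.24,0.0676,12.8,,Health care payer,
Raltegravir,Isentress,45687,CHF,2007,QALY,46906,3.73,50,,Health care payer,
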