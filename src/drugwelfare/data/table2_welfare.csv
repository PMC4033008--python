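name,welfare
Bosentan monohydrate,10717086
Peginterferon alfa 2a,658144
Conjugated vaccine,1026706
Ezetimibe,6234995
Sirolimus,18005274
Interferon beta-1a,1778900
Ibandronate,3935835
Rizatriptan,268926615
Linezolid,10769990
Rivastigmine,13303996
Rosiglitazone,3486152
Oseltamivir,3630309
Clopidogrel,257359176
Memantine,4550762
Risperidone,996206
Atomoxetine,4430139
Atorvastatin,55463430
Orlistat,25768442
Natalizumab,1961690
Oxaliplatin,3725213
Rosuvastatin,15291792
Trastuzumab,1216275
Cinacalcet,-59101
Sitagliptin,7543994
Rimonabant,7759
Pimecrolimus,54412070
HPV vaccine,22157
Fulvestrant,316366
Erlotinib,956471
Eplerenone,511542
Raltegravir,4440071
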