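table,currency,year,value
deflator,AUD,2004,90.0
deflator,AUD,2010,100.0
deflator,CAD,2001,81.40885222669299
deflator,CAD,2002,85.53851786146949
deflator,CAD,2004,90.0
deflator,CAD,2010,100.0
deflator,CHF,2006,96.72679933048168
deflator,CHF,2007,97.40118534942226
deflator,CHF,2010,100.0
deflator,EUR,2003,77.85499005066875
deflator,EUR,2005,83.7541680269533
deflator,EUR,2006,79.28483073320947
deflator,EUR,2007,90.0
deflator,EUR,2010,100.0
deflator,GBP,2000,69.15156819837718
deflator,GBP,2001,69.88942603667007
deflator,GBP,2003,90.0
deflator,GBP,2004,72.97351723008636
deflator,GBP,2005,74.17695839716882
deflator,GBP,2006,75.6065053714562
deflator,GBP,2010,100.0
deflator,USD,2001,62.81461399847207
deflator,USD,2002,63.53336564670051
deflator,USD,2005,90.00000000000001
deflator,USD,2006,75.68705552348214
deflator,USD,2007,83.62891490910177
deflator,USD,2010,100.0
ppp,AUD,2010,1.0228687396069878
ppp,CAD,2010,0.9388282521727135
ppp,EUR,2010,1.076111375889905
ppp,GBP,2010,1.2313488731553
ppp,USD,2010,0.7243945259337669
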