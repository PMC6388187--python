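indicator,unit,S1,S2,S3,S4
TH,mg/L,150,300,450,550
TDS,mg/L,300,500,1000,2000
NO2,mg/L,1.0,2.0,3.0,10
NO3,mg/L,2.0,5.0,20,30
NH4,mg/L,0.02,0.02,0.2,0.5
Mn,mg/L,0.05,0.05,3.0,10
Fe,mg/L,0.1,0.2,0.3,1.5
Cl,mg/L,50,150,250,350
SO4,mg/L,50,150,250,350
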