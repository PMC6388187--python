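indicator,unit,min,max,mean,sd
pH,-,6.90,7.10,7.00,0.06
EC,uS/cm,655.93,1269.08,915.75,200.29
TH,mg/L,302.80,628.10,437.92,121.28
TDS,mg/L,387.00,824.90,566.63,146.43
Na,mg/L,10.20,58.00,25.95,17.13
K,mg/L,1.80,2.50,2.25,0.25
Ca,mg/L,98.20,194.40,137.90,37.80
Mg,mg/L,13.98,34.66,22.72,6.92
HCO3,mg/L,146.40,411.90,307.12,95.86
Cl,mg/L,12.79,78.15,36.86,22.07
SO4,mg/L,85.03,276.00,140.04,71.35
NO2,mg/L,0.004,0.03,0.01,0.01
NO3,mg/L,0.12,3.40,1.36,1.22
NH4,mg/L,0.02,0.36,0.12,0.15
Mn,mg/L,0.003,0.19,0.05,0.07
Fe,mg/L,0.02,0.18,0.08,0.08
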