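indicator,scheme,lower,upper
pH,WHO2011,6.5,8.5
EC,WHO2011,,500
TH,WHO2011,,300
TDS,WHO2011,,500
Na,WHO2011,,200
K,WHO2011,,12
Ca,WHO2011,,75
Mg,WHO2011,,50
HCO3,WHO2011,,500
Cl,WHO2011,,250
SO4,WHO2011,,250
NO2,WHO2011,,3
NO3,WHO2011,,50
NH4,WHO2011,,35
Mn,WHO2011,,0.1
Fe,WHO2011,,0.3
pH,GB5749,6.5,8.5
TH,GB5749,,450
TDS,GB5749,,1000
Na,GB5749,,200
Cl,GB5749,,250
SO4,GB5749,,250
NO2,GB5749,,0.02
NO3,GB5749,,20
NH4,GB5749,,0.2
Mn,GB5749,,0.05
Fe,GB5749,,0.3
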