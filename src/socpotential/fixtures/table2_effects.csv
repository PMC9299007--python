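measure,intervention,climate,mean_tC_ha_yr,se_tC_ha_yr
M1,IF-NF,temperate,0.12,0.01
M1,IF-NF,subtropical,0.17,0.02
M1,IF-NF,tropical,0.17,0.04
M1,IF-NF,other,0.14,0.01
M2,COF-NF,temperate,0.68,0.06
M2,COF-NF,subtropical,0.90,0.12
M2,COF-NF,tropical,0.51,0.05
M2,COF-NF,other,0.59,0.04
M2,CRF-NF,temperate,0.98,0.16
M2,CRF-NF,subtropical,0.89,0.06
M2,CRF-NF,tropical,0.71,0.14
M2,CRF-NF,other,0.85,0.05
M2,OF-IF,temperate,0.42,0.11
M2,OF-IF,subtropical,0.37,0.07
M2,OF-IF,tropical,0.20,0.04
M2,OF-IF,other,0.29,0.04
M2,OF-NF,temperate,0.53,0.14
M2,OF-NF,subtropical,0.63,0.11
M2,OF-NF,tropical,0.31,0.07
M2,OF-NF,other,0.43,0.05
M3,IT-HT,temperate,0.10,0.02
M3,IT-HT,subtropical,0.17,0.04
M3,IT-HT,other,0.13,0.01
M3,NT-HT,temperate,0.19,0.03
M3,NT-HT,subtropical,0.28,0.05
M3,NT-HT,other,0.23,0.02
M3,NT-IT,temperate,0.09,0.03
M3,NT-IT,subtropical,0.17,0.06
M3,NT-IT,other,0.10,0.03
M4,CC,temperate,0.14,0.01
M4,CC,subtropical,0.15,0.06
M4,CC,tropical,0.17,0.03
M4,CC,other,0.15,0.01
M4,CCP,temperate,0.29,0.19
M4,CCP,other,0.29,0.19
M5,CRES,temperate,0.21,0.02
M5,CRES,other,0.21,0.02
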