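measure,climate,mean_mton,q01_mton,q99_mton
M1,subtropical,21,18,23
M1,temperate,9,8,10
M1,tropical,35,27,45
M1,other,13,13,14
M1,all,78,70,88
M2,subtropical,235,142,326
M2,temperate,114,82,145
M2,tropical,139,85,199
M2,other,104,82,125
M2,all,592,467,713
M2cor,subtropical,10,6,10
M2cor,temperate,6,5,6
M2cor,tropical,8,8,8
M2cor,other,6,5,6
M2cor,all,30,26,30
M3,subtropical,82,50,114
M3,temperate,42,29,56
M3,tropical,58,39,77
M3,other,45,32,57
M3,all,227,182,273
M4,subtropical,49,2,96
M4,temperate,33,29,38
M4,tropical,34,23,45
M4,other,37,33,41
M4,all,153,106,202
M5,subtropical,27,21,33
M5,temperate,22,17,27
M5,tropical,8,6,10
M5,other,16,12,20
M5,all,73,56,90
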