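patient,ptv_cc,sc1,sc2,sc3,sc4,sc5
A,168.19,0.0005,0.0050,0.0088,0.0021,0.0016
B,242.66,0.1303,0.3951,0.6070,0.2774,0.2455
C,361.77,0.1697,0.5131,0.6820,0.3174,0.3069
D,365.68,0.1109,0.3146,0.3335,0.1790,0.1878
E,190.45,0.0057,0.0165,0.0258,0.0124,0.0101
F,556.36,1.4744,3.1408,5.0063,2.5758,2.2159
G,107.51,0.0044,0.0188,0.0433,0.0140,0.0097
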