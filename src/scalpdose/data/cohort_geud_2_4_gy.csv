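patient,ptv_cc,sc1,sc2,sc3,sc4,sc5
A,168.19,39.98,41.81,41.86,40.97,40.91
B,242.66,51.17,52.25,52.61,51.92,51.80
C,361.77,53.38,54.27,54.54,53.94,53.89
D,365.68,52.41,53.27,53.19,52.79,52.87
E,190.45,46.14,47.11,47.22,46.72,46.74
F,556.36,59.16,59.92,60.20,59.67,59.58
G,107.51,47.61,48.80,49.29,48.52,48.28
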