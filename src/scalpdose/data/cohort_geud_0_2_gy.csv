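patient,ptv_cc,sc1,sc2,sc3,sc4,sc5
A,168.19,32.85,37.30,38.48,35.55,35.03
B,242.66,44.71,47.68,48.93,46.70,46.37
C,361.77,45.39,48.44,49.28,47.07,46.98
D,365.68,44.30,47.05,47.21,45.53,45.66
E,190.45,37.59,39.83,40.84,39.21,38.78
F,556.36,51.71,54.37,56.19,53.64,53.11
G,107.51,37.05,40.12,42.02,39.48,38.70
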