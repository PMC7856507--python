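patient,ptv_cc,sc1,sc2,sc3,sc4,sc5
A,168.19,45.3,48.9,52.3,47.8,47.0
B,242.66,62.4,64.7,67.9,64.9,63.6
C,361.77,58.2,62.5,64.8,61.5,60.2
D,365.68,62.7,66.0,65.4,63.5,64.3
E,190.45,60.7,60.4,62.2,61.5,60.6
F,556.36,61.8,63.2,66.3,63.5,62.0
G,107.51,53.1,58.1,61.0,57.2,55.6
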